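# Methods

## The classification model

`taxaprior` trains a multinomial naive Bayes classifier over k-mer counts.
A query sequence S is reduced to counts of its overlapping k-mers (default
k = 7; windows containing characters outside {A,C,G,T} are skipped; no
reverse-complement canonicalisation).  Classes are distinct full-depth
reference lineages, not individual sequences: all reference sequences
annotated with the same lineage pool their k-mer counts, because the priors
are per-taxon.  The score of taxon T is

    log P(T|S) ∝ log P(T) + Σ_m n_S(m) · log θ(T, m),
    θ(T, m) = (count(T, m) + α) / (total(T) + α·|V|),

with Laplace smoothing α = 0.001 over the training vocabulary V.  Query
k-mers outside V are dropped (they carry no information about the fitted
multinomials); a query with no usable k-mers falls back to the priors with a
warning.  Priors come from a `TaxonomicWeights` distribution; the uniform
variant uses a constant log-prior (equivalent to P(T) = 1 up to the shared
normaliser, so the argmax is unchanged and posteriors remain a
distribution).

Reported lineages are truncated by confidence: starting from the winning
class's full depth and moving rootward, the posteriors of all classes
sharing the first L labels are aggregated, and the deepest L whose aggregate
meets the threshold is reported together with that aggregate.  The default
threshold 0.7 follows the balanced-parameter recommendation for this
classifier family; −1 disables truncation (used during weight assembly).
Ties in the argmax resolve to the lexicographically smallest lineage string,
keeping every prediction seed-free and deterministic.

## Taxonomic weights

Bespoke weights are assembled from per-taxon read counts: counts are
aggregated across samples, normalised over the reference taxon set (taxa
never observed get zero), a uniform *unobserved offset* of 10⁻⁶ is added to
every taxon, and the result is renormalised so the weights stay a
probability distribution.  The offset keeps unobserved taxa classifiable;
the final renormalisation is this package's choice (the alternative —
leaving the sum slightly above one — is available behind
`renormalize=False` and changes nothing downstream, since the classifier
normalises posteriors).  Counts may be fractional, so relative-abundance
profiles (e.g. from shotgun metagenomics) work without a separate path.
Average weights are the per-taxon arithmetic mean of several habitats'
bespoke weight distributions — averaging distributions, not pooling raw
counts, so habitats with different sequencing depths contribute equally.
Weights can also be assembled from raw per-sample sequence counts: each
distinct sequence is classified under a uniform-weights model at confidence
−1 and its read counts accrue to the predicted full-depth taxon.

## The cross-validation benchmark

The benchmark never lets information leak from test to train on either
axis.  Reference sequences and samples are folded simultaneously (fold i of
one paired with fold i of the other; 5 folds by default):

1. **Strata.** Standard stratified folding needs ≥ 5 sequences per class.
   Each taxon with ≥ `min_count` (5) sequences becomes its own stratum.  A
   uniform-weights classifier is trained on those large taxa only; every
   sequence of a smaller taxon is classified at confidence −1 and votes for
   its predicted large taxon, weighted by the posterior of that prediction.
   Each small taxon merges into the large taxon with the greatest summed
   vote (ties lexicographic).  The vote tallies are retained.
2. **Folds.** Shuffled stratified K-fold over sequences
   (scikit-learn `StratifiedKFold`), seeded unstratified `KFold` over
   samples (independent shuffle at seed + 1); both partitions are exact and
   per-stratum balanced within one sequence.
3. **Weights per fold.**  Bespoke weights aggregate the *training* samples'
   taxon counts over the *training* sequences' taxa.  A taxon absent from
   the fold's training taxa is remapped to the nearest available taxon:
   its stored voting target if available, otherwise the available taxon
   with the greatest stored vote, with a rank-distance argmin (ties
   lexicographic) as the total-function fallback.
4. **Simulation.**  Each test sample is re-created from test-fold
   sequences: its taxon counts (remapped onto taxa the test sequences
   represent) are spread over that taxon's sequences as evenly as possible
   in lexicographic id order, so every read count is a whole number and
   totals are conserved.  When a taxon has more test sequences than reads,
   the first c sequences get one read each.
5. **Scoring.**  Simulated reads are classified at confidence 0.7 (the
   0.92 alternative is a flag) and scored at every rank.

Correctness is strict (*exact truncation*): a read is correct at a level
only if expected and observed lineages, truncated to that level, are
label-identical including depth — classifying deeper than a shallow
expected annotation is wrong, as is stopping short.  Error rate and
F-measure aggregate across samples weighted by sample read count;
Bray-Curtis dissimilarity (Σ|x−y| / Σ(x+y) on read-count profiles, with
unclassified reads in a dedicated observed-profile bin) averages unweighted
but excludes samples under 1000 reads; folds aggregate unweighted.  TAR
(precision on presence) and TDR (recall on presence) are computed on
presence/absence sets per sample and level; the F-measure is their harmonic
mean on those sets (presence-based by default; the abundance-weighted
variant was deliberately not implemented since nothing downstream consumes
it).  Both leakage invariants — no simulated read's source sequence in the
fold's training set, no test sample in the fold's weights — are asserted at
run time on every fold.

## The confusion index

For a reference database and weights, CI = log Σᵢⱼ d_t(i,j) · I(d_s(i,j) <
0.25) · w(i) w(j), where d_s is the Bray-Curtis dissimilarity of the two
sequences' k-mer profiles (same k as the classifier), d_t the rank depth of
the most recent common ancestor measured from species (0 same species, 1
sister species, 7 different domains), and w(i) the per-sequence weight.
Conventions made explicit here: the log is natural; the sum runs over all
ordered pairs including i = j (self-pairs contribute zero); sequences with
identical lineage annotations contribute zero regardless of annotation
depth (the index counts pairs with *different* taxonomies); taxon weights
split equally among that taxon's sequences, since weights are per-taxon but
the sum is indexed by sequences.  The strict inequality at the 0.25
threshold is kept as displayed.  The exact mode evaluates the full double
sum with pairwise-distance matrices; the Monte Carlo mode draws n pairs
i.i.d. with probability w(i)w(j), estimates the mean of d_t·I(d_s < 0.25),
and reports log(mean) with the delta-method standard error SE(mean)/mean.
Both are deterministic given their inputs (the MC mode given its seed).

## The synthetic-study generator

The generator produces the structure the method exploits, with no external
data: a rank-complete seven-level taxonomy (deterministic topology and
labels given the spec), sequences evolved root-to-leaf by i.i.d.
substitutions with per-rank rates (0.30, 0.20, 0.12, 0.08, 0.05, 0.03, 0.0
by default over 250 bp), 2–7 sequences per species with within-species
substitutions at rate 10⁻⁴, and habitat compositions drawn i.i.d. from a
symmetric Dirichlet (concentration 0.1 → strongly skewed communities).
Samples are multinomial draws of taxon counts at fixed depth; optional reads
copy a uniformly chosen reference sequence of the taxon with i.i.d. errors.
References are rejection-resampled until they contain a sister pair with
d_s < 0.25, a pair with d_s ≥ 0.25, a species with ≥ 5 sequences and one
with fewer — guaranteeing the benchmark exercises stratum merging and
remapping.  All randomness flows from the spec's single seed through
numbered seed-sequence streams, so any sub-artifact is reproducible alone.

Two default choices deserve emphasis.  The species-rank substitution rate
is zero: sister species share their ancestral marker and differ only by
within-species variation.  This is the saturated-marker regime that
motivates habitat weights in the first place — in 99%-identity reference
sets many named species carry indistinguishable amplicons — and it is the
regime in which priors, not likelihoods, decide the call.  With appreciable
species-rank divergence the k-mer likelihood is overwhelmingly decisive
(a single substitution shifts seven k-mers) and any prior is irrelevant.
Second, within-species variation is kept very small (≈ 0.025 substitutions
per sequence) so that pooled class profiles of sister species stay nearly
proportional; larger within-species spread injects spurious decisive
likelihood tilts between sisters.  Consequently the generator emulates the
*confusable* end of real references: absolute error rates it produces
(e.g. uniform species-level error near 80–90%) are far above what mixed
real references show, and passing benchmarks here demonstrates the ordering
and monotonicity of weighting strategies, not real-world error magnitudes.
It also omits chimeras, PCR/primer bias, indels and base-composition
realism.

## Study scales and numerical conventions

The shipped benchmarks run one habitat of 40 samples × 2000 reads against a
32-species reference (16 sister pairs), with 13 further habitats feeding
the average-weights strategy (matching the 14-habitat design of the survey
compilation whose per-habitat sample counts ship as
`EMPO3_SAMPLE_COUNTS`); five study seeds for the strategy comparison and
three for the misspecification ladder.  These sizes keep the full
acceptance run under a minute while leaving every effect far from
floating-point noise.  The ladder probes, per study, the auxiliary habitat
whose bespoke weights are most L1-distant from the evaluated habitat's —
the most dissimilar habitat is the informative probe for degradation.
Weight distributions validate to sum 1 within 10⁻⁸; posterior vectors
normalise through log-sum-exp; zero-read samples are dropped with a
warning; a Dirichlet component that underflows to zero is clipped to
10⁻¹² before renormalisation so weights stay strictly positive.  Model
files carry a format-version field and refuse to load under a mismatched
version.

## Known limitations

Distances between lineages annotated to different depths follow one fixed
convention (total ranks minus common-prefix length), so two identical
genus-level annotations sit at distance 1, not 0 — except inside the
confusion index, which zeroes identical annotations by design.  The
confidence-aggregation rule (posterior mass summed over classes sharing the
winner's prefix) is this package's stated convention; upstream
implementations do not document theirs.  Cross-habitat orchestration is a
thin loop over `run_cv` calls, not a scheduler; training is in-memory and
single-threaded, adequate for references up to a few thousand sequences.
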