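# taxaprior

Habitat-aware taxonomic weights for naive Bayes amplicon classification.

Marker-gene surveys assign taxonomy to amplicon sequence variants with a
multinomial naive Bayes classifier over k-mer counts.  The standard setup
assumes *uniform* class priors — every reference taxon equally likely — which
is badly wrong for real communities and costs accuracy exactly where it
matters most: species whose marker sequences are nearly identical.
`taxaprior` implements the weighted alternative end to end:

- **taxonomic weights** — per-taxon priors P(T) for the classifier, which
  scores P(T|S) = P(S|T)·P(T)/P(S) with smoothed multinomial likelihoods
  θ(T,m) = (count(T,m) + α) / (total(T) + α·|V|) over k-mers, and truncates
  the reported lineage to the deepest rank whose aggregated posterior meets a
  confidence threshold (default 0.7; −1 forces a full-depth call);
- **bespoke weights** assembled from the taxonomic abundances observed in
  samples of the query's habitat (aggregate → normalise → add a 10⁻⁶ uniform
  unobserved offset → renormalise), **average weights** (the mean of several
  habitats' bespoke weights), and **uniform weights**;
- an **abundance-aware cross-validation benchmark** that folds reference
  sequences (stratified, with <5-sequence taxa merged into larger strata by
  confidence-weighted voting) and samples simultaneously, simulates each test
  sample from test-fold sequences with whole-number read counts, and scores
  error rate, F-measure, TAR/TDR and Bray-Curtis at every rank under the
  exact-truncation correctness rule;
- the **confusion index**
  CI = log Σᵢ Σⱼ d_t(i,j) · I(d_s(i,j) < 0.25) · w(i) · w(j),
  the log expected taxonomic distance between weight-sampled sequence pairs
  whose k-mer Bray-Curtis dissimilarity d_s falls below 0.25 — a property of
  a reference database plus weights that predicts how hard a habitat is to
  classify (exact double sum and a seeded Monte Carlo estimator);
- a **synthetic-study generator** producing seven-rank references with
  confusable sister species, skewed Dirichlet habitats, and multinomial
  samples, so the whole pipeline runs at desk scale with no downloads.

## Worked example

`examples/cross_validation_benchmark.py` simulates one skewed habitat
(40 samples × 2000 reads) over a 32-species reference whose sister species
share their marker sequence, then benchmarks the three weighting strategies:

```
 weighting  genus error  species error
   bespoke        0.000          0.172
   average        0.000          0.349
   uniform        0.000          0.822
```

Every strategy resolves the genus perfectly — the genera are well separated —
but at species rank the marker alone cannot split sister pairs: uniform
priors misclassify 82% of reads (calls either retreat to genus or pick the
wrong sister), averaging habitats recovers part of the signal, and the
habitat's own bespoke priors cut the error to 17%, essentially the reads of
the rarer sisters.  `examples/weight_misspecification_ladder.py` shows the
error climbing monotonically (Pearson r = 0.909) as the priors interpolate
from bespoke towards a dissimilar habitat's weights, and
`examples/confusion_index_of_a_habitat.py` scores habitats' intrinsic
difficulty with the confusion index.

The same operations are available as a CLI:

```bash
taxaprior simulate --seed 1 --n-habitats 2 --out-dir study/
taxaprior assemble-weights --table study/habitat01_table.tsv \
    --reference-tax study/reference_taxonomy.tsv --output weights.json
taxaprior fit --reference-seqs study/reference.fasta \
    --reference-tax study/reference_taxonomy.tsv \
    --weights weights.json --output model.json
taxaprior classify --model model.json --queries study/reference.fasta \
    --confidence 0.7 --output calls.tsv
```

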