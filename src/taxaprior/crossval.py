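"""Abundance-aware cross-validation benchmark for weighted classification.

The benchmark folds reference sequences and empirical samples
simultaneously: a classifier only ever scores sequences it was not trained
on, and bespoke/average weights are only ever derived from samples they are
not tested on.  Reference folding is stratified; because many taxa hold
fewer than five sequences, every taxon with at least ``min_count`` (default
5) sequences becomes its own stratum and each smaller taxon is merged into
the large taxon elected by confidence-weighted voting of its sequences'
classifications.  Sample folding is unstratified.

Within each fold, test samples are re-created from test-fold reference
sequences: each sample's taxon counts (remapped onto taxa the test
sequences actually represent) are spread over that taxon's test sequences
as evenly as possible so that every read count stays a whole number, and
the resulting reads are classified and scored level by level.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import (
    DEFAULT_ALPHA,
    DEFAULT_CONFIDENCE,
    DEFAULT_K,
    classify,
    fit,
)
from .io import FeatureTable, ReferenceDB
from .metrics import EvaluationReport, sample_metrics, DEFAULT_MIN_READS_BRAY_CURTIS
from .taxonomy import Lineage, taxonomic_distance
from .weights import (
    DEFAULT_UNOBSERVED_OFFSET,
    TaxonomicWeights,
    assemble_weights,
    average_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StrataPlan",
    "FoldPlan",
    "SimulatedSample",
    "build_strata",
    "split_folds",
    "remap_missing",
    "simulate_sample",
    "run_cv",
    "cross_habitat_pairs",
    "DEFAULT_MIN_STRATUM_COUNT",
]

DEFAULT_MIN_STRATUM_COUNT = 5


@dataclass(frozen=True)
class StrataPlan:
    """Assignment of every reference sequence to a stratum.

    ``vote_tallies[small_taxon][large_taxon]`` accumulates the posterior of
    each of the small taxon's sequences for its predicted large taxon; the
    argmax is stored in ``small_to_large`` and re-used when missing taxa
    must be remapped to whatever taxa a fold makes available.
    """

    stratum_of: dict[str, Lineage]
    large_taxa: frozenset[Lineage]
    small_to_large: dict[Lineage, Lineage]
    vote_tallies: dict[Lineage, dict[Lineage, float]]


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int
    ref_fold_of: dict[str, int]
    sample_fold_of: dict[str, int]
    seed: int

    def ref_ids(self, fold: int, train: bool) -> list[str]:
        return sorted(
            i for i, f in self.ref_fold_of.items() if (f != fold) == train
        )

    def sample_ids(self, fold: int, train: bool) -> list[str]:
        return sorted(
            s for s, f in self.sample_fold_of.items() if (f != fold) == train
        )


@dataclass(frozen=True)
class SimulatedSample:
    sample_id: str
    expected: dict[Lineage, int]
    draws: dict[str, int]


def _vote(tally: Mapping[Lineage, float]) -> Lineage:
    top = max(tally.values())
    return min((t for t, v in tally.items() if v == top), key=str)


def build_strata(
    reference: ReferenceDB,
    min_count: int = DEFAULT_MIN_STRATUM_COUNT,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
) -> StrataPlan:
    """Form cross-validation strata, merging small taxa into large ones.

    Taxa with at least ``min_count`` sequences become their own strata.  A
    uniform-weights classifier is trained on the large taxa only; each
    sequence of a small taxon is classified at confidence −1 and votes for
    its predicted taxon with weight equal to that prediction's posterior.
    Each small taxon joins the large taxon with the greatest summed vote
    (ties resolved to the lexicographically smallest lineage).
    """
    by_taxon = reference.ids_by_taxon()
    large = {t for t, ids in by_taxon.items() if len(ids) >= min_count}
    if not large:
        raise ValueError(
            f"no taxon has >= {min_count} sequences; lower min_count"
        )
    stratum_of: dict[str, Lineage] = {}
    for taxon in large:
        for sid in by_taxon[taxon]:
            stratum_of[sid] = taxon
    small = sorted(set(by_taxon) - large, key=str)
    small_to_large: dict[Lineage, Lineage] = {}
    vote_tallies: dict[Lineage, dict[Lineage, float]] = {}
    if small:
        large_ids = [sid for t in large for sid in by_taxon[t]]
        model = fit(reference.subset(large_ids), weights=None, k=k, alpha=alpha)
        for taxon in small:
            tally: dict[Lineage, float] = defaultdict(float)
            for sid in by_taxon[taxon]:
                predicted, posterior = classify(
                    model, reference.sequences[sid], confidence=-1
                )
                tally[predicted] += posterior
            target = _vote(tally)
            small_to_large[taxon] = target
            vote_tallies[taxon] = dict(tally)
            for sid in by_taxon[taxon]:
                stratum_of[sid] = target
    return StrataPlan(
        stratum_of=stratum_of,
        large_taxa=frozenset(large),
        small_to_large=small_to_large,
        vote_tallies=vote_tallies,
    )


def split_folds(
    strata: StrataPlan,
    sample_ids: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Shuffled stratified folds for sequences, unstratified for samples.

    Deterministic given ``seed``; the sample split uses an independent
    seeded shuffle (``seed + 1``).
    """
    ids = sorted(strata.stratum_of)
    labels = [str(strata.stratum_of[i]) for i in ids]
    stratum_sizes = Counter(labels)
    too_small = [s for s, n in stratum_sizes.items() if n < n_folds]
    if too_small:
        raise ValueError(
            f"{len(too_small)} strata have fewer than {n_folds} sequences"
        )
    if len(sample_ids) < n_folds:
        raise ValueError(
            f"need at least {n_folds} samples, got {len(sample_ids)}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ref_fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        for j in test_idx:
            ref_fold_of[ids[j]] = fold
    samples = sorted(sample_ids)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + 1)
    sample_fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(kf.split(np.zeros(len(samples)))):
        for j in test_idx:
            sample_fold_of[samples[j]] = fold
    return FoldPlan(
        n_folds=n_folds,
        ref_fold_of=ref_fold_of,
        sample_fold_of=sample_fold_of,
        seed=seed,
    )


def remap_missing(
    taxon: Lineage, available: set[Lineage], strata: StrataPlan
) -> Lineage:
    """Map a taxon onto the nearest taxon present in ``available``.

    Identity when already available; otherwise the stored voting target if
    that is available; otherwise the available taxon with the greatest
    stored vote tally.  As a last resort (e.g. a taxon with no tally) the
    available taxon at minimal rank distance, ties to the lexicographically
    smallest, keeps the function total.
    """
    if not available:
        raise ValueError("no available taxa to remap onto")
    if taxon in available:
        return taxon
    target = strata.small_to_large.get(taxon)
    if target is not None and target in available:
        return target
    tally = strata.vote_tallies.get(taxon)
    if tally:
        restricted = {t: v for t, v in tally.items() if t in available}
        if restricted:
            return _vote(restricted)
    return min(available, key=lambda t: (taxonomic_distance(taxon, t), str(t)))


def simulate_sample(
    expected: Mapping[Lineage, int],
    test_sequences_by_taxon: Mapping[Lineage, Sequence[str]],
    sample_id: str = "",
) -> SimulatedSample:
    """Spread each taxon's expected reads evenly over its test sequences.

    For a taxon with ``c`` reads and ``m`` sequences, every sequence gets
    ``c // m`` reads and the first ``c mod m`` sequences in lexicographic id
    order get one extra; when ``c < m`` the first ``c`` sequences get a
    single read each.  Totals are conserved and every count is a whole
    number.
    """
    draws: dict[str, int] = {}
    for taxon in sorted(expected, key=str):
        c = int(expected[taxon])
        if c <= 0:
            continue
        seqs = sorted(test_sequences_by_taxon.get(taxon, ()))
        if not seqs:
            raise ValueError(
                f"expected taxon has no test sequence (remap first): {taxon}"
            )
        m = len(seqs)
        base, extra = divmod(c, m)
        for i, sid in enumerate(seqs):
            n = base + (1 if i < extra else 0)
            if n > 0:
                draws[sid] = draws.get(sid, 0) + n
    return SimulatedSample(
        sample_id=sample_id, expected=dict(expected), draws=draws
    )


def _bespoke_counts(
    table: FeatureTable,
    sample_ids: Iterable[str],
    available: set[Lineage],
    strata: StrataPlan,
) -> Counter:
    counts: Counter[Lineage] = Counter()
    for sample_id in sample_ids:
        for taxon, c in table.sample_counts(sample_id).items():
            counts[remap_missing(taxon, available, strata)] += c
    return counts


def _fold_weights(
    weighting: str,
    table: FeatureTable,
    train_samples: Sequence[str],
    train_taxa: set[Lineage],
    strata: StrataPlan,
    fixed_weights: TaxonomicWeights | None,
    aux_tables: Sequence[FeatureTable] | None,
    unobserved_offset: float,
) -> TaxonomicWeights | None:
    if weighting == "uniform":
        return None
    if weighting == "bespoke":
        counts = _bespoke_counts(table, train_samples, train_taxa, strata)
        return assemble_weights(counts, train_taxa, unobserved_offset)
    if weighting == "average":
        if not aux_tables:
            raise ValueError(
                "average weighting needs aux_tables holding the other habitats"
            )
        sets = [
            assemble_weights(
                _bespoke_counts(table, train_samples, train_taxa, strata),
                train_taxa,
                unobserved_offset,
            )
        ]
        for aux in aux_tables:
            sets.append(
                assemble_weights(
                    _bespoke_counts(aux, aux.samples, train_taxa, strata),
                    train_taxa,
                    unobserved_offset,
                )
            )
        return average_weights(sets)
    if weighting == "fixed":
        if fixed_weights is None:
            raise ValueError("fixed weighting needs fixed_weights")
        # Treat the supplied weights as fractional counts so taxa missing
        # from this fold's training set are remapped and the offset applies.
        counts: Counter[Lineage] = Counter()
        for taxon, w in fixed_weights.items():
            counts[remap_missing(taxon, train_taxa, strata)] += w
        return assemble_weights(counts, train_taxa, unobserved_offset)
    raise ValueError(f"unknown weighting {weighting!r}")


def run_cv(
    reference: ReferenceDB,
    table: FeatureTable,
    weighting: str = "uniform",
    *,
    fixed_weights: TaxonomicWeights | None = None,
    aux_tables: Sequence[FeatureTable] | None = None,
    n_folds: int = 5,
    seed: int = 0,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
    confidence: float = DEFAULT_CONFIDENCE,
    levels: Sequence[int] = tuple(range(1, 8)),
    min_count: int = DEFAULT_MIN_STRATUM_COUNT,
    unobserved_offset: float = DEFAULT_UNOBSERVED_OFFSET,
    min_reads_bray_curtis: int = DEFAULT_MIN_READS_BRAY_CURTIS,
) -> EvaluationReport:
    """Run the full benchmark for one weighting strategy.

    Per fold: weights are derived only from training samples over the taxa
    of the training sequences; the classifier is trained on training
    sequences; test samples are simulated from test sequences and
    classified; per-sample metrics are recorded at every requested level.
    Reference fold i is paired with sample fold i.  Leakage is asserted at
    run time: no simulated read's source sequence is in that fold's
    training set, and no test sample contributes to the fold's weights.
    """
    strata = build_strata(reference, min_count=min_count, k=k, alpha=alpha)
    sample_ids = [s for s in table.samples if table.total(s) > 0]
    dropped = set(table.samples) - set(sample_ids)
    if dropped:
        logger.warning("dropping %d zero-read samples", len(dropped))
    folds = split_folds(strata, sample_ids, n_folds=n_folds, seed=seed)
    report = EvaluationReport(
        provenance={
            "weighting": weighting,
            "n_folds": n_folds,
            "seed": seed,
            "k": k,
            "alpha": alpha,
            "confidence": confidence,
            "min_count": min_count,
            "unobserved_offset": unobserved_offset,
            "fold_pairing": "reference fold i paired with sample fold i",
            "n_samples": len(sample_ids),
            "n_reference": len(reference),
        },
        min_reads_bray_curtis=min_reads_bray_curtis,
    )
    for fold in range(n_folds):
        train_ref = folds.ref_ids(fold, train=True)
        test_ref = folds.ref_ids(fold, train=False)
        train_db = reference.subset(train_ref)
        train_taxa = train_db.taxa()
        test_by_taxon = reference.subset(test_ref).ids_by_taxon()
        train_samples = folds.sample_ids(fold, train=True)
        test_samples = folds.sample_ids(fold, train=False)
        assert set(train_samples).isdisjoint(test_samples)
        weights = _fold_weights(
            weighting,
            table,
            train_samples,
            train_taxa,
            strata,
            fixed_weights,
            aux_tables,
            unobserved_offset,
        )
        model = fit(train_db, weights, k=k, alpha=alpha)
        train_ref_set = set(train_ref)
        prediction_cache: dict[str, Lineage] = {}
        for sample_id in test_samples:
            counts = table.sample_counts(sample_id)
            available = set(test_by_taxon)
            expected: Counter[Lineage] = Counter()
            for taxon, c in counts.items():
                expected[remap_missing(taxon, available, strata)] += c
            sim = simulate_sample(expected, test_by_taxon, sample_id=sample_id)
            assert not set(sim.draws) & train_ref_set, "train/test sequence leakage"
            reads = []
            for sid, n in sim.draws.items():
                if sid not in prediction_cache:
                    prediction_cache[sid], _ = classify(
                        model, reference.sequences[sid], confidence=confidence
                    )
                reads.append((reference.lineages[sid], prediction_cache[sid], n))
            for level in levels:
                record = sample_metrics(reads, level)
                report.add(
                    sample_id=sample_id, fold=fold, level=level, **record
                )
    return report


def cross_habitat_pairs(habitat_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered (weights-habitat, sample-habitat) pairs across habitats.

    These are the comparisons probed when weights from one habitat classify
    samples from another; 14 habitats yield 182 pairs.
    """
    return [
        (a, b) for a in habitat_ids for b in habitat_ids if a != b
    ]
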