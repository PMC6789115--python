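"""Taxonomic weights: per-taxon prior probabilities for the classifier.

A classifier trained with *uniform* weights assumes every reference taxon is
equally likely to be observed — the conventional default, and demonstrably
wrong for real communities.  *Bespoke* weights are assembled from taxonomic
abundances observed in samples from the habitat of interest; *average*
weights are the arithmetic mean of several habitats' bespoke weights.

Assembly follows aggregate -> normalise -> add a small uniform unobserved
offset (default ``1e-6``) -> renormalise, so unobserved reference taxa keep
a strictly positive prior.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Mapping
from typing import Iterable, Sequence

from .taxonomy import Lineage

__all__ = [
    "TaxonomicWeights",
    "uniform_weights",
    "assemble_weights",
    "average_weights",
    "weights_from_sequence_samples",
    "DEFAULT_UNOBSERVED_OFFSET",
]

DEFAULT_UNOBSERVED_OFFSET = 1e-6
_SUM_TOL = 1e-8


class TaxonomicWeights(Mapping):
    """Normalized probability distribution over full-depth reference taxa.

    Behaves as a read-only mapping ``Lineage -> probability``.  All
    probabilities are positive and sum to one within ``1e-8`` unless
    ``check=False`` (used only for the deliberately-unnormalized assembly
    variant).
    """

    def __init__(
        self,
        weights: Mapping[Lineage, float],
        unobserved_offset: float = 0.0,
        *,
        check: bool = True,
    ):
        self._weights = dict(weights)
        self.unobserved_offset = float(unobserved_offset)
        if check:
            if not self._weights:
                raise ValueError("weights must cover at least one taxon")
            if any(w <= 0 for w in self._weights.values()):
                raise ValueError("all taxonomic weights must be positive")
            total = sum(self._weights.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValueError(f"weights must sum to 1, got {total!r}")

    def __getitem__(self, taxon: Lineage) -> float:
        return self._weights[taxon]

    def __iter__(self):
        return iter(self._weights)

    def __len__(self) -> int:
        return len(self._weights)

    @property
    def taxa(self) -> frozenset[Lineage]:
        return frozenset(self._weights)

    def __repr__(self) -> str:
        return f"TaxonomicWeights({len(self)} taxa, offset={self.unobserved_offset})"


def uniform_weights(taxa: Iterable[Lineage]) -> TaxonomicWeights:
    """Equal probability ``1/|taxa|`` for every taxon."""
    taxa = set(taxa)
    if not taxa:
        raise ValueError("cannot build uniform weights over an empty taxon set")
    p = 1.0 / len(taxa)
    return TaxonomicWeights({t: p for t in taxa})


def assemble_weights(
    taxon_read_counts: Mapping[Lineage, float],
    reference_taxa: Iterable[Lineage],
    unobserved_offset: float = DEFAULT_UNOBSERVED_OFFSET,
    renormalize: bool = True,
) -> TaxonomicWeights:
    """Turn aggregated taxon read counts into weights over the reference taxa.

    Counts are normalised to sum to one over ``reference_taxa`` (taxa with no
    reads get zero), the uniform ``unobserved_offset`` is added to every
    taxon, and the result is renormalised.  Counts may be fractional, e.g.
    relative abundances from shotgun profiles.  Taxa counted but absent from
    the reference must be remapped upstream and are an error here.
    """
    reference_taxa = set(reference_taxa)
    if not reference_taxa:
        raise ValueError("reference taxon set is empty")
    extra = set(taxon_read_counts) - reference_taxa
    if extra:
        raise ValueError(
            f"{len(extra)} counted taxa are not reference taxa "
            f"(remap them first), e.g. {sorted(map(str, extra))[:3]}"
        )
    if any(c < 0 for c in taxon_read_counts.values()):
        raise ValueError("read counts must be non-negative")
    total = float(sum(taxon_read_counts.values()))
    if total == 0 and unobserved_offset <= 0:
        raise ValueError("all counts are zero and the unobserved offset is zero")
    weights = {}
    for taxon in reference_taxa:
        normalized = taxon_read_counts.get(taxon, 0.0) / total if total > 0 else 0.0
        weights[taxon] = normalized + unobserved_offset
    if renormalize:
        z = sum(weights.values())
        weights = {t: w / z for t, w in weights.items()}
        return TaxonomicWeights(weights, unobserved_offset=unobserved_offset)
    return TaxonomicWeights(weights, unobserved_offset=unobserved_offset, check=False)


def average_weights(weight_sets: Sequence[TaxonomicWeights]) -> TaxonomicWeights:
    """Per-taxon arithmetic mean of several weight sets over the same taxa."""
    if not weight_sets:
        raise ValueError("need at least one weight set to average")
    support = weight_sets[0].taxa
    for ws in weight_sets[1:]:
        if ws.taxa != support:
            raise ValueError("weight sets to average must share the same taxon set")
    n = len(weight_sets)
    return TaxonomicWeights(
        {t: sum(ws[t] for ws in weight_sets) / n for t in support},
        unobserved_offset=weight_sets[0].unobserved_offset,
    )


def weights_from_sequence_samples(
    sample_sequences: Mapping[str, Mapping[str, float]],
    model,
    unobserved_offset: float = DEFAULT_UNOBSERVED_OFFSET,
) -> TaxonomicWeights:
    """Assemble bespoke weights from raw per-sample sequence counts.

    ``sample_sequences`` maps sample id -> {sequence string: read count}.
    Every distinct sequence is classified with a uniform-weights model at
    confidence −1 (full-depth output forced), read counts are accumulated on
    the predicted taxa across all samples, and the totals are passed to
    :func:`assemble_weights`.  Aggregation is order-free, so two samples are
    interchangeable with one merged sample.
    """
    from .classifier import classify

    if not sample_sequences:
        raise ValueError("no samples provided")
    if not model.uniform_priors:
        raise ValueError("weights must be assembled under a uniform-weights model")
    counts: Counter[Lineage] = Counter()
    prediction_cache: dict[str, Lineage] = {}
    for sample_id in sorted(sample_sequences):
        for seq, n_reads in sample_sequences[sample_id].items():
            if n_reads <= 0:
                continue
            if seq not in prediction_cache:
                prediction_cache[seq], _ = classify(model, seq, confidence=-1)
            counts[prediction_cache[seq]] += n_reads
    return assemble_weights(
        counts, set(model.classes), unobserved_offset=unobserved_offset
    )
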