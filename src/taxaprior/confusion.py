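"""The confusion index: how often near-identical sequences disagree in taxonomy.

For a reference database and taxonomic weights, the confusion index is the
natural log of the expected taxonomic distance between two independently
weight-sampled sequences, restricted (via an indicator) to pairs whose
k-mer Bray-Curtis dissimilarity falls below a threshold (default 0.25):

    CI = log sum_i sum_j d_t(i, j) * I(d_s(i, j) < 0.25) * w(i) * w(j)

A habitat whose abundant species have near-identical marker sequences in
different taxa scores high and is hard to classify; the index therefore
predicts habitat-specific classification difficulty.  Taxon weights are
split equally among a taxon's reference sequences to give the per-sequence
w(i).  The double sum runs over all ordered pairs including i = j
(self-pairs contribute zero since d_t = 0).  Besides the exact double sum,
a Monte Carlo estimator samples pairs i.i.d. with probability w(i)w(j).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .classifier import DEFAULT_K, kmer_profile
from .io import ReferenceDB
from .metrics import bray_curtis
from .taxonomy import taxonomic_distance
from .weights import TaxonomicWeights

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionIndexEstimate",
    "sequence_dissimilarity",
    "per_sequence_weights",
    "confusion_index_exact",
    "confusion_index_mc",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.25


@dataclass(frozen=True)
class ConfusionIndexEstimate:
    """A confusion-index value (natural log scale) with its uncertainty.

    ``value`` is ``-inf`` when the double sum (or sample mean) is zero.
    The exact method has ``standard_error`` 0 and ``n_pairs = n**2``; the
    Monte Carlo method reports the delta-method standard error of the log
    (SE of the mean divided by the mean).
    """

    value: float
    standard_error: float
    n_pairs: int
    threshold: float
    k: int
    method: str
    seed: int | None = None


def sequence_dissimilarity(seq_a: str, seq_b: str, k: int = DEFAULT_K) -> float:
    """Bray-Curtis dissimilarity of the two sequences' k-mer count profiles."""
    pa = kmer_profile(seq_a, k)
    pb = kmer_profile(seq_b, k)
    if not pa or not pb:
        raise ValueError("both sequences must yield a non-empty k-mer profile")
    return bray_curtis(pa, pb)


def per_sequence_weights(
    reference: ReferenceDB, weights: TaxonomicWeights | None
) -> dict[str, float]:
    """Split each taxon's weight equally among that taxon's sequences.

    ``weights=None`` means uniform taxonomic weights.  The result sums to
    one over all sequence ids.
    """
    by_taxon = reference.ids_by_taxon()
    if weights is None:
        taxon_weight = {t: 1.0 / len(by_taxon) for t in by_taxon}
    else:
        missing = [t for t in by_taxon if t not in weights]
        if missing:
            raise ValueError(
                f"{len(missing)} reference taxa missing from weights"
            )
        taxon_weight = {t: weights[t] for t in by_taxon}
        total = sum(taxon_weight.values())
        taxon_weight = {t: w / total for t, w in taxon_weight.items()}
    out: dict[str, float] = {}
    for taxon, ids in by_taxon.items():
        share = taxon_weight[taxon] / len(ids)
        for sid in ids:
            out[sid] = share
    return out


def _pair_matrices(reference: ReferenceDB, k: int):
    """Pairwise sequence-dissimilarity and taxonomic-distance matrices."""
    ids = reference.ids
    profiles = [kmer_profile(reference.sequences[i], k) for i in ids]
    if any(not p for p in profiles):
        raise ValueError("a reference sequence yields no k-mers at this k")
    vocab = sorted(set().union(*profiles))
    index = {m: j for j, m in enumerate(vocab)}
    x = np.zeros((len(ids), len(vocab)))
    for i, profile in enumerate(profiles):
        for kmer, n in profile.items():
            x[i, index[kmer]] = n
    d_s = squareform(pdist(x, metric="braycurtis"))
    lineages = [reference.lineages[i] for i in ids]
    # identical taxonomies contribute zero regardless of annotation depth:
    # the index counts pairs with *different* taxonomies only
    d_t = np.array(
        [
            [0.0 if a == b else taxonomic_distance(a, b) for b in lineages]
            for a in lineages
        ]
    )
    return ids, d_s, d_t


def confusion_index_exact(
    reference: ReferenceDB,
    weights: TaxonomicWeights | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
) -> ConfusionIndexEstimate:
    """Evaluate the confusion-index double sum over all ordered pairs."""
    n = len(reference)
    if n < 2:
        logger.warning("reference has fewer than two sequences; CI is -inf")
        return ConfusionIndexEstimate(
            value=-math.inf,
            standard_error=0.0,
            n_pairs=n * n,
            threshold=threshold,
            k=k,
            method="exact",
        )
    ids, d_s, d_t = _pair_matrices(reference, k)
    w = np.array([per_sequence_weights(reference, weights)[i] for i in ids])
    total = float((d_t * (d_s < threshold) * np.outer(w, w)).sum())
    value = math.log(total) if total > 0 else -math.inf
    return ConfusionIndexEstimate(
        value=value,
        standard_error=0.0,
        n_pairs=n * n,
        threshold=threshold,
        k=k,
        method="exact",
    )


def confusion_index_mc(
    reference: ReferenceDB,
    weights: TaxonomicWeights | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_K,
    n_pairs: int = 100_000,
    seed: int = 0,
) -> ConfusionIndexEstimate:
    """Monte Carlo estimate of the confusion index.

    Draws ``n_pairs`` ordered pairs (i, j) i.i.d. with probability
    w(i)w(j); the estimate is the log of the sample mean of
    ``d_t * I(d_s < threshold)``.  Pairwise dissimilarities are computed
    lazily and memoized.  Deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    ids = reference.ids
    w = np.array([per_sequence_weights(reference, weights)[i] for i in ids])
    rng = np.random.default_rng(seed)
    n = len(ids)
    i_draw = rng.choice(n, size=n_pairs, p=w)
    j_draw = rng.choice(n, size=n_pairs, p=w)
    pair_code = i_draw * n + j_draw
    uniq, counts = np.unique(pair_code, return_counts=True)
    cache: dict[tuple[str, str], float] = {}
    values = np.empty(len(uniq))
    for idx, code in enumerate(uniq):
        i, j = divmod(int(code), n)
        if i == j:
            values[idx] = 0.0
            continue
        a, b = ids[i], ids[j]
        if reference.lineages[a] == reference.lineages[b]:
            values[idx] = 0.0
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = sequence_dissimilarity(
                reference.sequences[a], reference.sequences[b], k
            )
        d_s = cache[key]
        values[idx] = (
            taxonomic_distance(reference.lineages[a], reference.lineages[b])
            if d_s < threshold
            else 0.0
        )
    mean = float((values * counts).sum() / n_pairs)
    if mean == 0:
        logger.warning("Monte Carlo sample mean is zero; CI is -inf")
        return ConfusionIndexEstimate(
            value=-math.inf,
            standard_error=math.nan,
            n_pairs=n_pairs,
            threshold=threshold,
            k=k,
            method="monte_carlo",
            seed=seed,
        )
    if n_pairs > 1:
        var = float(
            (counts * (values - mean) ** 2).sum() / (n_pairs - 1)
        )
        se_mean = math.sqrt(var / n_pairs)
    else:
        se_mean = math.nan
    return ConfusionIndexEstimate(
        value=math.log(mean),
        standard_error=se_mean / mean,
        n_pairs=n_pairs,
        threshold=threshold,
        k=k,
        method="monte_carlo",
        seed=seed,
    )
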