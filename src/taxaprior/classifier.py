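"""Multinomial naive Bayes over k-mer counts with taxonomic-weight priors.

The classifier finds the taxon maximising P(T|S) = P(S|T) P(T) / P(S), where
P(S|T) is a multinomial likelihood over the query's k-mer counts and P(T) is
the taxonomic weight (prior) of taxon T.  Under uniform weights the prior
term is a constant and the decision reduces to maximum likelihood.  Classes
are full-depth reference lineages: reference sequences sharing a lineage
pool their k-mer counts, because the priors are per-taxon.

A confidence threshold in [0, 1] truncates the reported lineage: posteriors
of all classes sharing the winner's first L labels are aggregated and the
deepest level whose aggregate meets the threshold is reported.  Setting the
confidence to −1 forces full-depth output (used during weight assembly).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io import ReferenceDB
from .taxonomy import UNCLASSIFIED, Lineage, parse_lineage, truncate_lineage
from .weights import TaxonomicWeights

logger = logging.getLogger(__name__)

__all__ = ["KmerProfile", "NBModel", "kmer_profile", "fit", "predict_posteriors", "classify"]

MODEL_FORMAT_VERSION = 1
DEFAULT_K = 7
DEFAULT_ALPHA = 0.001
DEFAULT_CONFIDENCE = 0.7

_VALID = frozenset("ACGT")

KmerProfile = Counter


def kmer_profile(sequence: str, k: int) -> Counter:
    """Counts of every overlapping window of length ``k`` over {A,C,G,T}.

    Windows containing any other character (N, IUPAC ambiguity codes, ...)
    are skipped; no reverse-complement canonicalization is applied.
    Sequences shorter than ``k`` yield an empty profile.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = sequence.upper()
    counts: Counter[str] = Counter()
    # Positions of invalid characters let us skip whole windows cheaply.
    bad = [i for i, ch in enumerate(seq) if ch not in _VALID]
    if not bad:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
        return counts
    bad_idx = 0
    for i in range(len(seq) - k + 1):
        while bad_idx < len(bad) and bad[bad_idx] < i:
            bad_idx += 1
        if bad_idx < len(bad) and bad[bad_idx] < i + k:
            continue
        counts[seq[i : i + k]] += 1
    return counts


@dataclass
class NBModel:
    """Fitted multinomial naive Bayes state.

    ``log_likelihoods[c, m]`` is the smoothed log conditional probability of
    vocabulary k-mer ``m`` given class ``c``; rows exponentiate to one.
    ``log_priors`` holds log P(T) from the taxonomic weights, or a constant
    zero vector under the uniform assumption (P(T) = 1; a constant shift
    that leaves the posterior argmax unchanged).
    """

    k: int
    alpha: float
    classes: tuple[Lineage, ...]
    vocabulary: tuple[str, ...]
    log_priors: np.ndarray
    log_likelihoods: np.ndarray
    uniform_priors: bool
    vocab_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocab_index:
            self.vocab_index = {m: i for i, m in enumerate(self.vocabulary)}

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_json(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "k": self.k,
            "alpha": self.alpha,
            "uniform_priors": self.uniform_priors,
            "classes": [str(c) for c in self.classes],
            "vocabulary": list(self.vocabulary),
            "log_priors": self.log_priors.tolist(),
            "log_likelihoods": self.log_likelihoods.tolist(),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_json(cls, path) -> "NBModel":
        with open(path) as handle:
            payload = json.load(handle)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model format version {version!r} is not supported "
                f"(expected {MODEL_FORMAT_VERSION})"
            )
        return cls(
            k=int(payload["k"]),
            alpha=float(payload["alpha"]),
            classes=tuple(parse_lineage(c) for c in payload["classes"]),
            vocabulary=tuple(payload["vocabulary"]),
            log_priors=np.asarray(payload["log_priors"], dtype=float),
            log_likelihoods=np.asarray(payload["log_likelihoods"], dtype=float),
            uniform_priors=bool(payload["uniform_priors"]),
        )


def fit(
    reference: ReferenceDB,
    weights: TaxonomicWeights | None = None,
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
) -> NBModel:
    """Train the classifier on a reference database.

    One class per distinct full-depth lineage; each class pools the k-mer
    counts of all its sequences.  Smoothed likelihoods follow
    ``theta(T, m) = (count(T, m) + alpha) / (total(T) + alpha * |vocab|)``.
    ``weights=None`` fits the uniform-weights variant; otherwise every
    reference taxon must appear in ``weights``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    by_taxon = reference.ids_by_taxon()
    classes = tuple(sorted(by_taxon, key=str))
    if weights is not None:
        missing = [t for t in classes if t not in weights]
        if missing:
            raise ValueError(
                f"{len(missing)} reference taxa missing from weights: "
                f"{[str(t) for t in missing[:5]]}"
            )
    class_profiles = []
    vocab: set[str] = set()
    for taxon in classes:
        pooled: Counter[str] = Counter()
        for sid in by_taxon[taxon]:
            pooled.update(kmer_profile(reference.sequences[sid], k))
        class_profiles.append(pooled)
        vocab.update(pooled)
    vocabulary = tuple(sorted(vocab))
    vocab_index = {m: i for i, m in enumerate(vocabulary)}
    counts = np.zeros((len(classes), len(vocabulary)))
    for c, pooled in enumerate(class_profiles):
        for kmer, n in pooled.items():
            counts[c, vocab_index[kmer]] = n
    totals = counts.sum(axis=1, keepdims=True)
    log_likelihoods = np.log(counts + alpha) - np.log(totals + alpha * len(vocabulary))
    if weights is None:
        log_priors = np.zeros(len(classes))
        uniform = True
    else:
        prior = np.array([weights[t] for t in classes])
        log_priors = np.log(prior) - np.log(prior.sum())
        uniform = False
    return NBModel(
        k=k,
        alpha=alpha,
        classes=classes,
        vocabulary=vocabulary,
        log_priors=log_priors,
        log_likelihoods=log_likelihoods,
        uniform_priors=uniform,
        vocab_index=vocab_index,
    )


def predict_posteriors(model: NBModel, sequence: str) -> np.ndarray:
    """Posterior P(T|S) over ``model.classes`` for one query sequence.

    Query k-mers outside the training vocabulary are ignored.  A query with
    an empty usable profile falls back to the (normalized) priors, with a
    logged warning.
    """
    profile = kmer_profile(sequence, model.k)
    idx = []
    mult = []
    for kmer, n in profile.items():
        j = model.vocab_index.get(kmer)
        if j is not None:
            idx.append(j)
            mult.append(n)
    scores = model.log_priors.copy()
    if idx:
        scores = scores + model.log_likelihoods[:, idx] @ np.asarray(mult, dtype=float)
    else:
        logger.warning("query yielded no usable k-mers; returning the priors")
    return np.exp(scores - logsumexp(scores))


def _argmax_class(model: NBModel, posteriors: np.ndarray) -> int:
    top = posteriors.max()
    candidates = np.flatnonzero(posteriors == top)
    # Deterministic tie-break: lexicographically smallest lineage string.
    return min(candidates, key=lambda i: str(model.classes[i]))


def classify(
    model: NBModel, sequence: str, confidence: float = DEFAULT_CONFIDENCE
) -> tuple[Lineage, float]:
    """Classify a query, truncating the lineage by aggregated confidence.

    With ``confidence=-1`` the full-depth winning class and its posterior
    are returned (no truncation).  Otherwise, starting at the winner's full
    depth and moving rootward, posteriors of all classes sharing the first
    L labels are summed and the deepest L whose aggregate meets the
    threshold is reported with that aggregate.  If even the domain fails,
    the depth-0 ``UNCLASSIFIED`` sentinel is returned.
    """
    if confidence != -1 and not (0.0 <= confidence <= 1.0):
        raise ValueError(f"confidence must be in [0, 1] or -1, got {confidence}")
    posteriors = predict_posteriors(model, sequence)
    best = _argmax_class(model, posteriors)
    winner = model.classes[best]
    if confidence == -1:
        return winner, float(posteriors[best])
    aggregate = float(posteriors[best])
    for level in range(winner.depth, 0, -1):
        prefix = winner.labels[:level]
        aggregate = float(
            sum(
                posteriors[i]
                for i, cls in enumerate(model.classes)
                if cls.labels[:level] == prefix
            )
        )
        if aggregate >= confidence:
            return truncate_lineage(winner, level), aggregate
    return UNCLASSIFIED, aggregate
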