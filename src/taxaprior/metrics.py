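"""Level-wise evaluation metrics and their aggregation rules.

Correctness is strict: a read is correct at a level only if the observed
lineage, truncated to that level, is label-identical to the expected lineage
truncated the same way — including depth.  An expected lineage annotated
only to genus therefore requires the observed lineage to stop at exactly the
genus; classifying deeper counts as wrong.  Error rate and F-measure are
aggregated across samples weighted by each sample's total read count;
Bray-Curtis dissimilarity is averaged unweighted but samples with fewer
than 1000 reads are excluded from that average.  Aggregation across folds
is an unweighted mean.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import braycurtis as _braycurtis

from .taxonomy import Lineage, truncate_lineage

logger = logging.getLogger(__name__)

__all__ = [
    "classification_correct",
    "error_rate",
    "aggregate_error",
    "bray_curtis",
    "presence_metrics",
    "EvaluationReport",
    "DEFAULT_MIN_READS_BRAY_CURTIS",
]

DEFAULT_MIN_READS_BRAY_CURTIS = 1000

#: Observed-profile bin for reads the classifier left without any rank.
UNCLASSIFIED_BIN = "unclassified"


def classification_correct(expected: Lineage, observed: Lineage, level: int) -> bool:
    """Exact-truncation correctness of one read at a taxonomic level.

    Both lineages are truncated to ``level``; the call is correct iff the
    truncations are label-identical, which in particular requires equal
    depth: an observed lineage deeper than a shallow expected annotation is
    wrong, and vice versa.  A depth-0 (unclassified) observation is wrong at
    every level.
    """
    if not 1 <= level:
        raise ValueError(f"level must be >= 1, got {level}")
    e = expected.labels[:level]
    o = observed.labels[:level]
    return e == o


def error_rate(
    reads: Iterable[tuple[Lineage, Lineage, int]], level: int
) -> float:
    """Fraction of reads classified incorrectly at ``level``.

    ``reads`` iterates ``(expected, observed, read_count)`` records for one
    sample.
    """
    total = 0
    wrong = 0
    for expected, observed, count in reads:
        total += count
        if not classification_correct(expected, observed, level):
            wrong += count
    if total == 0:
        raise ValueError("sample has no reads")
    return wrong / total


def aggregate_error(samples: Sequence[tuple[float, int]]) -> float:
    """Read-count-weighted mean of per-sample rates.

    ``samples`` holds ``(rate, total_reads)`` pairs; zero-read samples are
    excluded with a warning.
    """
    kept = [(r, n) for r, n in samples if n > 0]
    if len(kept) < len(samples):
        logger.warning("excluded %d empty samples", len(samples) - len(kept))
    if not kept:
        raise ValueError("no non-empty samples to aggregate")
    total = sum(n for _, n in kept)
    return sum(r * n for r, n in kept) / total


def bray_curtis(
    expected_profile: Mapping[object, float], observed_profile: Mapping[object, float]
) -> float:
    """Bray-Curtis dissimilarity sum|x−y| / sum(x+y) on read-count profiles.

    Profiles are compared over the union of their keys, absent taxa count as
    zero.  Two all-zero profiles are an error.
    """
    keys = sorted(set(expected_profile) | set(observed_profile), key=str)
    x = np.array([expected_profile.get(k, 0) for k in keys], dtype=float)
    y = np.array([observed_profile.get(k, 0) for k in keys], dtype=float)
    if x.sum() + y.sum() == 0:
        raise ValueError("cannot compute Bray-Curtis of two all-zero profiles")
    return float(_braycurtis(x, y))


def presence_metrics(
    expected_taxa: set, observed_taxa: set
) -> tuple[float, float, float]:
    """Presence/absence accuracy: (TAR, TDR, F-measure).

    TDR (taxon detection rate) is the fraction of expected taxa that were
    observed (recall on presence); TAR (taxon accuracy rate) is the fraction
    of observed taxa that were expected (precision on presence).  F is their
    harmonic mean, zero when both are zero.
    """
    if not expected_taxa:
        raise ValueError("expected taxon set is empty")
    inter = len(expected_taxa & observed_taxa)
    tdr = inter / len(expected_taxa)
    tar = inter / len(observed_taxa) if observed_taxa else 0.0
    f = 2 * tar * tdr / (tar + tdr) if (tar + tdr) > 0 else 0.0
    return tar, tdr, f


def level_profiles(
    reads: Iterable[tuple[Lineage, Lineage, int]], level: int
) -> tuple[dict[str, int], dict[str, int]]:
    """Expected and observed taxon-count profiles of a sample at a level.

    Keys are truncated-lineage strings; unclassified reads contribute to a
    dedicated ``unclassified`` bin of the observed profile.
    """
    expected_profile: dict[str, int] = {}
    observed_profile: dict[str, int] = {}
    for expected, observed, count in reads:
        ekey = str(truncate_lineage(expected, level))
        expected_profile[ekey] = expected_profile.get(ekey, 0) + count
        if observed.depth == 0:
            okey = UNCLASSIFIED_BIN
        else:
            okey = str(truncate_lineage(observed, level))
        observed_profile[okey] = observed_profile.get(okey, 0) + count
    return expected_profile, observed_profile


def sample_metrics(
    reads: Sequence[tuple[Lineage, Lineage, int]], level: int
) -> dict[str, float]:
    """All per-sample metrics of one simulated sample at one level."""
    expected_profile, observed_profile = level_profiles(reads, level)
    observed_taxa = set(observed_profile) - {UNCLASSIFIED_BIN}
    tar, tdr, f = presence_metrics(set(expected_profile), observed_taxa)
    return {
        "error_rate": error_rate(reads, level),
        "bray_curtis": bray_curtis(expected_profile, observed_profile),
        "tar": tar,
        "tdr": tdr,
        "f_measure": f,
        "total_reads": sum(c for _, _, c in reads),
    }


_WEIGHTED_METRICS = ("error_rate", "f_measure", "tar", "tdr")


@dataclass
class EvaluationReport:
    """Per-sample metric records from a cross-validation run, plus provenance.

    Every aggregated number is reproducible from the stored records; the
    aggregation rules (read-count weighting, the <1000-read Bray-Curtis
    filter, unweighted fold means) live in :meth:`per_fold` and
    :meth:`summary` only.
    """

    records: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    min_reads_bray_curtis: int = DEFAULT_MIN_READS_BRAY_CURTIS

    def add(self, **record) -> None:
        self.records.append(record)

    @property
    def folds(self) -> list[int]:
        return sorted({r["fold"] for r in self.records})

    @property
    def levels(self) -> list[int]:
        return sorted({r["level"] for r in self.records})

    def per_fold(self, level: int, metric: str) -> dict[int, float]:
        """Per-fold aggregate of one metric at one taxonomic level."""
        out: dict[int, float] = {}
        for fold in self.folds:
            rows = [r for r in self.records if r["fold"] == fold and r["level"] == level]
            if not rows:
                continue
            if metric in _WEIGHTED_METRICS:
                out[fold] = aggregate_error(
                    [(r[metric], r["total_reads"]) for r in rows]
                )
            elif metric == "bray_curtis":
                kept = [r for r in rows if r["total_reads"] >= self.min_reads_bray_curtis]
                if not kept:
                    logger.warning(
                        "fold %d: no samples pass the %d-read Bray-Curtis filter",
                        fold,
                        self.min_reads_bray_curtis,
                    )
                    continue
                out[fold] = float(np.mean([r[metric] for r in kept]))
            else:
                raise KeyError(f"unknown metric {metric!r}")
        return out

    def summary(self, level: int, metric: str) -> float:
        """Unweighted mean of the per-fold aggregates."""
        per_fold = self.per_fold(level, metric)
        if not per_fold:
            raise ValueError(f"no records for level {level}, metric {metric}")
        return float(np.mean(list(per_fold.values())))

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "provenance": self.provenance,
            "min_reads_bray_curtis": self.min_reads_bray_curtis,
            "records": self.records,
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            records=payload["records"],
            provenance=payload["provenance"],
            min_reads_bray_curtis=payload["min_reads_bray_curtis"],
        )

    def to_tsv(self, path) -> None:
        """Long-format per-sample TSV: sample, fold, level, metric, value."""
        with open(path, "w") as handle:
            handle.write("sample_id\tfold\tlevel\tmetric\tvalue\n")
            for r in self.records:
                for metric in (*_WEIGHTED_METRICS, "bray_curtis", "total_reads"):
                    handle.write(
                        f"{r['sample_id']}\t{r['fold']}\t{r['level']}\t"
                        f"{metric}\t{r[metric]}\n"
                    )
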