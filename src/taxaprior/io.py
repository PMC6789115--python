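"""Readers and writers for the on-disk artifacts the toolkit touches.

Formats are deliberately plain-text and diff-able: FASTA for reference
sequences, two-column TSV for taxonomy annotations, TSV for feature tables
(read counts), and TSV or JSON for taxonomic weights.  All readers reject
malformed input with a descriptive error rather than silently coercing.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .taxonomy import Lineage, parse_lineage, sort_lineages

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDB",
    "FeatureTable",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
    "read_reference",
    "read_feature_table",
    "read_weights",
    "write_weights",
]

_SUM_TOL = 1e-8


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class ReferenceDB:
    """Reference sequences keyed by identifier, each with a ranked lineage."""

    sequences: dict[str, str]
    lineages: dict[str, Lineage]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference database must contain at least one record")
        if set(self.sequences) != set(self.lineages):
            raise ValueError("every reference record needs both a sequence and a lineage")

    @property
    def ids(self) -> list[str]:
        return sorted(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def taxa(self) -> set[Lineage]:
        return set(self.lineages.values())

    def ids_by_taxon(self) -> dict[Lineage, list[str]]:
        """Sequence ids grouped by full-depth lineage, ids sorted."""
        groups: dict[Lineage, list[str]] = {}
        for sid in self.ids:
            groups.setdefault(self.lineages[sid], []).append(sid)
        return groups

    def subset(self, ids: Iterable[str]) -> "ReferenceDB":
        ids = list(ids)
        missing = [i for i in ids if i not in self.sequences]
        if missing:
            raise KeyError(f"unknown sequence ids: {missing[:5]}")
        return ReferenceDB(
            sequences={i: self.sequences[i] for i in ids},
            lineages={i: self.lineages[i] for i in ids},
        )


class FeatureTable:
    """Taxa x samples table of non-negative integer read counts.

    Row labels are lineage strings (full or truncated), column labels sample
    ids; column sums are each sample's read depth.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("feature table row/column labels must be unique")
        try:
            counts = counts.astype("int64")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"feature table counts must be integers: {exc}") from exc
        if (counts.to_numpy() < 0).any():
            raise ValueError("feature table counts must be non-negative")
        self.counts = counts

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def total(self, sample_id: str) -> int:
        return int(self.counts[sample_id].sum())

    def sample_counts(self, sample_id: str) -> dict[Lineage, int]:
        """Non-zero taxon counts of one sample, keyed by parsed lineage."""
        col = self.counts[sample_id]
        return {
            parse_lineage(taxon): int(count)
            for taxon, count in col.items()
            if count > 0
        }

    @classmethod
    def from_tsv(cls, path, orientation: str = "taxa-as-rows") -> "FeatureTable":
        if orientation not in ("taxa-as-rows", "samples-as-rows"):
            raise ValueError(f"unknown orientation: {orientation!r}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "samples-as-rows":
            df = df.T
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="taxon")

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)


def read_fasta(path) -> dict[str, str]:
    """FASTA records as ``{id: uppercased sequence}``.

    Ids are the first whitespace token of each header.  Duplicate ids and
    empty files are errors.
    """
    records: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate sequence id in {path}: {rec.id}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as handle:
        for sid in sorted(sequences):
            handle.write(f">{sid}\n{sequences[sid]}\n")


def read_taxonomy(path, skip_header: bool = False) -> dict[str, Lineage]:
    """Two-column TSV (sequence_id TAB semicolon-delimited lineage)."""
    taxonomy: dict[str, Lineage] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            sid = parts[0].strip()
            if sid in taxonomy:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {sid}")
            taxonomy[sid] = parse_lineage(parts[1])
    if not taxonomy:
        raise ValueError(f"no taxonomy rows found in {path}")
    return taxonomy


def write_taxonomy(lineages: Mapping[str, Lineage], path) -> None:
    with open(path, "w") as handle:
        for sid in sorted(lineages):
            handle.write(f"{sid}\t{lineages[sid]}\n")


def read_reference(fasta_path, taxonomy_path, skip_header: bool = False) -> ReferenceDB:
    """Inner join of a FASTA file and a taxonomy TSV on sequence id.

    Ids present in only one file are dropped with a logged warning; an empty
    join is an error.
    """
    sequences = read_fasta(fasta_path)
    taxonomy = read_taxonomy(taxonomy_path, skip_header=skip_header)
    shared = sorted(set(sequences) & set(taxonomy))
    only_seq = set(sequences) - set(taxonomy)
    only_tax = set(taxonomy) - set(sequences)
    if only_seq:
        logger.warning("%d sequence ids lack taxonomy and were dropped", len(only_seq))
    if only_tax:
        logger.warning("%d taxonomy ids lack sequences and were dropped", len(only_tax))
    if not shared:
        raise ValueError("sequence and taxonomy files share no ids")
    return ReferenceDB(
        sequences={i: sequences[i] for i in shared},
        lineages={i: taxonomy[i] for i in shared},
    )


def read_feature_table(path, orientation: str = "taxa-as-rows") -> FeatureTable:
    return FeatureTable.from_tsv(path, orientation=orientation)


def write_weights(weights, path, format: str | None = None) -> None:
    """Serialize taxonomic weights losslessly as TSV or JSON.

    TSV is two columns (lineage TAB probability); JSON is an object with a
    ``weights`` mapping and the ``unobserved_offset`` used at assembly.
    Format inferred from the filename when not given.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    taxa = sort_lineages(weights.keys())
    if format == "tsv":
        with open(path, "w") as handle:
            for taxon in taxa:
                handle.write(f"{taxon}\t{weights[taxon]!r}\n")
    elif format == "json":
        payload = {
            "unobserved_offset": weights.unobserved_offset,
            "weights": {str(t): weights[t] for t in taxa},
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)
    else:
        raise ValueError(f"unknown weights format: {format!r}")


def read_weights(path, format: str | None = None):
    """Inverse of :func:`write_weights`; validates the probabilities sum to 1."""
    from .weights import TaxonomicWeights  # local import to avoid a cycle

    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    offset = 0.0
    mapping: dict[Lineage, float] = {}
    if format == "tsv":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two columns")
                mapping[parse_lineage(parts[0])] = float(parts[1])
    elif format == "json":
        with open(path) as handle:
            payload = json.load(handle)
        offset = float(payload.get("unobserved_offset", 0.0))
        mapping = {parse_lineage(t): float(w) for t, w in payload["weights"].items()}
    else:
        raise ValueError(f"unknown weights format: {format!r}")
    total = sum(mapping.values())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(
            f"weights in {path} sum to {total!r}, expected 1 within {_SUM_TOL}"
        )
    return TaxonomicWeights(mapping, unobserved_offset=offset)
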