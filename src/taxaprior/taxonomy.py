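"""Ranked taxonomic lineages and the rank-depth distance between them.

A lineage is an ordered path of rank labels from domain down to (at most)
species, written Greengenes-style as ``k__Bacteria; p__Firmicutes; ...``.
Reference taxonomies are frequently annotated to fewer than the full seven
ranks, so a :class:`Lineage` carries only the labels it has and every
operation treats missing tail ranks explicitly.  Rank-prefix markers such as
``k__`` are part of the label string; no semantic parsing of them is
attempted, so lineage equality is exact label-by-label comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "Lineage",
    "UNCLASSIFIED",
    "parse_lineage",
    "taxonomic_distance",
    "truncate_lineage",
    "TOTAL_RANKS",
]

#: Default number of ranks (domain, phylum, class, order, family, genus, species).
TOTAL_RANKS = 7

# A label that is only a rank-prefix marker, e.g. "s__" or "g__", denotes an
# unannotated rank and is dropped from the tail at parse time.
_EMPTY_MARKER = re.compile(r"^[A-Za-z0-9]{0,2}__$")


@dataclass(frozen=True, order=True)
class Lineage:
    """An ordered tuple of rank labels, index 0 = domain.

    The empty lineage (depth 0) is reserved for the :data:`UNCLASSIFIED`
    sentinel returned by the classifier when no rank meets the confidence
    threshold; it never results from parsing.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for label in self.labels:
            if not label or not label.strip():
                raise ValueError("lineage labels must be non-empty: %r" % (self.labels,))

    @property
    def depth(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return "; ".join(self.labels)

    def startswith(self, prefix: tuple[str, ...]) -> bool:
        return self.labels[: len(prefix)] == prefix


#: Sentinel for reads that could not be classified at any rank.
UNCLASSIFIED = Lineage(())


def parse_lineage(
    text: str, delimiter: str = ";", strip_empty_tail: bool = True
) -> Lineage:
    """Parse a delimited lineage string into a :class:`Lineage`.

    Surrounding whitespace of each label is trimmed.  With
    ``strip_empty_tail`` (the default), trailing labels that are empty or
    bare rank markers (``s__``) are dropped, so
    ``"k__Bacteria; p__; c__"`` parses to a depth-1 lineage.

    Raises ``ValueError`` if nothing remains after trimming.
    """
    labels = [part.strip() for part in text.split(delimiter)]
    if strip_empty_tail:
        while labels and (not labels[-1] or _EMPTY_MARKER.match(labels[-1])):
            labels.pop()
    else:
        while labels and not labels[-1]:
            labels.pop()
    if not labels:
        raise ValueError(f"lineage string is empty after parsing: {text!r}")
    return Lineage(tuple(labels))


def taxonomic_distance(a: Lineage, b: Lineage, total_ranks: int = TOTAL_RANKS) -> int:
    """Rank depth of the most recent common ancestor, measured from species.

    Zero for identical full-depth lineages, one for two species of the same
    genus, and ``total_ranks`` for lineages differing already at the domain.
    Computed as ``total_ranks`` minus the length of the longest common label
    prefix; labels beyond the common prefix (including missing tail ranks)
    all count towards the distance, which keeps the formula consistent for
    tail-truncated annotations.
    """
    common = 0
    for la, lb in zip(a.labels, b.labels):
        if la != lb:
            break
        common += 1
    return max(total_ranks - common, 0)


def truncate_lineage(lineage: Lineage, level: int) -> Lineage:
    """First ``min(level, depth)`` labels of ``lineage``.

    ``level`` counts ranks from the domain (1 = domain only).
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    if level >= lineage.depth:
        return lineage
    return Lineage(lineage.labels[:level])


def serialize_lineage(lineage: Lineage, delimiter: str = "; ") -> str:
    """Join labels with ``delimiter`` (round-trips with :func:`parse_lineage`)."""
    return delimiter.join(lineage.labels)


def common_prefix_depth(a: Lineage, b: Lineage) -> int:
    """Length of the longest common label prefix of two lineages."""
    depth = 0
    for la, lb in zip(a.labels, b.labels):
        if la != lb:
            break
        depth += 1
    return depth


def sort_lineages(lineages: Iterable[Lineage]) -> list[Lineage]:
    """Deterministic (lexicographic by string form) ordering of lineages."""
    return sorted(lineages, key=str)
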