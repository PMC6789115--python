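"""Synthetic reference databases and habitat communities.

The generator emulates the statistical structure that habitat-aware priors
exploit in real amplicon surveys: a seven-rank reference taxonomy with a
variable number of sequences per species (including species with fewer than
five, which exercises the stratum-merging machinery), sister species whose
marker sequences are nearly identical (so likelihoods alone cannot separate
them), and habitat-specific, highly skewed abundance distributions over the
reference species.

Sequences evolve down the taxonomy tree by i.i.d. substitutions, with
per-rank substitution rates decreasing towards the leaves so that
species-level siblings are the most similar.  Tree topology and lineage
labels are a deterministic function of the spec; only sequences and
abundances consume randomness.  All randomness flows from the spec's single
seed through numbered ``numpy`` seed-sequence streams, so any sub-artifact
is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .confusion import sequence_dissimilarity
from .io import FeatureTable, ReferenceDB
from .taxonomy import Lineage
from .weights import TaxonomicWeights

__all__ = [
    "SyntheticSpec",
    "species_lineages",
    "make_reference",
    "make_habitats",
    "make_samples",
    "EMPO3_SAMPLE_COUNTS",
]

#: Sample counts per EMPO 3 habitat type in the large public 16S survey
#: compilation that motivates this package's study designs.  The smallest
#: habitat, Surface (saline) with 152 samples, sets the scale at which
#: bespoke weights are still worth assembling: a 4/5 cross-validation
#: training split of it leaves 122 samples.
EMPO3_SAMPLE_COUNTS: dict[str, int] = {
    "Animal corpus": 1158,
    "Animal distal gut": 5632,
    "Animal proximal gut": 903,
    "Animal secretion": 974,
    "Animal surface": 1839,
    "Plant corpus": 543,
    "Plant rhizosphere": 328,
    "Sediment (non-saline)": 188,
    "Surface (non-saline)": 1383,
    "Soil (non-saline)": 2802,
    "Water (non-saline)": 4769,
    "Sediment (saline)": 414,
    "Surface (saline)": 152,
    "Water (saline)": 428,
}

_RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")
_BASES = np.array(list("ACGT"))

# Stream labels appended to the spec seed for independent randomness.
_STREAM_REFERENCE = 0
_STREAM_HABITATS = 1
_STREAM_SAMPLES = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``branching`` gives the number of children per node at each of the
    seven ranks; its product is the species count.  The default tree holds
    32 species in 16 genera of two sister species each.
    ``substitution_rates`` are the
    expected per-site divergence a child accrues from its parent at each
    rank; the species-rank default of 0.0 means sister species share their
    ancestral marker sequence and differ only by within-species variation —
    the saturated-marker regime (common among closely related species in
    99%-identity reference sets) in which only the habitat priors can
    resolve the classification.  ``habitat_concentration`` is the
    symmetric Dirichlet concentration of habitat compositions; 0.1 yields
    the strongly skewed communities typical of real habitats.
    """

    branching: tuple[int, ...] = (1, 1, 2, 2, 2, 2, 2)
    sequence_length: int = 250
    substitution_rates: tuple[float, ...] = (0.30, 0.20, 0.12, 0.08, 0.05, 0.03, 0.0)
    within_species_rate: float = 0.0001
    sequences_per_species: tuple[int, int] = (2, 7)
    habitat_concentration: float = 0.1
    n_samples: int = 40
    reads_per_sample: int = 2000
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branching) != 7 or any(b < 1 for b in self.branching):
            raise ValueError("branching must give seven factors >= 1")
        if len(self.substitution_rates) != 7:
            raise ValueError("need one substitution rate per rank")
        if any(
            a < b
            for a, b in zip(self.substitution_rates, self.substitution_rates[1:])
        ):
            raise ValueError("substitution rates must be non-increasing with depth")
        if not all(0.0 <= r <= 1.0 for r in self.substitution_rates):
            raise ValueError("substitution rates must lie in [0, 1]")
        lo, hi = self.sequences_per_species
        if not 1 <= lo <= hi:
            raise ValueError("sequences_per_species must be a valid (lo, hi) range")

    @property
    def n_species(self) -> int:
        return math.prod(self.branching)


def species_lineages(spec: SyntheticSpec) -> list[Lineage]:
    """The full-depth lineages of the spec's taxonomy tree (deterministic)."""
    paths: list[tuple[str, ...]] = [()]
    for rank, b in enumerate(spec.branching):
        prefix = _RANK_PREFIXES[rank]
        paths = [
            path + (f"{prefix}__T{''.join(c[-1] for c in path)}{i + 1}",)
            for path in paths
            for i in range(b)
        ]
    return [Lineage(p) for p in paths]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    n_sub = rng.binomial(len(seq), rate)
    if n_sub == 0:
        return seq.copy()
    out = seq.copy()
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    for pos in positions:
        choices = _BASES[_BASES != out[pos]]
        out[pos] = rng.choice(choices)
    return out


def _generate(rng: np.random.Generator, spec: SyntheticSpec) -> ReferenceDB:
    root = rng.choice(_BASES, size=spec.sequence_length)
    nodes = [((), root)]
    for rank, b in enumerate(spec.branching):
        prefix = _RANK_PREFIXES[rank]
        rate = spec.substitution_rates[rank]
        nodes = [
            (
                path + (f"{prefix}__T{''.join(c[-1] for c in path)}{i + 1}",),
                _mutate(rng, seq, rate),
            )
            for path, seq in nodes
            for i in range(b)
        ]
    lo, hi = spec.sequences_per_species
    sequences: dict[str, str] = {}
    lineages: dict[str, Lineage] = {}
    for path, seq in nodes:
        lineage = Lineage(path)
        code = path[-1].split("__", 1)[1]
        n_seqs = int(rng.integers(lo, hi + 1))
        for j in range(n_seqs):
            sid = f"{code}.{j + 1:02d}"
            sequences[sid] = "".join(_mutate(rng, seq, spec.within_species_rate))
            lineages[sid] = lineage
    return ReferenceDB(sequences=sequences, lineages=lineages)


def _satisfies(db: ReferenceDB, spec: SyntheticSpec, min_count: int = 5) -> bool:
    by_taxon = db.ids_by_taxon()
    sizes = [len(ids) for ids in by_taxon.values()]
    if not any(s >= min_count for s in sizes):
        return False
    if len(sizes) > 1 and not any(s < min_count for s in sizes):
        return False
    # One representative sequence per species for the pair guarantees.
    reps = {t: db.sequences[ids[0]] for t, ids in by_taxon.items()}
    taxa = sorted(reps, key=str)
    confusable = False
    separated = False
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            d = sequence_dissimilarity(reps[a], reps[b])
            if d >= 0.25:
                separated = True
            elif a.labels[:6] == b.labels[:6]:
                confusable = True  # near-identical sister species
            if confusable and separated:
                return True
    return confusable and separated


def make_reference(spec: SyntheticSpec, max_retries: int = 50) -> ReferenceDB:
    """Generate a reference database satisfying the fixture guarantees.

    Guarantees (rejection-resampled until met): at least one sister-species
    pair with k-mer Bray-Curtis dissimilarity below 0.25, at least one
    well-separated pair at or above 0.25, at least one species with five or
    more sequences, and (when more than one species exists) at least one
    with fewer.  Deterministic given the spec seed.
    """
    streams = np.random.SeedSequence(
        (spec.seed, _STREAM_REFERENCE)
    ).spawn(max_retries)
    for stream in streams:
        db = _generate(np.random.default_rng(stream), spec)
        if _satisfies(db, spec):
            return db
    raise RuntimeError(
        f"could not satisfy fixture guarantees in {max_retries} attempts; "
        "adjust the spec (rates or sequence counts)"
    )


def make_habitats(spec: SyntheticSpec, n_habitats: int) -> list[TaxonomicWeights]:
    """Ground-truth habitat compositions over the spec's species.

    Each habitat is an independent symmetric-Dirichlet draw at the spec's
    concentration; low concentration gives the skewed compositions real
    communities show.
    """
    if n_habitats < 1:
        raise ValueError("n_habitats must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence((spec.seed, _STREAM_HABITATS))
    )
    taxa = species_lineages(spec)
    habitats = []
    for _ in range(n_habitats):
        composition = rng.dirichlet(
            np.full(len(taxa), spec.habitat_concentration)
        )
        # Dirichlet draws can underflow to exact zero at low concentration;
        # keep weights strictly positive.
        composition = np.clip(composition, 1e-12, None)
        composition = composition / composition.sum()
        habitats.append(
            TaxonomicWeights(dict(zip(taxa, map(float, composition))))
        )
    return habitats


def make_samples(
    habitat: TaxonomicWeights,
    reference: ReferenceDB,
    n_samples: int,
    depth: int,
    read_error_rate: float = 0.0,
    seed: int = 0,
    with_reads: bool = False,
) -> tuple[FeatureTable, list[dict[str, int]] | None]:
    """Draw per-sample taxon counts (and optionally reads) from a habitat.

    Taxon counts are multinomial at the given read depth with the habitat's
    composition, so column sums equal ``depth``.  With ``with_reads``, each
    read is a copy of a uniformly chosen reference sequence of its taxon
    with i.i.d. substitutions at ``read_error_rate``; the result is one
    ``{read string: count}`` mapping per sample.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    missing = habitat.taxa - reference.taxa()
    if missing:
        raise ValueError(
            f"habitat names {len(missing)} taxa absent from the reference"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_SAMPLES)))
    taxa = sorted(habitat, key=str)
    p = np.array([habitat[t] for t in taxa])
    counts = rng.multinomial(depth, p, size=n_samples).T  # taxa x samples
    sample_ids = [f"sample{i + 1:03d}" for i in range(n_samples)]
    table = FeatureTable(
        pd.DataFrame(counts, index=[str(t) for t in taxa], columns=sample_ids)
    )
    if not with_reads:
        return table, None
    by_taxon = reference.ids_by_taxon()
    reads: list[dict[str, int]] = []
    for s in range(n_samples):
        sample_reads: dict[str, int] = {}
        for ti, taxon in enumerate(taxa):
            c = int(counts[ti, s])
            if c == 0:
                continue
            ids = by_taxon[taxon]
            per_seq = rng.multinomial(c, np.full(len(ids), 1.0 / len(ids)))
            for sid, n in zip(ids, per_seq):
                if n == 0:
                    continue
                base = reference.sequences[sid]
                if read_error_rate > 0:
                    for _ in range(n):
                        read = "".join(
                            _mutate(rng, np.array(list(base)), read_error_rate)
                        )
                        sample_reads[read] = sample_reads.get(read, 0) + 1
                else:
                    sample_reads[base] = sample_reads.get(base, 0) + n
        reads.append(sample_reads)
    return table, reads
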