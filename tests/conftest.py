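"""Shared fixtures: small hand-built and synthetic references."""

from __future__ import annotations

import pytest

from taxaprior.io import ReferenceDB
from taxaprior.synthetic import SyntheticSpec, make_reference
from taxaprior.taxonomy import parse_lineage


def lineage(text: str):
    return parse_lineage(text)


@pytest.fixture
def toy_reference() -> ReferenceDB:
    """Two genera; one genus holds two sister species with identical sequences."""
    records = {
        # genus gA: sisters s1/s2 share the same sequence
        "a1": ("ACGTACGTACGTACGTACGT", "k__K; p__P; c__C; o__O; f__F; g__gA; s__s1"),
        "a2": ("ACGTACGTACGTACGTACGT", "k__K; p__P; c__C; o__O; f__F; g__gA; s__s2"),
        # genus gB: well separated
        "b1": ("TTTTGGGGCCCCAAAATTTT", "k__K; p__P; c__C; o__O; f__F; g__gB; s__s3"),
    }
    return ReferenceDB(
        sequences={k: v[0] for k, v in records.items()},
        lineages={k: parse_lineage(v[1]) for k, v in records.items()},
    )


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """An 8-species synthetic study kept small for fast unit tests."""
    return SyntheticSpec(
        branching=(1, 1, 1, 1, 2, 2, 2),
        n_samples=10,
        reads_per_sample=300,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_spec) -> ReferenceDB:
    return make_reference(small_spec)
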