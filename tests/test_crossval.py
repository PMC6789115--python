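"""Strata, folds, remapping, whole-count simulation, and the CV benchmark."""

import pytest
from hypothesis import given, settings, strategies as st

from taxaprior.crossval import (
    StrataPlan,
    build_strata,
    cross_habitat_pairs,
    remap_missing,
    run_cv,
    simulate_sample,
    split_folds,
)
from taxaprior.io import ReferenceDB
from taxaprior.synthetic import SyntheticSpec, make_habitats, make_reference, make_samples
from taxaprior.taxonomy import parse_lineage


def _seq(base, n_sub=0):
    seq = list(base)
    for i in range(n_sub):
        seq[i] = "T" if seq[i] != "T" else "G"
    return "".join(seq)


def _merge_db():
    """One 5-sequence large taxon, one 4-sequence taxon, one 1-sequence taxon."""
    big = "ACGTACGTACGTACGTACGTACGT"
    other = "GGTTCCAAGGTTCCAAGGTTCCAA"
    seqs, lins = {}, {}
    for i in range(5):
        seqs[f"L{i}"] = big
        lins[f"L{i}"] = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__G; s__big")
    for i in range(4):
        seqs[f"M{i}"] = other
        lins[f"M{i}"] = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__H; s__mid")
    seqs["S0"] = _seq(big, 1)
    lins["S0"] = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__G; s__small")
    for i in range(5):
        seqs[f"N{i}"] = other
        lins[f"N{i}"] = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__H; s__other")
    return ReferenceDB(sequences=seqs, lineages=lins)


def test_build_strata_thresholds_and_voting():
    db = _merge_db()
    plan = build_strata(db, min_count=5, k=4)
    big = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__G; s__big")
    other = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__H; s__other")
    small = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__G; s__small")
    mid = parse_lineage("k__K; p__P; c__C; o__O; f__F; g__H; s__mid")
    assert plan.large_taxa == {big, other}
    # the small taxon's near-identical sequence votes it into the big stratum
    assert plan.small_to_large[small] == big
    assert plan.small_to_large[mid] == other
    assert plan.stratum_of["S0"] == big
    # every sequence assigned exactly one stratum
    assert set(plan.stratum_of) == set(db.ids)


def test_build_strata_requires_a_large_taxon():
    db = ReferenceDB(
        sequences={"a": "ACGTACGT", "b": "CCCCAAAA"},
        lineages={
            "a": parse_lineage("k__K; s__A"),
            "b": parse_lineage("k__K; s__B"),
        },
    )
    with pytest.raises(ValueError, match="min_count"):
        build_strata(db, min_count=5, k=4)


def test_split_folds_balanced_and_deterministic():
    db = _merge_db()
    plan = build_strata(db, min_count=5, k=4)
    samples = [f"s{i}" for i in range(152)]
    folds = split_folds(plan, samples, n_folds=5, seed=3)
    # per-stratum balance within 1 on the reference side
    for stratum in plan.large_taxa:
        ids = [i for i, s in plan.stratum_of.items() if s == stratum]
        per_fold = [sum(folds.ref_fold_of[i] == f for i in ids) for f in range(5)]
        assert max(per_fold) - min(per_fold) <= 1
    # 152 samples in 5 folds: the largest training partition holds 122
    train_sizes = [len(folds.sample_ids(f, train=True)) for f in range(5)]
    assert max(train_sizes) == 122
    assert split_folds(plan, samples, n_folds=5, seed=3) == folds
    assert split_folds(plan, samples, n_folds=5, seed=4) != folds


def test_split_folds_rejects_small_strata():
    db = _merge_db()
    plan = build_strata(db, min_count=5, k=4)
    with pytest.raises(ValueError):
        split_folds(plan, ["s1", "s2"], n_folds=5, seed=0)
    with pytest.raises(ValueError):
        split_folds(plan, [f"s{i}" for i in range(9)], n_folds=7, seed=0)


def test_remap_missing_rules():
    big = parse_lineage("k__K; s__big")
    alt = parse_lineage("k__K; s__alt")
    small = parse_lineage("k__K; s__small")
    plan = StrataPlan(
        stratum_of={},
        large_taxa=frozenset({big, alt}),
        small_to_large={small: big},
        vote_tallies={small: {big: 0.9, alt: 0.4}},
    )
    available = {big, alt}
    assert remap_missing(big, available, plan) == big
    assert remap_missing(small, available, plan) == big
    # vote target unavailable: recount over what remains
    assert remap_missing(small, {alt}, plan) == alt
    # unknown taxon: nearest by rank distance, ties lexicographic
    stranger = parse_lineage("k__K; s__big2")
    assert remap_missing(stranger, available, plan) == alt  # d=1 both, lex smallest


@pytest.mark.parametrize(
    "c, n_seqs, expected",
    [
        (5, 2, [3, 2]),
        (4, 2, [2, 2]),
        (1, 3, [1]),
        (7, 3, [3, 2, 2]),
    ],
)
def test_simulate_sample_even_whole_counts(c, n_seqs, expected):
    taxon = parse_lineage("k__K; s__A")
    seqs = [f"id{i}" for i in range(n_seqs)]
    sim = simulate_sample({taxon: c}, {taxon: seqs})
    assert sorted(sim.draws.values(), reverse=True) == expected
    assert sum(sim.draws.values()) == c
    # extras go to lexicographically first ids
    if c >= n_seqs:
        assert sim.draws["id0"] == max(sim.draws.values())


def test_simulate_sample_missing_taxon_is_error():
    taxon = parse_lineage("k__K; s__A")
    with pytest.raises(ValueError, match="remap"):
        simulate_sample({taxon: 3}, {})


@settings(derandomize=True, max_examples=40)
@given(
    counts=st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=5),
    m=st.integers(min_value=1, max_value=7),
)
def test_simulate_sample_conserves_totals(counts, m):
    expected = {
        parse_lineage(f"k__K; s__t{i}"): c for i, c in enumerate(counts)
    }
    by_taxon = {t: [f"{t}.{j}" for j in range(m)] for t in expected}
    sim = simulate_sample(expected, by_taxon)
    assert sum(sim.draws.values()) == sum(counts)
    assert all(v >= 1 for v in sim.draws.values())


@pytest.fixture(scope="module")
def cv_setup():
    spec = SyntheticSpec(
        branching=(1, 1, 1, 1, 2, 2, 2),
        n_samples=10,
        reads_per_sample=300,
        seed=11,
    )
    ref = make_reference(spec)
    habitat = make_habitats(spec, 1)[0]
    table, _ = make_samples(habitat, ref, spec.n_samples, spec.reads_per_sample, seed=11)
    return ref, table


def test_run_cv_structure_and_determinism(cv_setup):
    ref, table = cv_setup
    report = run_cv(ref, table, "bespoke", seed=5, levels=(6, 7))
    # one record per (test sample, level)
    assert len(report.records) == len(table.samples) * 2
    assert report.provenance["weighting"] == "bespoke"
    again = run_cv(ref, table, "bespoke", seed=5, levels=(6, 7))
    assert again.records == report.records
    assert 0.0 <= report.summary(7, "error_rate") <= 1.0


def test_run_cv_fold_partitions_are_exact(cv_setup):
    ref, table = cv_setup
    plan = build_strata(ref)
    folds = split_folds(plan, table.samples, n_folds=5, seed=5)
    all_test_refs = [i for f in range(5) for i in folds.ref_ids(f, train=False)]
    assert sorted(all_test_refs) == ref.ids
    all_test_samples = [s for f in range(5) for s in folds.sample_ids(f, train=False)]
    assert sorted(all_test_samples) == sorted(table.samples)


def test_cross_habitat_pairs_count():
    pairs = cross_habitat_pairs([f"h{i}" for i in range(14)])
    assert len(pairs) == 182
    assert all(a != b for a, b in pairs)
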