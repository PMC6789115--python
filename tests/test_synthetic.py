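"""The synthetic-study generator: determinism, guarantees, distributions."""

import numpy as np
import pytest

from taxaprior.confusion import sequence_dissimilarity
from taxaprior.synthetic import (
    SyntheticSpec,
    make_habitats,
    make_reference,
    make_samples,
    species_lineages,
)
from taxaprior.weights import assemble_weights


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(branching=(1, 1, 1, 2, 2, 2))  # six ranks
    with pytest.raises(ValueError):
        SyntheticSpec(substitution_rates=(0.1, 0.2, 0.1, 0.1, 0.1, 0.1, 0.0))
    with pytest.raises(ValueError):
        SyntheticSpec(sequences_per_species=(5, 2))


def test_species_count_and_lineage_depth(small_spec):
    taxa = species_lineages(small_spec)
    assert len(taxa) == small_spec.n_species == 8
    assert all(t.depth == 7 for t in taxa)
    assert len(set(taxa)) == 8


def test_reference_counts_and_determinism(small_spec, small_reference):
    assert small_reference.taxa() == set(species_lineages(small_spec))
    lo, hi = small_spec.sequences_per_species
    for ids in small_reference.ids_by_taxon().values():
        assert lo <= len(ids) <= hi
    again = make_reference(small_spec)
    assert again.sequences == small_reference.sequences
    assert again.lineages == small_reference.lineages


def test_reference_confusable_and_separated_guarantees(small_reference):
    by_taxon = small_reference.ids_by_taxon()
    reps = {t: small_reference.sequences[ids[0]] for t, ids in by_taxon.items()}
    taxa = sorted(reps, key=str)
    pairs = [
        (a, b, sequence_dissimilarity(reps[a], reps[b]))
        for i, a in enumerate(taxa)
        for b in taxa[i + 1 :]
    ]
    assert any(d < 0.25 and a.labels[:6] == b.labels[:6] for a, b, d in pairs)
    assert any(d >= 0.25 for _, _, d in pairs)
    sizes = [len(ids) for ids in by_taxon.values()]
    assert any(s >= 5 for s in sizes) and any(s < 5 for s in sizes)


def test_habitats_sum_to_one_and_skew(small_spec):
    habitats = make_habitats(small_spec, 50)
    maxes = []
    for h in habitats:
        assert sum(h.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(v > 0 for v in h.values())
        maxes.append(max(h.values()))
    # concentration 0.1 is strongly skewed: the dominant species typically
    # carries several times the uniform share
    assert np.median(maxes) > 3 / small_spec.n_species
    flat_spec = SyntheticSpec(
        branching=small_spec.branching, habitat_concentration=1000.0, seed=3
    )
    flat = make_habitats(flat_spec, 5)
    assert max(max(h.values()) for h in flat) < 2 / flat_spec.n_species


def test_samples_depth_and_composition(small_spec, small_reference):
    habitat = make_habitats(small_spec, 1)[0]
    table, reads = make_samples(
        habitat, small_reference, n_samples=200, depth=10_000, seed=9
    )
    assert reads is None
    for s in table.samples:
        assert table.total(s) == 10_000
    # law of large numbers: mean composition approaches the habitat weights
    mean = table.counts.mean(axis=1) / 10_000
    l1 = sum(abs(mean[str(t)] - habitat[t]) for t in habitat)
    assert l1 < 0.05


def test_error_free_reads_match_reference(small_spec, small_reference):
    habitat = make_habitats(small_spec, 1)[0]
    _, reads = make_samples(
        habitat, small_reference, n_samples=2, depth=50, seed=4, with_reads=True
    )
    known = set(small_reference.sequences.values())
    for sample in reads:
        assert sum(sample.values()) == 50
        assert set(sample) <= known


def test_weight_recovery_from_deep_samples(small_spec, small_reference):
    """Aggregating many deep samples recovers the habitat's ground truth."""
    habitat = make_habitats(small_spec, 1)[0]
    table, _ = make_samples(
        habitat, small_reference, n_samples=100, depth=10_000, seed=21
    )
    counts = {}
    for s in table.samples:
        for taxon, c in table.sample_counts(s).items():
            counts[taxon] = counts.get(taxon, 0) + c
    recovered = assemble_weights(counts, small_reference.taxa())
    l1 = sum(abs(recovered[t] - habitat[t]) for t in habitat)
    assert l1 < 0.05


def test_make_samples_rejects_bad_depth(small_spec, small_reference):
    habitat = make_habitats(small_spec, 1)[0]
    with pytest.raises(ValueError):
        make_samples(habitat, small_reference, 2, 0)
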