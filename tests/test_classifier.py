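"""The k-mer naive Bayes classifier: likelihoods, priors, truncation.

Includes two independent cross-checks of the posterior computation: an
explicitly coded brute-force Bayes loop and scikit-learn's MultinomialNB.
"""

import math

import numpy as np
import pytest

from taxaprior.classifier import classify, fit, kmer_profile, predict_posteriors
from taxaprior.io import ReferenceDB
from taxaprior.taxonomy import UNCLASSIFIED, parse_lineage
from taxaprior.weights import TaxonomicWeights, uniform_weights


def _db(records):
    return ReferenceDB(
        sequences={k: v[0] for k, v in records.items()},
        lineages={k: parse_lineage(v[1]) for k, v in records.items()},
    )


@pytest.mark.parametrize(
    "seq, k, expected",
    [
        ("ACGT", 2, {"AC": 1, "CG": 1, "GT": 1}),
        ("ACGNT", 2, {"AC": 1, "CG": 1}),
        ("ACG", 5, {}),
        ("AAAA", 2, {"AA": 3}),
        ("acgt", 3, {"ACG": 1, "CGT": 1}),
    ],
)
def test_kmer_profile(seq, k, expected):
    assert dict(kmer_profile(seq, k)) == expected


def test_kmer_profile_rejects_bad_k():
    with pytest.raises(ValueError):
        kmer_profile("ACGT", 0)


def test_two_class_toy_posterior_hand_computed():
    """A on AAAA, B on CCCC, k=2, alpha=1: theta_A(AA)=4/5, so the
    posterior of A for query AAAA is 0.8^3/(0.8^3+0.2^3) = 64/65."""
    db = _db({"a": ("AAAA", "k__K; s__A"), "b": ("CCCC", "k__K; s__B")})
    model = fit(db, None, k=2, alpha=1.0)
    post = predict_posteriors(model, "AAAA")
    a_idx = [str(c) for c in model.classes].index("k__K; s__A")
    assert post[a_idx] == pytest.approx(64 / 65, abs=1e-12)
    assert post.sum() == pytest.approx(1.0, abs=1e-8)


def test_empty_profile_returns_priors():
    db = _db(
        {
            "a": ("AAAAAAAA", "k__K; s__A"),
            "b": ("CCCCCCCC", "k__K; s__B"),
            "c": ("GGGGGGGG", "k__K; s__C"),
        }
    )
    w = TaxonomicWeights(
        {
            parse_lineage("k__K; s__A"): 0.7,
            parse_lineage("k__K; s__B"): 0.2,
            parse_lineage("k__K; s__C"): 0.1,
        }
    )
    model = fit(db, w, k=4)
    post = predict_posteriors(model, "NNNNNN")
    assert np.allclose(sorted(post), [0.1, 0.2, 0.7])


def test_identical_likelihoods_return_the_weights():
    """Two classes trained on the same sequence: likelihoods cancel and the
    posterior equals the prior for any query."""
    db = _db({"a": ("ACGTACGT", "k__K; s__A"), "b": ("ACGTACGT", "k__K; s__B")})
    w = TaxonomicWeights(
        {parse_lineage("k__K; s__A"): 0.9, parse_lineage("k__K; s__B"): 0.1}
    )
    model = fit(db, w, k=3)
    post = predict_posteriors(model, "ACGTAC")
    assert np.allclose(sorted(post), [0.1, 0.9], atol=1e-12)


def test_single_class_posterior_one():
    db = _db({"a": ("ACGTACGT", "k__K; s__A")})
    model = fit(db, None, k=3)
    lineage, conf = classify(model, "TTTTACGT", confidence=0.7)
    assert str(lineage) == "k__K; s__A" and conf == pytest.approx(1.0)


def test_fit_rejects_missing_weight_taxa():
    db = _db({"a": ("ACGT", "k__K; s__A"), "b": ("CCCC", "k__K; s__B")})
    w = TaxonomicWeights({parse_lineage("k__K; s__A"): 1.0})
    with pytest.raises(ValueError, match="missing"):
        fit(db, w, k=2)


def test_confidence_truncates_tied_sisters_to_genus():
    db = _db(
        {
            "a": ("ACGTACGTACGT", "k__K; p__P; c__C; o__O; f__F; g__G; s__A"),
            "b": ("ACGTACGTACGT", "k__K; p__P; c__C; o__O; f__F; g__G; s__B"),
        }
    )
    model = fit(db, None, k=4)
    lineage, conf = classify(model, "ACGTACGT", confidence=0.7)
    assert lineage == parse_lineage("k__K; p__P; c__C; o__O; f__F; g__G")
    assert conf == pytest.approx(1.0)
    full, post = classify(model, "ACGTACGT", confidence=-1)
    assert full.depth == 7 and post == pytest.approx(0.5)


def test_confidence_minus_one_always_full_depth(small_reference):
    model = fit(small_reference, None)
    for sid in small_reference.ids[:8]:
        lineage, _ = classify(model, small_reference.sequences[sid], confidence=-1)
        assert lineage.depth == 7


def test_raising_confidence_never_deepens_output(small_reference):
    model = fit(small_reference, None)
    for sid in small_reference.ids[:6]:
        seq = small_reference.sequences[sid]
        depths = [
            classify(model, seq, confidence=c)[0].depth
            for c in (0.0, 0.3, 0.5, 0.7, 0.9, 0.999, 1.0)
        ]
        assert depths == sorted(depths, reverse=True)


def test_unclassifiable_query_returns_sentinel():
    db = _db({"a": ("AAAAAAA", "k__K; s__A"), "b": ("CCCCCCC", "k__X; s__B")})
    model = fit(db, None, k=3)
    lineage, _ = classify(model, "AAAACCCC", confidence=1.0)
    # posterior mass splits across domains, so nothing reaches 1.0
    assert lineage == UNCLASSIFIED


def test_invalid_confidence_rejected(toy_reference):
    model = fit(toy_reference, None, k=4)
    for bad in (-0.5, 1.5, 2):
        with pytest.raises(ValueError):
            classify(model, "ACGT", confidence=bad)


def _brute_force_posteriors(db, query, k, alpha, priors):
    """Independent Bayes computation with explicit loops over the
    smoothed-likelihood formula."""
    classes = {}
    for sid in db.ids:
        classes.setdefault(db.lineages[sid], []).append(sid)
    vocab = set()
    pooled = {}
    for taxon, ids in classes.items():
        counts = {}
        for sid in ids:
            seq = db.sequences[sid]
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if set(w) <= set("ACGT"):
                    counts[w] = counts.get(w, 0) + 1
        pooled[taxon] = counts
        vocab |= set(counts)
    log_scores = {}
    for taxon, counts in pooled.items():
        total = sum(counts.values())
        score = math.log(priors[taxon])
        for i in range(len(query) - k + 1):
            m = query[i : i + k]
            if m not in vocab or not set(m) <= set("ACGT"):
                continue
            score += math.log(
                (counts.get(m, 0) + alpha) / (total + alpha * len(vocab))
            )
        log_scores[taxon] = score
    mx = max(log_scores.values())
    exp = {t: math.exp(s - mx) for t, s in log_scores.items()}
    z = sum(exp.values())
    return {t: v / z for t, v in exp.items()}


def test_posteriors_match_brute_force_oracle(small_reference):
    ten = small_reference.subset(small_reference.ids[:10])
    w = uniform_weights(ten.taxa())
    model = fit(ten, w, k=5, alpha=0.01)
    priors = {t: w[t] for t in ten.taxa()}
    for sid in small_reference.ids[10:16]:
        query = small_reference.sequences[sid]
        expected = _brute_force_posteriors(ten, query, k=5, alpha=0.01, priors=priors)
        post = predict_posteriors(model, query)
        for i, cls in enumerate(model.classes):
            assert post[i] == pytest.approx(expected[cls], abs=1e-10)


def test_posteriors_match_sklearn_multinomial_nb(small_reference):
    """Cross-check against an established implementation: per-sequence k-mer
    count vectors with class labels, uniform priors."""
    from sklearn.naive_bayes import MultinomialNB

    k, alpha = 5, 0.01
    model = fit(small_reference, None, k=k, alpha=alpha)
    vocab_index = model.vocab_index
    x = np.zeros((len(small_reference), len(model.vocabulary)))
    y = []
    for row, sid in enumerate(small_reference.ids):
        for kmer, n in kmer_profile(small_reference.sequences[sid], k).items():
            x[row, vocab_index[kmer]] = n
        y.append(str(small_reference.lineages[sid]))
    clf = MultinomialNB(alpha=alpha, fit_prior=False).fit(x, y)
    query = small_reference.sequences[small_reference.ids[0]]
    qv = np.zeros(len(model.vocabulary))
    for kmer, n in kmer_profile(query, k).items():
        qv[vocab_index[kmer]] = n
    sk = clf.predict_proba([qv])[0]
    ours = predict_posteriors(model, query)
    # both class orders are ascending by lineage string
    assert list(clf.classes_) == [str(c) for c in model.classes]
    np.testing.assert_allclose(ours, sk, atol=1e-8)


def test_classification_deterministic(small_reference):
    model = fit(small_reference, None)
    seq = small_reference.sequences[small_reference.ids[3]]
    assert classify(model, seq, 0.7) == classify(model, seq, 0.7)
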