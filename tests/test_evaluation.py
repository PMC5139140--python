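import numpy as np
import pytest

from screenlite.evaluation import (
    DRUG_REVIEW_COLLECTIONS,
    ConfusionCounts,
    collection_stats,
    crossval_protocol,
    recall,
    roc_auc,
    wss,
    wss_at_recall,
)
from screenlite.synthetic import CorpusSpec, generate
from screenlite.text_features import build_feature_space, featurize_citation, vectorize_corpus


def brute_force_auc(scores, labels):
    """Independent O(P*Q) pairwise oracle: wins + half-ties over all pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_confusion_counts_conservation():
    c = ConfusionCounts(TP=3, FP=2, TN=10, FN=1)
    assert c.N == 16
    with pytest.raises(ValueError):
        ConfusionCounts(TP=-1, FP=0, TN=0, FN=0)


@pytest.mark.parametrize(
    "tp,fn,expected", [(19, 1, 0.95), (7, 0, 1.0), (0, 5, 0.0)]
)
def test_recall_values(tp, fn, expected):
    assert recall(ConfusionCounts(TP=tp, FP=0, TN=0, FN=fn)) == pytest.approx(expected)


def test_recall_undefined_without_positives():
    with pytest.raises(ValueError):
        recall(ConfusionCounts(TP=0, FP=3, TN=4, FN=0))


def test_wss_formula_values():
    assert wss(ConfusionCounts(TP=10, FP=0, TN=90, FN=0), 1.0) == pytest.approx(0.90)
    # screen-everything baseline: nothing excluded, recall target 0.95
    assert wss(ConfusionCounts(TP=100, FP=0, TN=0, FN=0), 0.95) == pytest.approx(-0.05)
    assert wss(ConfusionCounts(TP=19, FP=0, TN=980, FN=1), 0.95) == pytest.approx(0.931)


def test_wss_rejects_empty():
    with pytest.raises(ValueError):
        wss(ConfusionCounts(TP=0, FP=0, TN=0, FN=0), 0.5)


def test_auc_perfect_and_derived_example():
    assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
    # pos {0.9, 0.4}, neg {0.8, 0.1}: 3 of 4 pairs correctly ordered
    assert roc_auc([0.9, 0.4, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 2], [1, 1])


def test_auc_matches_bruteforce_oracle_with_ties():
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(10, 120))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_complement_identity_without_ties():
    rng = np.random.default_rng(5)
    scores = rng.permutation(50).astype(float)
    labels = (rng.random(50) < 0.3).astype(int)
    labels[0], labels[1] = 1, 0
    assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)


def test_wss_at_recall_perfect_ranking_closed_form():
    # N=1000, 20 positives ranked on top: prefix=19, TN=980, FN=1
    scores = np.concatenate([np.arange(1000, 980, -1), np.arange(980)[::-1]])
    labels = np.array([1] * 20 + [0] * 980)
    assert wss_at_recall(scores, labels) == pytest.approx(0.931)


def test_wss_at_recall_worst_ranking_saves_nothing():
    # all negatives scored above all positives: the whole list must be read
    scores = np.arange(100, 0, -1)
    labels = np.array([0] * 90 + [1] * 10)
    assert wss_at_recall(scores, labels) <= 0.0 + 1e-12


def test_wss_at_recall_rejects_bad_target():
    with pytest.raises(ValueError):
        wss_at_recall([1, 0], [1, 0], target_recall=0.0)
    with pytest.raises(ValueError):
        wss_at_recall([1, 0], [1, 0], target_recall=1.5)


def test_wss_at_recall_closed_form_random_settings():
    rng = np.random.default_rng(77)
    for _ in range(10):
        n = int(rng.integers(50, 400))
        n_pos = int(rng.integers(5, max(6, n // 5)))
        labels = np.array([1] * n_pos + [0] * (n - n_pos))
        scores = np.arange(n, 0, -1).astype(float)  # perfect ranking
        prefix = int(np.ceil(0.95 * n_pos))
        achieved = prefix / n_pos
        expected = (n - prefix) / n - (1 - achieved)
        assert wss_at_recall(scores, labels) == pytest.approx(expected)


def _small_eval_matrix(signal, seed, n=140):
    spec = CorpusSpec(
        n_citations=n, prevalence=0.15, signal_strength=signal,
        abstract_length=50.0, seed=seed,
    )
    citations, labels = generate(spec)
    bags = [featurize_citation(c) for c in citations]
    space = build_feature_space(bags, min_df=2)
    X = vectorize_corpus(bags, space)
    y = [labels[c.citation_id] for c in citations]
    return X, y


def test_crossval_shape_and_determinism():
    X, y = _small_eval_matrix(signal=0.8, seed=2)
    a = crossval_protocol(X, y, folds=2, repeats=10, seed=4)
    assert len(a.per_run) == 20
    b = crossval_protocol(X, y, folds=2, repeats=10, seed=4)
    assert a.per_run == b.per_run
    assert all(0.0 <= auc <= 1.0 for auc, _ in a.per_run)
    single = crossval_protocol(X, y, folds=2, repeats=3, seed=4, directions=1)
    assert len(single.per_run) == 3


def test_crossval_null_signal_centers_at_half():
    X, y = _small_eval_matrix(signal=0.0, seed=6)
    res = crossval_protocol(X, y, folds=2, repeats=10, seed=1)
    assert 0.4 <= res.auc_mean <= 0.6


def test_crossval_rejects_tiny_class():
    X, y = _small_eval_matrix(signal=0.5, seed=3, n=40)
    y = ["excluded"] * (len(y) - 2) + ["included"] * 2
    with pytest.raises(ValueError, match="stratify"):
        crossval_protocol(X, y)


@pytest.mark.parametrize(
    "name,total,abs_inc,full_inc,decimals,expected",
    [
        ("ACEInhibitors", 2544, 183, 41, 2, 1.61),
        ("ADHD", 851, 84, 20, 2, 2.35),
        ("Antihistamines", 310, 92, 16, 2, 5.16),
        ("UrinaryIncontinence", 327, 78, 40, 1, 12.2),
        ("Everything", 50, 50, 50, 1, 100.0),
    ],
)
def test_collection_stats_percentages(name, total, abs_inc, full_inc, decimals, expected):
    stats = collection_stats(name, total, abs_inc, full_inc, decimals=decimals)
    assert stats.pct_included == pytest.approx(expected)


def test_collection_stats_rejects_bad_ordering():
    with pytest.raises(ValueError):
        collection_stats("X", 100, 10, 20)
    with pytest.raises(ValueError):
        collection_stats("X", 100, 200, 10)


def test_bundled_collections_are_consistent():
    for name, total, abs_inc, full_inc in DRUG_REVIEW_COLLECTIONS:
        stats = collection_stats(name, total, abs_inc, full_inc)
        assert 0 < stats.pct_included <= 100
    sizes = [t for _, t, _, _ in DRUG_REVIEW_COLLECTIONS]
    assert max(sizes) == 3465 and min(sizes) == 310
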