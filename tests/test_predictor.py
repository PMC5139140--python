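import numpy as np
import pytest
import scipy.sparse as sp

from screenlite.predictor import (
    LabelSnapshot,
    active_loop,
    load_state,
    save_state,
    score,
    should_retrain,
    to_stars,
    train,
    update_convergence,
)
from screenlite.text_features import build_feature_space, featurize_citation, vectorize_corpus


def _featurize(citations):
    bags = [featurize_citation(c) for c in citations]
    space = build_feature_space(bags, min_df=2)
    return vectorize_corpus(bags, space), space


def test_train_separable_two_points():
    X = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
    state = train(X, ["included", "excluded"], seed=0)
    s = score(state, X)
    assert s[0] > 0 > s[1]


def test_train_separable_skewed_synthetic():
    rng = np.random.default_rng(0)
    # 5 includes on disjoint signal columns, 45 excludes on background columns
    X = np.zeros((50, 20))
    X[:5, :5] = rng.random((5, 5)) + 0.5
    X[5:, 5:] = rng.random((45, 15)) + 0.5
    labels = ["included"] * 5 + ["excluded"] * 45
    state = train(sp.csr_matrix(X), labels, seed=0)
    preds = score(state, sp.csr_matrix(X)) > 0
    assert all(preds[:5]) and not any(preds[5:])  # training accuracy 1.0


def test_train_single_class_errors_name_missing_class():
    X = sp.csr_matrix(np.eye(3))
    with pytest.raises(ValueError, match="excluded"):
        train(X, ["included"] * 3)
    with pytest.raises(ValueError, match="included"):
        train(X, ["excluded"] * 3)


def test_score_identities():
    X = sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
    state = train(X, ["included", "excluded"], seed=0)
    zero = sp.csr_matrix((1, 2))
    assert score(state, zero)[0] == pytest.approx(state.bias)
    twin = sp.csr_matrix(np.array([[0.3, 0.7], [0.3, 0.7]]))
    s = score(state, twin)
    assert s[0] == s[1]


def test_score_dimension_mismatch():
    X = sp.csr_matrix(np.eye(2))
    state = train(X, ["included", "excluded"])
    with pytest.raises(ValueError, match="feature-space"):
        score(state, sp.csr_matrix((1, 5)))


def test_stars_quintiles_of_distinct_scores():
    ratings = to_stars(list(range(10)))
    by_star = {s: sum(1 for r in ratings if r.stars == s) for s in range(1, 6)}
    assert by_star == {1: 2, 2: 2, 3: 2, 4: 2, 5: 2}
    assert max(ratings, key=lambda r: r.raw_score).stars == 5


def test_stars_all_ties_map_to_three():
    assert all(r.stars == 3 for r in to_stars([0.7] * 9))


def test_stars_monotone_in_score():
    rng = np.random.default_rng(3)
    for _ in range(20):
        scores = rng.normal(size=rng.integers(1, 40))
        ratings = to_stars(scores)
        order = np.argsort(scores)
        stars = np.array([r.stars for r in ratings])[order]
        assert (np.diff(stars) >= 0).all()
        assert set(stars) <= {1, 2, 3, 4, 5}


def test_stars_empty_input_rejected():
    with pytest.raises(ValueError):
        to_stars([])


def _snap(n_inc, n_exc, start=0):
    ids = [f"i{k}" for k in range(start, start + n_inc + n_exc)]
    return LabelSnapshot(frozenset(ids), n_inc, n_exc)


def test_should_retrain_needs_five_per_class():
    assert not should_retrain(None, _snap(4, 100))
    assert not should_retrain(None, _snap(100, 4))
    assert should_retrain(None, _snap(5, 5))


def test_should_retrain_needs_enough_new_labels():
    X = sp.csr_matrix(np.eye(12))
    labels = ["included"] * 6 + ["excluded"] * 6
    ids = [f"i{k}" for k in range(12)]
    state = train(X, labels, citation_ids=ids)
    # same labeled set: nothing new
    assert not should_retrain(state, LabelSnapshot(frozenset(ids), 6, 6))
    # 10 new labels reach max(10, 5% of 22)
    new = frozenset(ids) | frozenset(f"n{k}" for k in range(10))
    assert should_retrain(state, LabelSnapshot(new, 11, 11))
    few = frozenset(ids) | frozenset(f"n{k}" for k in range(3))
    assert not should_retrain(state, LabelSnapshot(few, 8, 7))


def test_should_retrain_blocked_after_convergence():
    X = sp.csr_matrix(np.eye(10))
    state = train(X, ["included"] * 5 + ["excluded"] * 5)
    for q in (0.80, 0.801, 0.8015, 0.8018):
        state = update_convergence(state, q)
    assert state.converged
    assert not should_retrain(state, _snap(50, 50))


def test_convergence_after_three_subthreshold_steps():
    X = sp.csr_matrix(np.eye(10))
    state = train(X, ["included"] * 5 + ["excluded"] * 5)
    assert not state.converged  # first-ever training
    flags = []
    for q in (0.80, 0.801, 0.8015, 0.8018):
        state = update_convergence(state, q)
        flags.append(state.converged)
    assert flags == [False, False, False, True]


def test_convergence_counter_resets_on_improvement():
    X = sp.csr_matrix(np.eye(10))
    state = train(X, ["included"] * 5 + ["excluded"] * 5)
    for q in (0.80, 0.801, 0.8015):
        state = update_convergence(state, q)
    state = update_convergence(state, 0.90)  # jump
    assert state.stall_count == 0 and not state.converged


def test_model_snapshot_roundtrip(tmp_path):
    X = sp.csr_matrix(np.eye(4))
    state = train(X, ["included", "excluded"] * 2, citation_ids=list("abcd"), seed=5)
    p = tmp_path / "model.json"
    save_state(state, p, space_hash="cafe")
    back = load_state(p)
    assert np.allclose(back.weights, state.weights)
    assert back.bias == state.bias
    assert back.trained_on == state.trained_on
    assert back.model_version == state.model_version


def test_active_loop_single_batch_covers_everything(strong_corpus):
    citations, labels = strong_corpus
    X, _ = _featurize(citations)
    ids = [c.citation_id for c in citations]
    traj = active_loop(X, ids, labels, batch_size=len(ids), seed=0)
    assert len(traj) == 1
    assert traj[0].recall == 1.0
    assert traj[0].model_version == 0  # no training before the first batch


def test_active_loop_deterministic(strong_corpus):
    citations, labels = strong_corpus
    X, _ = _featurize(citations)
    ids = [c.citation_id for c in citations]
    a = active_loop(X, ids, labels, batch_size=15, seed=9)
    b = active_loop(X, ids, labels, batch_size=15, seed=9)
    assert a == b


def test_active_loop_trains_and_reaches_full_recall(strong_corpus):
    citations, labels = strong_corpus
    X, _ = _featurize(citations)
    ids = [c.citation_id for c in citations]
    traj = active_loop(X, ids, labels, batch_size=15, seed=1)
    assert traj[-1].recall == 1.0
    assert traj[-1].n_labeled == len(ids)
    assert any(t.model_version >= 1 for t in traj)
    # suggestions never active before five includes are labeled
    for prev, cur in zip(traj, traj[1:]):
        if cur.suggestions_active and not prev.suggestions_active:
            assert prev.n_included_labeled >= 5


def test_active_loop_rejects_bad_batch(strong_corpus):
    citations, labels = strong_corpus
    X, _ = _featurize(citations)
    ids = [c.citation_id for c in citations]
    with pytest.raises(ValueError):
        active_loop(X, ids, labels, batch_size=0)
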