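"""Include/exclude prediction: SVM scoring, five-star ratings, retraining.

As reviewers label citations, a linear support-vector machine is retrained
on the labeled set and scores the rest by signed distance to its decision
boundary (higher = more include-like).  Scores are shown to reviewers as
one-to-five-star suggestions, mapped by quintile of the current unlabeled
score distribution.  Suggestions are withheld until the labeled set carries
enough signal (at least five included and five excluded citations), the
model is refreshed once enough new labels accumulate, and retraining stops
once its internal quality estimate plateaus.

:func:`active_loop` simulates the whole prospective process on a corpus
with known labels, yielding the recall trajectory of a screening session
that always reads the top-ranked citations next.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.svm import LinearSVC

from .evaluation import roc_auc

__all__ = [
    "PredictionState",
    "StarRating",
    "LabelSnapshot",
    "train",
    "score",
    "to_stars",
    "should_retrain",
    "update_convergence",
    "internal_quality",
    "active_loop",
    "save_state",
    "load_state",
]

MIN_INCLUDES = 5          # suggestions appear beyond five included studies
MIN_EXCLUDES = 5
MIN_NEW_LABELS = 10       # retrain once >= max(10, 5% of labeled) new labels
NEW_LABEL_FRACTION = 0.05
CONVERGENCE_DELTA = 0.005  # quality improvement below this counts as a stall
CONVERGENCE_PATIENCE = 3   # consecutive stalls before declaring convergence

POSITIVE, NEGATIVE = "included", "excluded"


@dataclass
class PredictionState:
    """A trained linear-SVM snapshot plus retraining bookkeeping."""

    weights: np.ndarray
    bias: float
    trained_on: frozenset[str]
    model_version: int = 1
    last_quality: float | None = None
    converged: bool = False
    stall_count: int = 0
    seed: int = 0


@dataclass(frozen=True)
class StarRating:
    citation_id: str
    stars: int
    raw_score: float


@dataclass(frozen=True)
class LabelSnapshot:
    """What is labeled right now, for the retraining policy."""

    labeled_ids: frozenset[str]
    n_included: int
    n_excluded: int

    @classmethod
    def from_labels(cls, labels: Mapping[str, str]) -> "LabelSnapshot":
        inc = sum(1 for v in labels.values() if v == POSITIVE)
        return cls(
            labeled_ids=frozenset(labels),
            n_included=inc,
            n_excluded=len(labels) - inc,
        )


def _as_binary(labels: Sequence[str]) -> np.ndarray:
    y = np.zeros(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab == POSITIVE:
            y[i] = 1
        elif lab != NEGATIVE:
            raise ValueError(f"labels must be '{POSITIVE}'/'{NEGATIVE}', got {lab!r}")
    return y


def train(
    X: sp.spmatrix,
    labels: Sequence[str],
    citation_ids: Sequence[str] | None = None,
    seed: int = 0,
    prev_state: PredictionState | None = None,
    C: float = 1.0,
) -> PredictionState:
    """Fit a linear SVM (C=1, balanced class weights) on the labeled vectors.

    Balanced class weighting counteracts the heavy class skew of screening
    corpora, where included citations are a few percent of the total.
    Deterministic given the same inputs and seed.  Raises if a class is
    missing from ``labels``.
    """
    y = _as_binary(labels)
    for cls_val, name in ((1, POSITIVE), (0, NEGATIVE)):
        if not np.any(y == cls_val):
            raise ValueError(f"training requires at least one '{name}' example")
    clf = LinearSVC(C=C, class_weight="balanced", random_state=seed, max_iter=5000)
    clf.fit(X, y)
    ids = frozenset(citation_ids) if citation_ids is not None else frozenset()
    return PredictionState(
        weights=np.asarray(clf.coef_).ravel(),
        bias=float(clf.intercept_[0]),
        trained_on=ids,
        model_version=(prev_state.model_version + 1) if prev_state else 1,
        last_quality=prev_state.last_quality if prev_state else None,
        converged=prev_state.converged if prev_state else False,
        stall_count=prev_state.stall_count if prev_state else 0,
        seed=seed,
    )


def score(state: PredictionState, X: sp.spmatrix) -> np.ndarray:
    """Signed distance to the decision boundary; higher = more include-like."""
    if X.shape[1] != state.weights.shape[0]:
        raise ValueError(
            f"feature-space mismatch: vectors have {X.shape[1]} features, "
            f"model expects {state.weights.shape[0]}"
        )
    return np.asarray(X @ state.weights).ravel() + state.bias


def to_stars(
    scores: Sequence[float], citation_ids: Sequence[str] | None = None
) -> list[StarRating]:
    """Map raw scores to 1..5 stars by quintile of the scored set.

    The top fifth of scores gets five stars, the next fifth four, and so on;
    tied scores share the star of their midrank, so an all-tied set lands in
    the middle at three stars.  Stars are non-decreasing in raw score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("to_stars requires at least one score")
    ranks = rankdata(scores, method="average")  # 1..n, ties -> midrank
    quantile = (ranks - 0.5) / scores.size
    stars = np.minimum(1 + np.floor(quantile * 5).astype(int), 5)
    if citation_ids is None:
        citation_ids = [str(i) for i in range(scores.size)]
    return [
        StarRating(citation_id=cid, stars=int(s), raw_score=float(sc))
        for cid, s, sc in zip(citation_ids, stars, scores)
    ]


def should_retrain(
    state: PredictionState | None, labeled_now: LabelSnapshot
) -> bool:
    """Decide whether a fresh model is worth building.

    True when (a) both classes have at least five labeled examples, (b) at
    least ``max(10, 5% of labeled)`` citations were labeled since the last
    training, and (c) the model has not converged.  A never-trained state
    counts every label as new.
    """
    if labeled_now.n_included < MIN_INCLUDES or labeled_now.n_excluded < MIN_EXCLUDES:
        return False
    if state is not None and state.converged:
        return False
    trained_on = state.trained_on if state is not None else frozenset()
    n_new = len(labeled_now.labeled_ids - trained_on)
    n_labeled = len(labeled_now.labeled_ids)
    return n_new >= max(MIN_NEW_LABELS, NEW_LABEL_FRACTION * n_labeled)


def update_convergence(
    state: PredictionState, new_quality: float
) -> PredictionState:
    """Fold a fresh internal quality estimate into the stop rule.

    The model is declared converged — "cannot be improved any further" —
    after ``CONVERGENCE_PATIENCE`` consecutive retrains whose quality
    improvement fell short of ``CONVERGENCE_DELTA``.  A genuine improvement
    resets the counter.
    """
    if not 0.0 <= new_quality <= 1.0:
        raise ValueError("quality must lie in [0, 1]")
    if state.last_quality is None:
        stall = 0
    elif new_quality - state.last_quality < CONVERGENCE_DELTA:
        stall = state.stall_count + 1
    else:
        stall = 0
    return replace(
        state,
        last_quality=new_quality,
        stall_count=stall,
        converged=stall >= CONVERGENCE_PATIENCE,
    )


def internal_quality(
    X: sp.spmatrix, labels: Sequence[str], seed: int = 0
) -> float:
    """Two-fold cross-validated AUC on the labeled set — the model's own
    estimate of its prediction quality, used by the convergence rule."""
    from sklearn.model_selection import StratifiedKFold

    y = _as_binary(labels)
    if min(np.bincount(y, minlength=2)) < 2:
        return 0.5
    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = LinearSVC(C=1.0, class_weight="balanced", random_state=seed, max_iter=5000)
        clf.fit(X[train_idx], y[train_idx])
        s = clf.decision_function(X[test_idx])
        if len(set(y[test_idx])) < 2:
            continue
        aucs.append(roc_auc(s, y[test_idx]))
    return float(np.mean(aucs)) if aucs else 0.5


@dataclass
class TrajectoryStep:
    """State of the simulated screening session after one labeled batch."""

    step: int
    n_labeled: int
    n_included_labeled: int
    recall: float
    model_version: int
    suggestions_active: bool


def active_loop(
    X: sp.spmatrix,
    citation_ids: Sequence[str],
    oracle_labels: Mapping[str, str],
    batch_size: int,
    seed: int = 0,
) -> list[TrajectoryStep]:
    """Simulate prospective screening with model-ranked reading order.

    An initial random batch is labeled (the oracle supplies the true
    verdict); then repeatedly: retrain when :func:`should_retrain` fires
    (updating the convergence state from the internal quality estimate),
    re-score the unlabeled pool, and label the top-ranked batch — or a
    random batch while no model exists yet.  Each step records the
    cumulative recall of included studies.  Runs to exhaustion of the
    corpus; with a fixed seed the trajectory is fully reproducible.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    ids = list(citation_ids)
    if len(ids) != X.shape[0]:
        raise ValueError("citation_ids length must match the number of vectors")
    rng = np.random.default_rng(seed)
    row_of = {cid: i for i, cid in enumerate(ids)}
    total_pos = sum(1 for cid in ids if oracle_labels[cid] == POSITIVE)

    unlabeled = list(ids)
    labels: dict[str, str] = {}
    state: PredictionState | None = None
    trajectory: list[TrajectoryStep] = []
    step = 0

    def label_batch(batch: list[str]) -> None:
        for cid in batch:
            labels[cid] = oracle_labels[cid]
            unlabeled.remove(cid)

    while unlabeled:
        snap = LabelSnapshot.from_labels(labels)
        if labels and should_retrain(state, snap):
            rows = sorted(labels, key=row_of.__getitem__)
            Xl = X[[row_of[c] for c in rows]]
            yl = [labels[c] for c in rows]
            quality = internal_quality(Xl, yl, seed=seed + len(labels))
            state = train(Xl, yl, citation_ids=rows, seed=seed, prev_state=state)
            state = update_convergence(state, quality)
        if state is not None:
            rows = [row_of[c] for c in unlabeled]
            s = score(state, X[rows])
            # stable ranking: descending score, ties broken by citation_id
            order = sorted(range(len(unlabeled)), key=lambda i: (-s[i], unlabeled[i]))
            batch = [unlabeled[i] for i in order[:batch_size]]
        else:
            batch = list(rng.choice(unlabeled, size=min(batch_size, len(unlabeled)),
                                    replace=False))
        label_batch(batch)
        step += 1
        n_inc = sum(1 for v in labels.values() if v == POSITIVE)
        trajectory.append(
            TrajectoryStep(
                step=step,
                n_labeled=len(labels),
                n_included_labeled=n_inc,
                recall=n_inc / total_pos if total_pos else 1.0,
                model_version=state.model_version if state else 0,
                suggestions_active=state is not None,
            )
        )
    return trajectory


def save_state(state: PredictionState, path: str | Path, space_hash: str = "") -> None:
    """Serialize a model snapshot as JSON (weights, bias, version, vocab hash)."""
    payload = {
        "weights": state.weights.tolist(),
        "bias": state.bias,
        "trained_on": sorted(state.trained_on),
        "model_version": state.model_version,
        "last_quality": state.last_quality,
        "converged": state.converged,
        "stall_count": state.stall_count,
        "seed": state.seed,
        "vocabulary_hash": space_hash,
    }
    Path(path).write_text(json.dumps(payload), "utf-8")


def load_state(path: str | Path) -> PredictionState:
    p = json.loads(Path(path).read_text("utf-8"))
    return PredictionState(
        weights=np.asarray(p["weights"], dtype=float),
        bias=float(p["bias"]),
        trained_on=frozenset(p["trained_on"]),
        model_version=p["model_version"],
        last_quality=p["last_quality"],
        converged=p["converged"],
        stall_count=p["stall_count"],
        seed=p["seed"],
    )


def vocabulary_hash(vocabulary: Sequence[str]) -> str:
    """Fingerprint of a feature-space vocabulary, stored with model snapshots."""
    h = hashlib.sha1("\n".join(vocabulary).encode("utf-8"))
    return h.hexdigest()[:12]
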