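"""Screening-prioritization evaluation: recall, ROC/AUC, WSS@95, CV protocol.

The benefit of ranking citations by classifier score is measured two ways:

* **AUC** — the area under the ROC curve (true-positive rate against
  false-positive rate as the decision threshold varies); 1.0 is a perfect
  ranking, 0.5 a random one.  Computed as the Mann-Whitney pair statistic
  with ties credited one half.

* **WSS@95** — work saved over sampling at 95% recall::

      WSS = (TN + FN) / N - (1 - Recall)

  the fraction of citations a reviewer need not read, relative to random
  ordering, while still finding 95% of the truly included studies.  On
  ranked scores the threshold is the smallest prefix whose recall reaches
  the target; the formula is applied with the recall actually achieved.

The evaluation protocol is stratified twofold cross-validation (a 50/50
train/test split) repeated ten times with the results averaged; by default
both fold directions are evaluated per repeat, giving twenty runs.

:func:`collection_stats` reproduces benchmark-table bookkeeping for
screening test collections (total records, included at abstract and at
full-text level, inclusion percentage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "CollectionStats",
    "recall",
    "wss",
    "roc_auc",
    "wss_at_recall",
    "crossval_protocol",
    "collection_stats",
    "DRUG_REVIEW_COLLECTIONS",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with the conservation check TP+FP+TN+FN = N."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalResult:
    """Cross-validation summary: per-run (AUC, WSS@95) plus means and SDs."""

    auc_mean: float
    auc_sd: float
    wss95_mean: float
    wss95_sd: float
    per_run: list[tuple[float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class CollectionStats:
    """One screening test collection: size and inclusion counts.

    ``abs_included`` counts citations included at abstract screening,
    ``full_included`` those still included after full-text review;
    ``pct_included`` is the full-text inclusion percentage of the total.
    """

    name: str
    total: int
    abs_included: int
    full_included: int
    pct_included: float


def recall(counts: ConfusionCounts) -> float:
    """Recall of the positive (included) class: TP / (TP + FN)."""
    pos = counts.TP + counts.FN
    if pos == 0:
        raise ValueError("recall undefined: no positive instances (TP + FN = 0)")
    return counts.TP / pos


def wss(counts: ConfusionCounts, recall_value: float) -> float:
    """Work saved over sampling: (TN + FN)/N − (1 − Recall).

    May be negative when the ranking is worse than reading at random.
    """
    if counts.N == 0:
        raise ValueError("WSS undefined for N = 0")
    if not 0.0 <= recall_value <= 1.0:
        raise ValueError("recall_value must lie in [0, 1]")
    return (counts.TN + counts.FN) / counts.N - (1.0 - recall_value)


def _as_binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        y = np.asarray([1 if v == "included" else 0 for v in arr])
    else:
        y = arr.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (0/1 or 'included'/'excluded')")
    return y


def roc_auc(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve of a score-based ranking.

    Equals the Mann-Whitney statistic: the probability that a random
    positive outscores a random negative, ties counted one half.
    """
    y = _as_binary_labels(labels)
    if len(set(y)) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def wss_at_recall(
    scores: Sequence[float],
    labels: Sequence,
    target_recall: float = 0.95,
    ids: Sequence[str] | None = None,
) -> float:
    """WSS at a target recall for a ranked screening list.

    Citations are ranked by descending score (ties broken stably by id);
    the smallest prefix achieving the target recall is "read", everything
    after it is predicted excluded, and the WSS formula is applied with the
    recall that prefix actually achieves.
    """
    if not 0.0 < target_recall <= 1.0:
        raise ValueError("target_recall must lie in (0, 1]")
    y = _as_binary_labels(labels)
    if len(set(y)) < 2:
        raise ValueError("wss_at_recall requires both classes present")
    s = np.asarray(scores, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(len(s))]
    order = sorted(range(len(s)), key=lambda i: (-s[i], ids[i]))
    y_ranked = y[order]
    n_pos = int(y_ranked.sum())
    cum_pos = np.cumsum(y_ranked)
    needed = int(np.ceil(target_recall * n_pos))
    prefix = int(np.searchsorted(cum_pos, needed) + 1)  # smallest prefix length
    tp = int(cum_pos[prefix - 1])
    fp = prefix - tp
    fn = n_pos - tp
    tn = len(s) - prefix - fn
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    return wss(counts, recall(counts))


def crossval_protocol(
    X: sp.spmatrix | np.ndarray,
    labels: Sequence,
    folds: int = 2,
    repeats: int = 10,
    seed: int = 0,
    target_recall: float = 0.95,
    directions: int | None = None,
) -> EvalResult:
    """Stratified k-fold CV repeated several times, averaging AUC and WSS.

    Per repeat a fresh stratified split is drawn; each fold serves once as
    the test half, so with the default twofold × 10 repeats there are 20
    per-run entries (``directions=1`` evaluates only the first fold per
    repeat, for the 10-run accounting).  Deterministic given the seed.
    """
    y = _as_binary_labels(labels)
    counts = np.bincount(y, minlength=2)
    if min(counts) < 2 * folds:
        raise ValueError(
            f"too few members of a class to stratify: need >= {2 * folds} per class, "
            f"have included={counts[1]}, excluded={counts[0]}"
        )
    from .predictor import train, score  # deferred: predictor imports this module

    X = sp.csr_matrix(X)
    per_run: list[tuple[float, float]] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for d, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            if directions is not None and d >= directions:
                break
            lab_train = ["included" if v else "excluded" for v in y[train_idx]]
            state = train(X[train_idx], lab_train, seed=seed)
            s = score(state, X[test_idx])
            per_run.append(
                (
                    roc_auc(s, y[test_idx]),
                    wss_at_recall(s, y[test_idx], target_recall=target_recall),
                )
            )
    aucs = np.array([a for a, _ in per_run])
    wsss = np.array([w for _, w in per_run])
    return EvalResult(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        wss95_mean=float(wsss.mean()),
        wss95_sd=float(wsss.std(ddof=1)) if len(wsss) > 1 else 0.0,
        per_run=per_run,
    )


def collection_stats(
    name: str,
    total: int,
    abs_included: int,
    full_included: int,
    decimals: int = 2,
) -> CollectionStats:
    """Tabulate one screening collection's inclusion statistics.

    ``pct_included`` is ``100 * full_included / total`` rounded to the
    requested number of decimals.  The counts must nest:
    full-text included <= abstract included <= total.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= full_included <= abs_included <= total:
        raise ValueError(
            "counts must satisfy 0 <= full_included <= abs_included <= total"
        )
    return CollectionStats(
        name=name,
        total=total,
        abs_included=abs_included,
        full_included=full_included,
        pct_included=round(100.0 * full_included / total, decimals),
    )


# Published screening test collections from 15 drug-effectiveness reviews
# (total records, included at abstract level, included at full-text level).
# Used for demonstrations and sanity checks of collection_stats; the full
# corpora themselves are not bundled.
DRUG_REVIEW_COLLECTIONS: list[tuple[str, int, int, int]] = [
    ("ACEInhibitors", 2544, 183, 41),
    ("ADHD", 851, 84, 20),
    ("Antihistamines", 310, 92, 16),
    ("AtypicalAntipsychotics", 1120, 363, 146),
    ("BetaBlockers", 2072, 302, 42),
    ("CalciumChannelBlockers", 1218, 279, 100),
    ("Estrogens", 368, 80, 80),
    ("NSAIDs", 393, 88, 41),
    ("Opioids", 1915, 48, 15),
    ("OralHypoglycemics", 503, 139, 136),
    ("ProtonPumpInhibitors", 1333, 238, 51),
    ("SkeletalMuscleRelaxants", 1643, 34, 9),
    ("Statins", 3465, 173, 85),
    ("Triptans", 671, 218, 24),
    ("UrinaryIncontinence", 327, 78, 40),
]
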