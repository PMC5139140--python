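"""Reviewer decision tracking: verdicts, reasons, conflicts, blinding, PRISMA.

A :class:`Review` holds the citations under screening plus every reviewer's
current verdict (included / excluded / undecided) and free-form exclusion
reasons.  The module supports the bookkeeping a systematic review needs:
filtering by decision or reviewer, surfacing disagreements between
reviewers, a blinded projection that hides collaborators' verdicts, and
PRISMA-flow-style counts with a conservation guarantee
(included + excluded + undecided = total).

Timestamps are logical counters rather than wall-clock times so that replays
of the same decision log are reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .citation_io import Citation

__all__ = [
    "VERDICTS",
    "DEFAULT_REASONS",
    "ScreeningDecision",
    "PrismaCounts",
    "Review",
    "record_decision",
    "filter_citations",
    "conflicts",
    "blind_view",
    "prisma_counts",
    "save_review",
    "load_review",
]

VERDICTS = ("included", "excluded", "undecided")

# Generic exclusion reasons offered out of the box; reviewers add their own.
DEFAULT_REASONS = (
    "wrong population",
    "wrong publication type",
    "wrong study design",
)


@dataclass(frozen=True)
class ScreeningDecision:
    citation_id: str
    reviewer_id: str
    verdict: str
    reasons: tuple[str, ...] = ()
    timestamp: int = 0

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}, got {self.verdict!r}")
        if self.reasons and self.verdict != "excluded":
            raise ValueError("exclusion reasons are only valid with verdict='excluded'")


@dataclass
class PrismaCounts:
    """PRISMA-flow tallies; conservation holds by construction."""

    n_total: int
    n_included: int
    n_excluded: int
    n_undecided: int
    excluded_by_reason: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_included + self.n_excluded + self.n_undecided != self.n_total:
            raise ValueError("PRISMA counts do not sum to the total")


@dataclass
class Review:
    """Citations plus the current decision state of every reviewer."""

    citations: list[Citation] = field(default_factory=list)
    decisions: dict[tuple[str, str], ScreeningDecision] = field(default_factory=dict)
    reason_vocabulary: list[str] = field(default_factory=lambda: list(DEFAULT_REASONS))
    blind: bool = False
    clock: int = 0

    def __post_init__(self) -> None:
        self._by_id = {c.citation_id: c for c in self.citations}

    def citation(self, citation_id: str) -> Citation:
        try:
            return self._by_id[citation_id]
        except KeyError:
            raise KeyError(f"unknown citation_id {citation_id!r}") from None

    def reviewers(self) -> list[str]:
        return sorted({rev for (_, rev) in self.decisions})

    def decisions_for(self, citation_id: str) -> dict[str, ScreeningDecision]:
        return {
            rev: d for (cid, rev), d in self.decisions.items() if cid == citation_id
        }

    def copy(self) -> "Review":
        return Review(
            citations=list(self.citations),
            decisions=dict(self.decisions),
            reason_vocabulary=list(self.reason_vocabulary),
            blind=self.blind,
            clock=self.clock,
        )


def record_decision(
    review: Review,
    citation_id: str,
    reviewer_id: str,
    verdict: str,
    reasons: Iterable[str] = (),
) -> Review:
    """Record (or replace) one reviewer's verdict on one citation.

    Each (citation, reviewer) pair holds at most one current decision;
    re-tagging replaces the previous verdict and clears its reasons.  New
    exclusion reasons are appended to the review's reason vocabulary.
    The review is updated in place and returned.
    """
    review.citation(citation_id)  # raises on unknown id
    reasons = tuple(r.strip() for r in reasons if r.strip())
    review.clock += 1
    decision = ScreeningDecision(
        citation_id=citation_id,
        reviewer_id=reviewer_id,
        verdict=verdict,
        reasons=reasons,
        timestamp=review.clock,
    )
    review.decisions[(citation_id, reviewer_id)] = decision
    for r in reasons:
        if r not in review.reason_vocabulary:
            review.reason_vocabulary.append(r)
    return review


def filter_citations(
    review: Review,
    by_verdict: str | None = None,
    by_reviewer: str | None = None,
    by_reason: str | None = None,
) -> list[Citation]:
    """Select citations by decision attributes (filters are conjunctive).

    With ``by_reviewer`` the verdict/reason filters apply to that reviewer's
    decision; otherwise a citation matches if any reviewer's decision does.
    ``by_verdict="undecided"`` matches citations with no decision as well.
    No filters returns all citations, in stable file order.
    """
    if by_verdict is not None and by_verdict not in VERDICTS:
        raise ValueError(f"verdict must be one of {VERDICTS}")

    def matches(cid: str) -> bool:
        decs = review.decisions_for(cid)
        if by_reviewer is not None:
            d = decs.get(by_reviewer)
            pool = [d] if d is not None else []
        else:
            pool = list(decs.values())
        if not pool:
            return (by_verdict in (None, "undecided")) and by_reason is None
        for d in pool:
            if by_verdict is not None and d.verdict != by_verdict:
                continue
            if by_reason is not None and by_reason not in d.reasons:
                continue
            return True
        return False

    return [c for c in review.citations if matches(c.citation_id)]


def conflicts(review: Review) -> list[tuple[str, dict[str, str]]]:
    """Citations on which reviewers actively disagree.

    A conflict is an included-vs-excluded split between at least two
    reviewers; "undecided" never conflicts with anything.  Returns, per
    conflicted citation in file order, the map of every deciding reviewer
    to their verdict.
    """
    out = []
    for c in review.citations:
        decs = review.decisions_for(c.citation_id)
        active = {d.verdict for d in decs.values() if d.verdict != "undecided"}
        if len(active) >= 2:
            out.append(
                (c.citation_id, {rev: d.verdict for rev, d in sorted(decs.items())})
            )
    return out


def blind_view(review: Review, viewer: str) -> Review:
    """Project the review so the viewer sees only their own decisions.

    Supports blinded, independent screening: with blind mode on, other
    reviewers' verdicts, reasons and activity are absent from the
    projection.  With blind mode off the full review is returned.
    """
    if not review.blind:
        return review.copy()
    projected = review.copy()
    projected.decisions = {
        key: d for key, d in review.decisions.items() if key[1] == viewer
    }
    return projected


def _consensus_verdict(decs: dict[str, ScreeningDecision]) -> str:
    active = [d.verdict for d in decs.values() if d.verdict != "undecided"]
    if active and all(v == active[0] for v in active):
        return active[0]
    return "undecided"


def prisma_counts(review: Review, reviewer_id: str | None = None) -> PrismaCounts:
    """PRISMA-style decision tallies for the flow diagram.

    With ``reviewer_id``, counts that reviewer's decisions (their undecided
    pile includes citations they have not touched).  Without it, a consensus
    rule applies: a citation counts as included or excluded only if every
    deciding reviewer agrees; disagreements and untouched citations count as
    undecided.  ``excluded_by_reason`` counts each excluded citation once
    per distinct reason given for it.
    """
    n_inc = n_exc = 0
    by_reason: dict[str, int] = {}
    for c in review.citations:
        decs = review.decisions_for(c.citation_id)
        if reviewer_id is not None:
            d = decs.get(reviewer_id)
            verdict = d.verdict if d else "undecided"
            reasons = set(d.reasons) if d else set()
        else:
            verdict = _consensus_verdict(decs)
            reasons = set()
            if verdict == "excluded":
                for d in decs.values():
                    reasons.update(d.reasons)
        if verdict == "included":
            n_inc += 1
        elif verdict == "excluded":
            n_exc += 1
            for r in sorted(reasons):
                by_reason[r] = by_reason.get(r, 0) + 1
    n_total = len(review.citations)
    return PrismaCounts(
        n_total=n_total,
        n_included=n_inc,
        n_excluded=n_exc,
        n_undecided=n_total - n_inc - n_exc,
        excluded_by_reason=by_reason,
    )


# ---------------------------------------------------------------------------
# persistence: review store (JSON) and decision log (TSV)

def save_review(review: Review, path: str | Path) -> None:
    payload = {
        "citations": [c.to_dict() for c in review.citations],
        "decisions": [
            {
                "citation_id": d.citation_id,
                "reviewer_id": d.reviewer_id,
                "verdict": d.verdict,
                "reasons": list(d.reasons),
                "timestamp": d.timestamp,
            }
            for d in sorted(review.decisions.values(), key=lambda d: d.timestamp)
        ],
        "reason_vocabulary": review.reason_vocabulary,
        "blind": review.blind,
        "clock": review.clock,
    }
    Path(path).write_text(json.dumps(payload, indent=1, ensure_ascii=False), "utf-8")


def load_review(path: str | Path) -> Review:
    payload = json.loads(Path(path).read_text("utf-8"))
    review = Review(
        citations=[Citation.from_dict(d) for d in payload["citations"]],
        reason_vocabulary=payload.get("reason_vocabulary", list(DEFAULT_REASONS)),
        blind=payload.get("blind", False),
        clock=payload.get("clock", 0),
    )
    for d in payload.get("decisions", []):
        review.decisions[(d["citation_id"], d["reviewer_id"])] = ScreeningDecision(
            citation_id=d["citation_id"],
            reviewer_id=d["reviewer_id"],
            verdict=d["verdict"],
            reasons=tuple(d.get("reasons", ())),
            timestamp=d.get("timestamp", 0),
        )
    return review


def write_decision_log(review: Review, path: str | Path) -> None:
    """Decision log as TSV: citation_id, reviewer, verdict, ;-joined reasons, ts."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["citation_id", "reviewer_id", "verdict", "reasons", "timestamp"])
        for d in sorted(review.decisions.values(), key=lambda d: d.timestamp):
            w.writerow(
                [d.citation_id, d.reviewer_id, d.verdict, ";".join(d.reasons), d.timestamp]
            )


def read_decision_log(path: str | Path) -> list[ScreeningDecision]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ScreeningDecision(
                    citation_id=row["citation_id"],
                    reviewer_id=row["reviewer_id"],
                    verdict=row["verdict"],
                    reasons=tuple(r for r in row["reasons"].split(";") if r),
                    timestamp=int(row["timestamp"]),
                )
            )
    return out
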