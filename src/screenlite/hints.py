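"""Keyword hints, text highlighting and the MeSH word cloud.

Two editable keyword lists — one hinting a citation should be included
(randomized-trial vocabulary, seeded in the spirit of the published EMBASE
RCT filter) and one hinting exclusion (non-trial publication types, animal
studies) — are matched against each citation's title and abstract as
whole words or phrases.  Matches drive facet filters and on-screen
highlighting; MeSH term frequencies across the review feed a word cloud
whose entry sizes scale with the number of studies carrying each term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from math import log
from pathlib import Path
from typing import Iterable, Sequence

from .citation_io import Citation

__all__ = [
    "HintLists",
    "WordCloudEntry",
    "default_hint_lists",
    "load_hint_list",
    "add_term",
    "remove_term",
    "match_hints",
    "highlight_spans",
    "word_cloud",
]


@dataclass
class HintLists:
    """Include/exclude hint phrases; lowercase, deduplicated, disjoint."""

    include_terms: list[str] = field(default_factory=list)
    exclude_terms: list[str] = field(default_factory=list)


def _parse_term_lines(lines: Iterable[str]) -> list[str]:
    terms: list[str] = []
    seen = set()
    for line in lines:
        term = line.split("#", 1)[0].strip().lower()
        if term and term not in seen:
            terms.append(term)
            seen.add(term)
    return terms


def load_hint_list(path: str | Path) -> list[str]:
    """Read one hint list: plain text, one phrase per line, '#' comments."""
    return _parse_term_lines(Path(path).read_text("utf-8").splitlines())


def default_hint_lists() -> HintLists:
    """The bundled seed lists (editable data files, not hard-coded).

    The include side carries phrases indicative of randomized controlled
    trials; the exclude side carries non-RCT publication types and animal
    studies.  Loading enforces that the two lists are disjoint.
    """
    lists = HintLists()
    for side, fname in (
        ("include_terms", "hints_include.txt"),
        ("exclude_terms", "hints_exclude.txt"),
    ):
        text = resources.files("screenlite.data").joinpath(fname).read_text("utf-8")
        setattr(lists, side, _parse_term_lines(text.splitlines()))
    overlap = set(lists.include_terms) & set(lists.exclude_terms)
    if overlap:
        raise ValueError(f"bundled hint lists overlap on {sorted(overlap)}")
    return lists


def add_term(
    lists: HintLists, add_to: str, term: str
) -> tuple[HintLists, list[str]]:
    """Add a phrase to one list; returns the new lists plus any warnings.

    Terms are lowercased and deduplicated; adding a term already present on
    the *other* list moves it there (with a warning), keeping the two lists
    disjoint.  Adding an existing term is a no-op.
    """
    term = term.strip().lower()
    if not term:
        raise ValueError("hint term must be non-empty")
    if add_to not in ("include", "exclude"):
        raise ValueError("add_to must be 'include' or 'exclude'")
    inc = list(lists.include_terms)
    exc = list(lists.exclude_terms)
    target, other = (inc, exc) if add_to == "include" else (exc, inc)
    warnings: list[str] = []
    if term in other:
        other.remove(term)
        warnings.append(f"moved {term!r} from the {'exclude' if add_to == 'include' else 'include'} list")
    if term not in target:
        target.append(term)
    return HintLists(include_terms=inc, exclude_terms=exc), warnings


def remove_term(lists: HintLists, remove_from: str, term: str) -> HintLists:
    """Remove a phrase from one list (no-op if absent)."""
    term = term.strip().lower()
    if not term:
        raise ValueError("hint term must be non-empty")
    if remove_from not in ("include", "exclude"):
        raise ValueError("remove_from must be 'include' or 'exclude'")
    inc = [t for t in lists.include_terms if not (remove_from == "include" and t == term)]
    exc = [t for t in lists.exclude_terms if not (remove_from == "exclude" and t == term)]
    return HintLists(include_terms=inc, exclude_terms=exc)


def _phrase_pattern(phrase: str) -> re.Pattern:
    # whole-word phrase match ("trial" must not hit "industrial"); internal
    # whitespace in the phrase matches any whitespace run
    words = [re.escape(w) for w in phrase.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def match_hints(
    citation: Citation, lists: HintLists, search_keywords: bool = False
) -> tuple[list[str], list[str]]:
    """Match the hint lists against one citation.

    Case-insensitive whole-word/phrase search over title + abstract (plus
    the source keywords field when ``search_keywords`` is set); each term
    is reported at most once per side, in list order.
    """
    haystack = citation.text()
    if search_keywords:
        haystack += " " + " ".join(citation.keywords)
    inc_hits = [t for t in lists.include_terms if _phrase_pattern(t).search(haystack)]
    exc_hits = [t for t in lists.exclude_terms if _phrase_pattern(t).search(haystack)]
    return inc_hits, exc_hits


def highlight_spans(text: str, terms: Sequence[str]) -> list[tuple[int, int]]:
    """Character intervals to highlight for a set of terms.

    Half-open, 0-based ``(start, end)`` intervals of case-insensitive
    whole-word matches; overlapping intervals from different terms are
    merged; result sorted by start.
    """
    raw: list[tuple[int, int]] = []
    for term in terms:
        term = term.strip()
        if not term:
            continue
        for m in _phrase_pattern(term).finditer(text):
            raw.append((m.start(), m.end()))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for start, end in raw:
        if merged and start < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass(frozen=True)
class WordCloudEntry:
    """One word-cloud term: how many studies carry it, and its display size
    relative to the most frequent term (the maximum has size 1)."""

    term: str
    n_studies: int
    relative_size: float


def word_cloud(
    citations: Sequence[Citation], scale: str = "linear"
) -> list[WordCloudEntry]:
    """Summarize the review's MeSH terms as word-cloud entries.

    ``n_studies`` counts citations whose ``mesh_terms`` contain the term
    (study count, not token frequency).  Sizes are linear in study count by
    default; ``scale="log"`` compresses the range for very skewed reviews.
    Entries are sorted by count descending, then term.
    """
    if scale not in ("linear", "log"):
        raise ValueError("scale must be 'linear' or 'log'")
    counts: dict[str, int] = {}
    for c in citations:
        for term in {t.lower() for t in c.mesh_terms}:
            counts[term] = counts.get(term, 0) + 1
    if not counts:
        return []
    max_n = max(counts.values())

    def size(n: int) -> float:
        if scale == "linear":
            return n / max_n
        return (1.0 + log(n)) / (1.0 + log(max_n)) if max_n > 1 else 1.0

    return [
        WordCloudEntry(term=t, n_studies=n, relative_size=size(n))
        for t, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
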