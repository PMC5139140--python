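"""Citation ingestion: RIS and EndNote export parsing, writing, deduplication.

Screening tools receive citation exports from bibliographic databases in a
handful of line-tagged plain-text formats.  This module reads the two most
common ones — RefMan RIS (``TY  - `` tags, records terminated by ``ER``) and
the EndNote export format (``%0``-prefixed tags) — into :class:`Citation`
records, writes RIS back out round-trip safely, and groups exact duplicates
arising from overlapping database searches.

Records that arrived corrupted (runs of question marks or Unicode replacement
characters where metadata should be, or a missing title) are kept but flagged
``malformed`` so reviewers can still see and repair them.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Citation",
    "ParseReport",
    "CitationFormatError",
    "parse_citations",
    "write_citations",
    "detect_exact_duplicates",
    "make_citation_id",
]


@dataclass
class Citation:
    """One bibliographic record under review.

    ``citation_id`` is stable across runs: it combines the zero-padded file
    position with a short content hash, so identical inputs always produce
    identical ids.  ``mesh_terms`` and ``language`` start empty/unknown and
    are filled in by the featurization step.
    """

    citation_id: str
    title: str
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    journal: str = ""
    year: int | None = None
    keywords: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    language: str | None = None
    source_file: str = ""
    malformed: bool = False

    def text(self) -> str:
        """Title and abstract joined — the screening text."""
        return f"{self.title} {self.abstract}".strip()

    def to_dict(self) -> dict:
        return {
            "citation_id": self.citation_id,
            "title": self.title,
            "abstract": self.abstract,
            "authors": list(self.authors),
            "journal": self.journal,
            "year": self.year,
            "keywords": list(self.keywords),
            "mesh_terms": list(self.mesh_terms),
            "language": self.language,
            "source_file": self.source_file,
            "malformed": self.malformed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Citation":
        return cls(**d)


@dataclass
class ParseReport:
    """Summary of one parse: record counts and per-record warnings."""

    n_parsed: int = 0
    n_malformed: int = 0
    warnings: list[tuple[str, str]] = field(default_factory=list)


class CitationFormatError(ValueError):
    """Raised when a citation file cannot be interpreted in the stated format."""


# Corruption markers seen in mangled uploads: replacement chars or >=3 '?'
_CORRUPT_RE = re.compile("\N{REPLACEMENT CHARACTER}|\\?{3,}")

# RIS tag line: two alphanumeric chars, then "  - " (canonical) or a lenient
# single-space variant; exports differ between databases.
_RIS_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])\s{1,2}-\s?(.*)$")
_ENDNOTE_TAG_RE = re.compile(r"^%([0-9A-Z@])\s?(.*)$")

_YEAR_RE = re.compile(r"\b(\d{4})\b")


def make_citation_id(index: int, *content: object) -> str:
    """Deterministic id: zero-padded position + 8-hex content hash."""
    digest = hashlib.sha1(repr(content).encode("utf-8")).hexdigest()[:8]
    return f"{index:05d}-{digest}"


def _read_text(path: Path, report: ParseReport) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        report.warnings.append(
            (str(path), "file is not valid UTF-8; decoded as Latin-1")
        )
        return raw.decode("latin-1")


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        if not line.strip():
            continue
        if _ENDNOTE_TAG_RE.match(line):
            return "endnote"
        if _RIS_TAG_RE.match(line):
            return "ris"
    return "ris"


def _parse_year(value: str) -> int | None:
    m = _YEAR_RE.search(value)
    return int(m.group(1)) if m else None


def _finish_record(
    fields: dict[str, list[str]],
    index: int,
    line_range: str,
    source_file: str,
    report: ParseReport,
) -> Citation:
    def first(*tags: str) -> str:
        for t in tags:
            if fields.get(t):
                return fields[t][0].strip()
        return ""

    title = first("TI", "T1")
    abstract = first("AB", "N2")
    authors = [a.strip() for a in fields.get("AU", []) + fields.get("A1", []) if a.strip()]
    journal = first("JO", "JF", "JA", "T2")
    year = _parse_year(first("PY", "Y1"))
    keywords = [k.strip() for k in fields.get("KW", []) if k.strip()]

    malformed = False
    if not title:
        malformed = True
        report.warnings.append((line_range, "record has no title"))
    if _CORRUPT_RE.search(title) or _CORRUPT_RE.search(abstract):
        malformed = True
        report.warnings.append(
            (line_range, "title/abstract contains corruption markers ('???' or �)")
        )

    cit = Citation(
        citation_id=make_citation_id(index, title, abstract, tuple(authors), year),
        title=title,
        abstract=abstract,
        authors=authors,
        journal=journal,
        year=year,
        keywords=keywords,
        source_file=source_file,
        malformed=malformed,
    )
    report.n_parsed += 1
    if malformed:
        report.n_malformed += 1
    return cit


def _parse_ris(text: str, source_file: str, report: ParseReport) -> list[Citation]:
    citations: list[Citation] = []
    fields: dict[str, list[str]] = {}
    start_line = 1
    last_tag: str | None = None
    saw_any_tag = False
    first_bad: tuple[int, str] | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _RIS_TAG_RE.match(line)
        if m:
            saw_any_tag = True
            tag, value = m.group(1), m.group(2)
            if tag == "ER":
                citations.append(
                    _finish_record(
                        fields, len(citations), f"{source_file}:{start_line}-{lineno}",
                        source_file, report,
                    )
                )
                fields = {}
                last_tag = None
                start_line = lineno + 1
            else:
                fields.setdefault(tag, []).append(value)
                last_tag = tag
        elif last_tag is not None:
            # continuation of a wrapped field value
            fields[last_tag][-1] += " " + line.strip()
        elif first_bad is None:
            first_bad = (lineno, line)

    if fields:  # trailing record without ER — accept leniently
        citations.append(
            _finish_record(
                fields, len(citations), f"{source_file}:{start_line}-end",
                source_file, report,
            )
        )
    if not citations and text.strip():
        bad = first_bad or (1, text.splitlines()[0])
        raise CitationFormatError(
            f"no RIS records parsed from {source_file}; "
            f"first offending line {bad[0]}: {bad[1]!r}"
        )
    if not saw_any_tag and citations:
        report.warnings.append((source_file, "no RIS tags recognized"))
    return citations


def _parse_endnote(text: str, source_file: str, report: ParseReport) -> list[Citation]:
    # %0 starts a record; map EndNote tags onto the RIS field names so both
    # formats share one record finisher.
    tag_map = {"T": "TI", "A": "AU", "D": "PY", "X": "AB", "J": "JO", "B": "T2", "K": "KW"}
    citations: list[Citation] = []
    fields: dict[str, list[str]] = {}
    start_line = 1
    in_record = False
    first_bad: tuple[int, str] | None = None

    def flush(end_line: int) -> None:
        nonlocal fields, in_record
        if in_record:
            citations.append(
                _finish_record(
                    fields, len(citations), f"{source_file}:{start_line}-{end_line}",
                    source_file, report,
                )
            )
        fields = {}
        in_record = False

    lines = text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        m = _ENDNOTE_TAG_RE.match(line)
        if not m:
            if first_bad is None:
                first_bad = (lineno, line)
            continue
        tag, value = m.group(1), m.group(2)
        if tag == "0":
            flush(lineno - 1)
            in_record = True
            start_line = lineno
        elif in_record and tag in tag_map:
            fields.setdefault(tag_map[tag], []).append(value)
    flush(len(lines))

    if not citations and text.strip():
        bad = first_bad or (1, lines[0] if lines else "")
        raise CitationFormatError(
            f"no EndNote records parsed from {source_file}; "
            f"first offending line {bad[0]}: {bad[1]!r}"
        )
    return citations


def parse_citations(
    path: str | Path, format: str = "auto"
) -> tuple[list[Citation], ParseReport]:
    """Parse a citation export file into records plus a parse report.

    Parameters
    ----------
    path
        RIS or EndNote export file.
    format
        ``"ris"``, ``"endnote"``, or ``"auto"`` (sniff by tag syntax:
        ``TY  - `` vs ``%0``).

    Returns
    -------
    (citations, report)
        Citations in file order with deterministic ids; the report counts
        parsed and malformed records and carries one warning per problem.
    """
    path = Path(path)
    if format not in {"ris", "endnote", "auto"}:
        raise ValueError(f"unknown format {format!r}")
    report = ParseReport()
    text = _read_text(path, report)
    if not text.strip():
        return [], report
    fmt = _sniff_format(text) if format == "auto" else format
    if fmt == "endnote":
        return _parse_endnote(text, path.name, report), report
    return _parse_ris(text, path.name, report), report


def write_citations(
    citations: Sequence[Citation], path: str | Path, format: str = "ris"
) -> None:
    """Write citations as RIS; ``parse(write(X))`` reproduces the core fields."""
    if format != "ris":
        raise ValueError(f"unsupported output format {format!r}")
    lines: list[str] = []
    for cit in citations:
        lines.append("TY  - JOUR")
        lines.append(f"TI  - {cit.title}")
        for author in cit.authors:
            lines.append(f"AU  - {author}")
        if cit.year is not None:
            lines.append(f"PY  - {cit.year}")
        if cit.journal:
            lines.append(f"JO  - {cit.journal}")
        if cit.abstract:
            lines.append(f"AB  - {cit.abstract}")
        for kw in cit.keywords:
            lines.append(f"KW  - {kw}")
        lines.append("ER  - ")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", _PUNCT_RE.sub(" ", text.lower())).strip()


def _first_author_surname(authors: Sequence[str]) -> str:
    if not authors:
        return ""
    first = authors[0]
    surname = first.split(",")[0] if "," in first else first.split()[-1] if first.split() else ""
    return _normalize(surname)


def detect_exact_duplicates(citations: Iterable[Citation]) -> list[list[Citation]]:
    """Group records identical on (normalized title, year, first-author surname).

    Exact/near-exact duplicates arise when the same study is exported from
    several databases.  Normalization is lowercase, punctuation stripped,
    whitespace collapsed.  Singletons are not reported; the returned groups
    are disjoint and each has at least two members, in file order.
    """
    groups: dict[tuple, list[Citation]] = {}
    for cit in citations:
        key = (_normalize(cit.title), cit.year, _first_author_surname(cit.authors))
        groups.setdefault(key, []).append(cit)
    return [members for members in groups.values() if len(members) >= 2]
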