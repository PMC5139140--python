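"""Citation similarity graph: edit-distance clustering of near-duplicates.

Citations become graph nodes; an edge connects two citations whose title,
abstract and author-list similarities all clear their per-attribute
thresholds and whose weighted overall similarity clears the overall
threshold.  Text similarity is a normalized Levenshtein measure
(1 − distance / longer length), so thresholds are scale-free; author
similarity is the Jaccard index over surname + first-initial keys.
Connected components of the resulting graph are the similarity clusters a
reviewer inspects for duplicate or related records.

Long abstracts are compared on a bounded prefix (default 1500 characters)
to keep the quadratic edit-distance cost predictable on large reviews.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from .citation_io import Citation

__all__ = [
    "SimilarityEdge",
    "SimilarityThresholds",
    "DEFAULT_WEIGHTS",
    "string_similarity",
    "author_similarity",
    "compute_similarities",
    "build_graph",
    "clusters",
    "write_edge_list",
]

DEFAULT_WEIGHTS = (0.4, 0.4, 0.2)  # title, abstract, authors
ABSTRACT_COMPARE_LIMIT = 1500


@dataclass(frozen=True)
class SimilarityThresholds:
    """Per-attribute and overall minimum similarities, each in [0, 1]."""

    t_title: float = 0.6
    t_abstract: float = 0.5
    t_authors: float = 0.3
    t_overall: float = 0.5

    def __post_init__(self) -> None:
        for name in ("t_title", "t_abstract", "t_authors", "t_overall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SimilarityEdge:
    """Unordered citation pair with per-field and combined similarities."""

    id_a: str
    id_b: str
    sim_title: float
    sim_abstract: float
    sim_authors: float
    sim_overall: float


def _levenshtein_py(a: str, b: str) -> int:
    # classic DP fallback; also the oracle edlib is checked against in tests
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _edit_distance(a: str, b: str) -> int:
    if _HAVE_EDLIB:
        try:
            return edlib.align(a, b)["editDistance"]
        except Exception:
            pass  # e.g. alphabet larger than edlib supports
    return _levenshtein_py(a, b)


_WS_RE = re.compile(r"\s+")


def _normalize_text(text: str) -> str:
    return _WS_RE.sub(" ", text.lower()).strip()


def string_similarity(a: str, b: str, max_len: int | None = None) -> float:
    """Normalized edit-distance similarity of two text fields.

    ``1 − Levenshtein(a, b) / max(len)`` on lowercased, whitespace-collapsed
    strings; two empty strings are identical (1.0).  ``max_len`` truncates
    both strings first (used to bound the cost on long abstracts).
    """
    a = _normalize_text(a)
    b = _normalize_text(b)
    if max_len is not None:
        a, b = a[:max_len], b[:max_len]
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - _edit_distance(a, b) / longest


_AUTHOR_PUNCT = re.compile(r"[^\w\s]")


def _author_key(name: str) -> str:
    """Normalize an author to 'surname + first initial' to survive the
    format variation between database exports (``Smith, J`` vs ``J Smith``)."""
    clean = _AUTHOR_PUNCT.sub(" ", name)
    if "," in name:
        parts = name.split(",", 1)
        surname = _AUTHOR_PUNCT.sub(" ", parts[0]).strip()
        rest = _AUTHOR_PUNCT.sub(" ", parts[1]).strip()
    else:
        tokens = clean.split()
        if not tokens:
            return ""
        surname, rest = tokens[-1], " ".join(tokens[:-1])
    initial = rest.strip()[:1]
    return f"{surname.strip().lower()} {initial.lower()}".strip()


def author_similarity(authors_a: Sequence[str], authors_b: Sequence[str]) -> float:
    """Jaccard index over normalized author keys; two empty lists → 0.0."""
    keys_a = {k for k in (_author_key(a) for a in authors_a) if k}
    keys_b = {k for k in (_author_key(b) for b in authors_b) if k}
    if not keys_a and not keys_b:
        return 0.0
    union = keys_a | keys_b
    return len(keys_a & keys_b) / len(union)


def _check_weights(weights: Sequence[float]) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9:
        raise ValueError(f"weights must be three values summing to 1, got {weights}")
    return w  # type: ignore[return-value]


def compute_similarities(
    citations: Sequence[Citation],
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    abstract_limit: int = ABSTRACT_COMPARE_LIMIT,
) -> list[SimilarityEdge]:
    """All-pairs similarities, threshold-free.

    Separating the O(n²) edit-distance work from thresholding lets callers
    sweep thresholds cheaply over the same corpus.
    """
    wt, wa, wau = _check_weights(weights)
    edges: list[SimilarityEdge] = []
    n = len(citations)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = citations[i], citations[j]
            st = string_similarity(a.title, b.title)
            sa = string_similarity(a.abstract, b.abstract, max_len=abstract_limit)
            sau = author_similarity(a.authors, b.authors)
            edges.append(
                SimilarityEdge(
                    id_a=a.citation_id,
                    id_b=b.citation_id,
                    sim_title=st,
                    sim_abstract=sa,
                    sim_authors=sau,
                    sim_overall=wt * st + wa * sa + wau * sau,
                )
            )
    return edges


def filter_edges(
    edges: Iterable[SimilarityEdge],
    thresholds: SimilarityThresholds,
    conjunctive: bool = True,
) -> list[SimilarityEdge]:
    """Apply thresholds to precomputed similarities.

    Conjunctive (default): every per-attribute similarity must clear its
    threshold AND the overall similarity must clear the overall threshold.
    Disjunctive: any per-attribute pass suffices, still subject to the
    overall threshold.
    """
    out = []
    for e in edges:
        attrs = (
            e.sim_title >= thresholds.t_title,
            e.sim_abstract >= thresholds.t_abstract,
            e.sim_authors >= thresholds.t_authors,
        )
        attr_ok = all(attrs) if conjunctive else any(attrs)
        if attr_ok and e.sim_overall >= thresholds.t_overall:
            out.append(e)
    return out


def build_graph(
    citations: Sequence[Citation],
    thresholds: SimilarityThresholds | None = None,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    conjunctive: bool = True,
    abstract_limit: int = ABSTRACT_COMPARE_LIMIT,
    precomputed: Sequence[SimilarityEdge] | None = None,
) -> nx.Graph:
    """Build the thresholded similarity graph over a set of citations.

    Every citation is a node (so isolates appear as singleton clusters);
    edges carry the per-field and overall similarities as attributes.
    Raising any threshold can only remove edges, never add them.
    """
    if len(citations) < 2:
        raise ValueError("a similarity graph needs at least two citations")
    thresholds = thresholds or SimilarityThresholds()
    edges = (
        precomputed
        if precomputed is not None
        else compute_similarities(citations, weights, abstract_limit)
    )
    g = nx.Graph()
    for c in citations:
        g.add_node(c.citation_id)
    for e in filter_edges(edges, thresholds, conjunctive=conjunctive):
        g.add_edge(
            e.id_a,
            e.id_b,
            sim_title=e.sim_title,
            sim_abstract=e.sim_abstract,
            sim_authors=e.sim_authors,
            sim_overall=e.sim_overall,
        )
    return g


def clusters(graph: nx.Graph) -> list[set[str]]:
    """Connected components as citation-id sets (singletons included).

    Components are sorted by size descending, then by smallest member id,
    so output order is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Export the graph as a TSV edge list with similarity columns."""
    lines = ["id_a\tid_b\tsim_title\tsim_abstract\tsim_authors\tsim_overall"]
    for a, b, data in sorted(graph.edges(data=True)):
        lines.append(
            f"{a}\t{b}\t{data['sim_title']:.4f}\t{data['sim_abstract']:.4f}"
            f"\t{data['sim_authors']:.4f}\t{data['sim_overall']:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n", "utf-8")
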