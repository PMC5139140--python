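"""Text featurization for screening classification.

The screening classifier sees each citation as a bag of features built from
the title and abstract: stopword-filtered, Porter-stemmed unigrams; bigrams
of adjacent surviving tokens (title and abstract tokenized separately, so no
bigram spans the boundary); and binary indicators for MeSH terms matched by
dictionary lookup.  A :class:`FeatureSpace` fixes the corpus vocabulary and
weighting so vectors from different citations are comparable.

Also here: the metadata computed at upload time — dictionary MeSH assignment
and a stopword-profile language guess.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from ._porter import porter_stem
from .citation_io import Citation

__all__ = [
    "FeatureBag",
    "FeatureSpace",
    "preprocess",
    "extract_features",
    "featurize_citation",
    "assign_mesh",
    "detect_language",
    "build_feature_space",
    "vectorize",
    "vectorize_corpus",
]

_TOKEN_RE = re.compile(r"[^0-9a-zà-öø-ÿ]+")
_WORD_RE = re.compile(r"[a-zà-öø-ÿ']+")

STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)


def preprocess(text: str) -> list[str]:
    """Tokenize screening text into stemmed content terms.

    Lowercases, splits on non-alphanumerics, drops pure numbers,
    single-character tokens and English stopwords, then Porter-stems.
    """
    tokens: list[str] = []
    for raw in _TOKEN_RE.split(text.lower()):
        if len(raw) <= 1 or raw.isdigit() or raw in STOPWORDS:
            continue
        tokens.append(porter_stem(raw))
    return tokens


@dataclass
class FeatureBag:
    """Per-citation feature counts: unigrams, adjacent bigrams, MeSH flags."""

    unigrams: Counter = field(default_factory=Counter)
    bigrams: Counter = field(default_factory=Counter)
    mesh: set = field(default_factory=set)

    def keys(self) -> list[str]:
        """Namespaced feature keys (``u:``, ``b:``, ``m:``)."""
        out = [f"u:{t}" for t in self.unigrams]
        out += [f"b:{a}|{b}" for a, b in self.bigrams]
        out += [f"m:{t}" for t in self.mesh]
        return out

    def get(self, key: str) -> float:
        ns, _, rest = key.partition(":")
        if ns == "u":
            return float(self.unigrams.get(rest, 0))
        if ns == "b":
            a, _, b = rest.partition("|")
            return float(self.bigrams.get((a, b), 0))
        if ns == "m":
            return 1.0 if rest in self.mesh else 0.0
        raise KeyError(key)


def extract_features(
    token_fields: Sequence[Sequence[str]] | Sequence[str],
    mesh_terms: Iterable[str] = (),
) -> FeatureBag:
    """Build a feature bag from tokenized text fields.

    ``token_fields`` is either one token sequence or a list of sequences
    (e.g. title tokens and abstract tokens); bigrams pair adjacent tokens
    within a field only, never across the field boundary.
    """
    if token_fields and isinstance(token_fields[0], str):
        fields: list[Sequence[str]] = [token_fields]  # type: ignore[list-item]
    else:
        fields = list(token_fields)  # type: ignore[arg-type]
    bag = FeatureBag()
    for toks in fields:
        bag.unigrams.update(toks)
        bag.bigrams.update(zip(toks, toks[1:]))
    bag.mesh = {t.lower() for t in mesh_terms}
    return bag


def featurize_citation(citation: Citation) -> FeatureBag:
    """Tokenize a citation's title and abstract separately and extract features."""
    return extract_features(
        [preprocess(citation.title), preprocess(citation.abstract)],
        citation.mesh_terms,
    )


def _phrase_pattern(phrase: str) -> re.Pattern:
    words = [re.escape(w) for w in phrase.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def assign_mesh(citation: Citation, vocabulary: Sequence[str]) -> list[str]:
    """Match a controlled vocabulary against title + abstract + keywords.

    Case-insensitive whole-phrase matching; each term reported once, in
    vocabulary order.  This is deliberately a dictionary lookup, not a full
    indexing pipeline: the vocabulary file (one term per line) defines what
    can be found.
    """
    haystack = " ".join([citation.title, citation.abstract, *citation.keywords])
    found: list[str] = []
    seen = set()
    for term in vocabulary:
        t = term.strip().lower()
        if not t or t in seen:
            continue
        if _phrase_pattern(t).search(haystack):
            found.append(t)
            seen.add(t)
    return found


def _load_profile(name: str) -> frozenset[str]:
    text = resources.files("screenlite.data").joinpath(name).read_text("utf-8")
    words = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        words.update(line.split())
    return frozenset(words)


_LANGUAGE_PROFILES: dict[str, frozenset[str]] = {}


def _profiles() -> dict[str, frozenset[str]]:
    if not _LANGUAGE_PROFILES:
        _LANGUAGE_PROFILES["en"] = STOPWORDS
        for code in ("es", "fr", "de"):
            _LANGUAGE_PROFILES[code] = _load_profile(f"stopwords_{code}.txt")
    return _LANGUAGE_PROFILES


def detect_language(
    citation: Citation, min_tokens: int = 20, min_hit_rate: float = 0.08
) -> str:
    """Guess the article language from stopword-profile hit rates.

    Function words are frequent and language-specific, so the share of
    tokens found in each language's stopword list separates the built-in
    languages (en, es, fr, de) reliably on abstract-length text.  Texts
    shorter than ``min_tokens`` tokens, or with no profile reaching
    ``min_hit_rate``, return ``"unknown"``.
    """
    tokens = _WORD_RE.findall(citation.text().lower())
    if len(tokens) < min_tokens:
        return "unknown"
    best_code, best_rate = "unknown", min_hit_rate
    for code, profile in sorted(_profiles().items()):
        rate = sum(1 for t in tokens if t in profile) / len(tokens)
        if rate > best_rate:
            best_code, best_rate = code, rate
    return best_code


@dataclass
class FeatureSpace:
    """Corpus vocabulary with document frequencies and a weighting scheme.

    weighting: ``"binary"`` (presence), ``"tf"`` (raw count) or ``"tfidf"``
    (count × smoothed idf, L2-normalized per document).
    """

    vocabulary: list[str]
    document_frequency: dict[str, int]
    n_documents: int
    weighting: str = "tfidf"

    def __post_init__(self) -> None:
        self._index = {k: i for i, k in enumerate(self.vocabulary)}

    def __len__(self) -> int:
        return len(self.vocabulary)

    def index(self, key: str) -> int | None:
        return self._index.get(key)

    def idf(self, key: str) -> float:
        df = self.document_frequency.get(key, 0)
        return math.log((1 + self.n_documents) / (1 + df)) + 1.0


def build_feature_space(
    corpus: Sequence[FeatureBag], min_df: int = 2, weighting: str = "tfidf"
) -> FeatureSpace:
    """Fix the vocabulary over a corpus of feature bags.

    Keys seen in fewer than ``min_df`` documents are dropped; the retained
    vocabulary is sorted lexicographically so runs are reproducible.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if weighting not in {"binary", "tf", "tfidf"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    df: Counter = Counter()
    for bag in corpus:
        df.update(set(bag.keys()))
    vocab = sorted(k for k, c in df.items() if c >= min_df)
    return FeatureSpace(
        vocabulary=vocab,
        document_frequency={k: df[k] for k in vocab},
        n_documents=len(corpus),
        weighting=weighting,
    )


def vectorize(bag: FeatureBag, space: FeatureSpace) -> sp.csr_matrix:
    """Project one feature bag onto the corpus vocabulary (1 × |V| sparse row)."""
    cols: list[int] = []
    vals: list[float] = []
    for key in bag.keys():
        j = space.index(key)
        if j is None:
            continue
        count = bag.get(key)
        if space.weighting == "binary":
            v = 1.0
        elif space.weighting == "tf":
            v = count
        else:
            v = count * space.idf(key)
        cols.append(j)
        vals.append(v)
    row = sp.csr_matrix(
        (vals, (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(space)),
    )
    if space.weighting == "tfidf":
        norm = sp.linalg.norm(row)
        if norm > 0:
            row = row / norm
    return sp.csr_matrix(row)


def vectorize_corpus(
    bags: Sequence[FeatureBag], space: FeatureSpace
) -> sp.csr_matrix:
    """Stack per-citation vectors into an (n × |V|) sparse matrix."""
    if not bags:
        return sp.csr_matrix((0, len(space)))
    return sp.csr_matrix(sp.vstack([vectorize(b, space) for b in bags]))


def load_term_file(path: str | Path) -> list[str]:
    """Read a one-term-per-line vocabulary file ('#' comments allowed)."""
    terms = []
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.append(line.lower())
    return terms
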