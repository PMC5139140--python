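"""Synthetic screening corpora with controlled prevalence and topical signal.

Real screening corpora are a large pool of citations of which only a few
percent end up included, and the included ones share a distinguishable
vocabulary (trial-design terms in a drug-effectiveness review, say) against
the shared background language.  The generator reproduces exactly that
structure so every downstream component — parsing, featurization,
classification, evaluation, the similarity graph — can be exercised without
downloading any external collection:

* exactly ``round(n_citations * prevalence)`` citations are labeled
  included, mirroring benchmark collections whose included fraction ranges
  from under 1% to roughly 20%;
* excluded citations draw tokens i.i.d. from a Zipf-weighted background
  vocabulary (natural language is heavy-tailed, and a realistic
  document-frequency profile matters for the TF-IDF features);
* included citations draw each token from a signal vocabulary with
  probability ``signal_strength``, otherwise from the background.
  ``signal_strength = 0`` makes the two classes statistically identical
  (a null corpus); ``1.0`` makes them perfectly separable.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .citation_io import Citation, make_citation_id

__all__ = ["CorpusSpec", "generate", "inject_near_duplicates"]

# Trial-design vocabulary used as the topical signal of included citations.
_SIGNAL_TERMS = [
    "randomized", "placebo", "blinding", "allocation", "concealment",
    "intervention", "efficacy", "endpoint", "enrollment", "baseline",
    "multicenter", "crossover", "dropout", "adherence", "dosage",
    "masking", "recruitment", "randomization", "arms", "washout",
    "superiority", "noninferiority", "tolerability", "titration",
    "comparator", "outcome", "followup", "protocol", "eligibility",
    "stratification",
]

_SYLLABLES = [
    "ba", "be", "bi", "bo", "bu", "da", "de", "di", "do", "du", "fa", "fe",
    "fi", "fo", "ga", "ge", "gi", "go", "ka", "ke", "ki", "ko", "la", "le",
    "li", "lo", "ma", "me", "mi", "mo", "na", "ne", "ni", "no", "pa", "pe",
    "pi", "po", "ra", "re", "ri", "ro", "sa", "se", "si", "so", "ta", "te",
    "ti", "to", "va", "ve", "vi", "vo", "za", "ze", "zi", "zo",
]

_SURNAMES = [
    "Smith", "Jones", "Garcia", "Kim", "Chen", "Patel", "Müller", "Rossi",
    "Silva", "Kowalski", "Haddad", "Okafor", "Tanaka", "Novak", "Hansen",
    "Dubois", "Costa", "Ali", "Nguyen", "Ivanov", "Johnson", "Brown",
    "Martinez", "Lee", "Wang", "Singh", "Weber", "Ferrari", "Santos",
    "Nowak", "Mansour", "Adeyemi", "Sato", "Svoboda", "Larsen", "Moreau",
    "Pereira", "Hassan", "Tran", "Petrov",
]

_JOURNALS = [
    "Journal of Clinical Studies",
    "Annals of Internal Research",
    "International Trials Review",
    "Evidence and Practice",
    "Clinical Outcomes Quarterly",
    "Archives of Therapeutics",
    "Primary Care Reports",
    "Global Health Letters",
]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic screening corpus.

    ``prevalence`` is the included fraction; ``signal_strength`` the
    per-token probability that an included citation's token comes from the
    signal vocabulary; token counts are Poisson around the stated means
    (titles never drop below 3 tokens).
    """

    n_citations: int = 1000
    prevalence: float = 0.1
    signal_strength: float = 0.8
    vocab_background: int = 2000
    vocab_signal: int = 30
    title_length: float = 10.0
    abstract_length: float = 120.0
    n_authors_range: tuple[int, int] = (1, 6)
    year_range: tuple[int, int] = (1995, 2020)
    zipf_exponent: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_citations < 1:
            raise ValueError("n_citations must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if round(self.n_citations * self.prevalence) < 1:
            raise ValueError("prevalence * n_citations must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.vocab_background < 1 or self.vocab_signal < 1:
            raise ValueError("vocabulary sizes must be >= 1")
        if not 1 <= self.n_authors_range[0] <= self.n_authors_range[1]:
            raise ValueError("n_authors_range must be an increasing pair >= 1")


def _background_vocabulary(size: int, signal: set[str]) -> list[str]:
    words: list[str] = []
    seen: set[str] = set(signal)
    i = 0
    while len(words) < size:
        # deterministic pseudo-words from syllable pairs/triples
        parts = [
            _SYLLABLES[(i // len(_SYLLABLES) ** k) % len(_SYLLABLES)]
            for k in range(2 + (i % 2))
        ]
        w = "".join(parts)
        i += 1
        if w not in seen:
            words.append(w)
            seen.add(w)
    return words


def _signal_vocabulary(size: int) -> list[str]:
    vocab = list(_SIGNAL_TERMS[:size])
    k = 0
    while len(vocab) < size:
        vocab.append(f"trialterm{k:03d}")
        k += 1
    return vocab


def generate(spec: CorpusSpec) -> tuple[list[Citation], dict[str, str]]:
    """Generate one corpus; returns (citations, gold labels by citation id).

    Labels are ``"included"`` / ``"excluded"``; the included count is exactly
    ``round(n_citations * prevalence)``.  Identical specs (including seed)
    yield byte-identical corpora.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    signal_vocab = _signal_vocabulary(spec.vocab_signal)
    background = _background_vocabulary(spec.vocab_background, set(signal_vocab))
    ranks = np.arange(1, len(background) + 1, dtype=float)
    bg_weights = ranks ** -spec.zipf_exponent
    bg_weights /= bg_weights.sum()

    n_included = int(round(spec.n_citations * spec.prevalence))
    included_idx = set(
        rng.choice(spec.n_citations, size=n_included, replace=False).tolist()
    )

    def draw_tokens(n: int, included: bool) -> list[str]:
        bg = rng.choice(len(background), size=n, p=bg_weights)
        toks = [background[j] for j in bg]
        if included and spec.signal_strength > 0:
            mask = rng.random(n) < spec.signal_strength
            sig = rng.choice(len(signal_vocab), size=n)
            toks = [
                signal_vocab[sig[k]] if mask[k] else toks[k] for k in range(n)
            ]
        return toks

    citations: list[Citation] = []
    labels: dict[str, str] = {}
    for i in range(spec.n_citations):
        included = i in included_idx
        n_title = max(3, int(rng.poisson(spec.title_length)))
        n_abstract = int(rng.poisson(spec.abstract_length))
        title_toks = draw_tokens(n_title, included)
        abstract_toks = draw_tokens(n_abstract, included)
        title = " ".join(title_toks).capitalize()
        abstract = (" ".join(abstract_toks).capitalize() + ".") if abstract_toks else ""
        n_authors = int(rng.integers(spec.n_authors_range[0], spec.n_authors_range[1] + 1))
        authors = [
            f"{_SURNAMES[int(rng.integers(len(_SURNAMES)))]}, "
            f"{string.ascii_uppercase[int(rng.integers(26))]}"
            for _ in range(n_authors)
        ]
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        cit = Citation(
            citation_id=make_citation_id(i, title, abstract, tuple(authors), year),
            title=title,
            abstract=abstract,
            authors=authors,
            journal=_JOURNALS[int(rng.integers(len(_JOURNALS)))],
            year=year,
            source_file="synthetic",
        )
        citations.append(cit)
        labels[cit.citation_id] = "included" if included else "excluded"
    return citations, labels


def inject_near_duplicates(
    citations: Sequence[Citation],
    n_pairs: int,
    edit_rate: float,
    seed: int = 0,
) -> tuple[list[Citation], dict[str, str]]:
    """Append perturbed copies of sampled citations.

    Each of ``n_pairs`` sampled citations gets a copy whose title and
    abstract have a fraction ``edit_rate`` of characters substituted
    (``edit_rate=0`` yields exact copies).  Returns the extended corpus and
    a provenance map from each duplicate's id to its source id — the ground
    truth for similarity-graph tests.
    """
    if n_pairs > len(citations):
        raise ValueError("n_pairs cannot exceed the corpus size")
    if not 0.0 <= edit_rate <= 1.0:
        raise ValueError("edit_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    letters = string.ascii_lowercase

    def perturb(text: str) -> str:
        if edit_rate == 0.0 or not text:
            return text
        chars = list(text)
        for k in range(len(chars)):
            if rng.random() < edit_rate:
                chars[k] = letters[int(rng.integers(26))]
        return "".join(chars)

    out = list(citations)
    provenance: dict[str, str] = {}
    picks = rng.choice(len(citations), size=n_pairs, replace=False)
    for offset, idx in enumerate(sorted(int(p) for p in picks)):
        src = citations[idx]
        title = perturb(src.title)
        abstract = perturb(src.abstract)
        dup = Citation(
            citation_id=make_citation_id(
                len(citations) + offset, title, abstract, tuple(src.authors), src.year
            ),
            title=title,
            abstract=abstract,
            authors=list(src.authors),
            journal=src.journal,
            year=src.year,
            keywords=list(src.keywords),
            source_file=src.source_file,
        )
        out.append(dup)
        provenance[dup.citation_id] = src.citation_id
    return out, provenance
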