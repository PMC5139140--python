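import pytest

from screenlite.citation_io import Citation
from screenlite.decisions import Review, record_decision
from screenlite.synthetic import CorpusSpec, generate


def make_citation(cid: str, title: str, **kw) -> Citation:
    return Citation(citation_id=cid, title=title, **kw)


@pytest.fixture
def small_review() -> Review:
    """Ten citations, two reviewers, a mix of verdicts."""
    citations = [
        make_citation(f"c{i}", f"Study number {i}", abstract=f"Abstract {i}")
        for i in range(10)
    ]
    review = Review(citations=citations)
    record_decision(review, "c0", "A", "included")
    record_decision(review, "c1", "A", "included")
    record_decision(review, "c2", "A", "excluded", ["wrong population"])
    record_decision(review, "c3", "A", "excluded", ["wrong study design"])
    record_decision(review, "c4", "A", "undecided")
    record_decision(review, "c0", "B", "included")
    record_decision(review, "c2", "B", "included")  # conflict with A on c2
    record_decision(review, "c5", "B", "excluded", ["wrong population"])
    return review


@pytest.fixture(scope="session")
def strong_corpus():
    """Small separable synthetic corpus shared across classifier tests."""
    spec = CorpusSpec(
        n_citations=120, prevalence=0.15, signal_strength=0.9,
        abstract_length=60.0, seed=11,
    )
    return generate(spec)
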