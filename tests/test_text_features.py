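import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from screenlite._porter import porter_stem
from screenlite.citation_io import Citation
from screenlite.text_features import (
    assign_mesh,
    build_feature_space,
    detect_language,
    extract_features,
    featurize_citation,
    preprocess,
    vectorize,
)

# Reference behavior of the published Porter algorithm (full run, all steps).
PORTER_REFERENCE = {
    "caresses": "caress", "ponies": "poni", "ties": "ti", "cats": "cat",
    "feed": "feed", "agreed": "agre", "plastered": "plaster",
    "motoring": "motor", "sing": "sing", "conflated": "conflat",
    "sized": "size", "hopping": "hop", "falling": "fall", "filing": "file",
    "happy": "happi", "sky": "sky", "relational": "relat",
    "conditional": "condit", "rational": "ration", "digitizer": "digit",
    "operator": "oper", "feudalism": "feudal", "decisiveness": "decis",
    "hopefulness": "hope", "triplicate": "triplic", "formative": "form",
    "formalize": "formal", "electrical": "electr", "hopeful": "hope",
    "goodness": "good", "revival": "reviv", "allowance": "allow",
    "inference": "infer", "adjustable": "adjust", "defensible": "defens",
    "irritant": "irrit", "replacement": "replac", "adjustment": "adjust",
    "dependent": "depend", "adoption": "adopt", "communism": "commun",
    "activate": "activ", "effective": "effect", "rate": "rate",
    "controlled": "control", "trials": "trial", "randomized": "random",
    "screening": "screen", "analyses": "analys", "studies": "studi",
}


@pytest.mark.parametrize("word,stem", sorted(PORTER_REFERENCE.items()))
def test_porter_reference_vocabulary(word, stem):
    assert porter_stem(word) == stem


def test_preprocess_stopwords_and_stemming():
    assert preprocess("") == []
    assert preprocess("of the trials") == ["trial"]
    assert preprocess("controlled trials") == ["control", "trial"]


def test_preprocess_drops_numbers_and_single_chars():
    assert preprocess("a 123 x trial 2020") == ["trial"]


@given(st.text(alphabet=st.characters(codec="ascii"), max_size=120))
@settings(max_examples=100, deadline=None)
def test_preprocess_output_is_clean(text):
    toks = preprocess(text)
    from screenlite.text_features import STOPWORDS

    assert all(t and t not in STOPWORDS for t in toks)


def test_bigrams_are_adjacent_pairs():
    bag = extract_features(["a", "b", "c"])
    assert bag.unigrams == {"a": 1, "b": 1, "c": 1}
    assert bag.bigrams == {("a", "b"): 1, ("b", "c"): 1}
    assert extract_features(["a"]).bigrams == {}


def test_bigrams_do_not_cross_title_abstract_boundary():
    bag = extract_features([["a", "b"], ["c", "d"]])
    assert ("b", "c") not in bag.bigrams
    assert bag.bigrams == {("a", "b"): 1, ("c", "d"): 1}


def test_bigram_count_identity():
    c = Citation("c1", "Randomized aspirin trial outcome",
                 abstract="Control group received placebo daily dosing")
    bag = featurize_citation(c)
    nt = len(preprocess(c.title))
    na = len(preprocess(c.abstract))
    assert sum(bag.bigrams.values()) == max(0, nt - 1) + max(0, na - 1)
    # every bigram part appears as a unigram of the same citation
    for a, b in bag.bigrams:
        assert a in bag.unigrams and b in bag.unigrams


def test_mesh_features_are_binary():
    bag = extract_features(["a", "b"], mesh_terms=["Humans"])
    assert bag.get("m:humans") == 1.0
    assert "m:humans" in bag.keys()


def test_assign_mesh_whole_phrase_once():
    c = Citation("c1", "Trial of therapy",
                 abstract="Conducted in humans; humans were screened. Humanoid robots excluded.")
    assert assign_mesh(c, ["humans"]) == ["humans"]  # whole word, reported once
    assert assign_mesh(c, []) == []
    assert assign_mesh(c, ["drug therapy"]) == []


def test_assign_mesh_searches_keywords_field():
    c = Citation("c1", "Short title", keywords=["Aspirin"])
    assert assign_mesh(c, ["aspirin"]) == ["aspirin"]


def test_language_detection_en_es_unknown():
    en = Citation("e", "T", abstract=(
        "We conducted a study of the effects of this drug and found that "
        "the treatment was better than the control in most of the patients."))
    es = Citation("s", "T", abstract=(
        "Se realizó un estudio de los efectos de este fármaco y se encontró "
        "que el tratamiento fue mejor que el control en la mayoría de los pacientes."))
    short = Citation("u", "", abstract="")
    assert detect_language(en) == "en"
    assert detect_language(es) == "es"
    assert detect_language(short) == "unknown"


def test_feature_space_min_df_and_determinism():
    bags = [extract_features(t) for t in (["a", "b"], ["a", "c"], ["c"])]
    space = build_feature_space(bags, min_df=2)
    assert "u:a" in space.vocabulary and "u:c" in space.vocabulary
    assert "u:b" not in space.vocabulary
    space2 = build_feature_space(bags, min_df=2)
    assert space.vocabulary == space2.vocabulary == sorted(space.vocabulary)


def test_feature_space_rejects_empty_corpus():
    with pytest.raises(ValueError):
        build_feature_space([], min_df=1)


def test_vectorize_weightings():
    bags = [extract_features(["a", "a", "a", "b"]), extract_features(["a", "b"])]
    for weighting, expected_a in (("binary", 1.0), ("tf", 3.0)):
        space = build_feature_space(bags, min_df=1, weighting=weighting)
        v = vectorize(bags[0], space).toarray().ravel()
        assert v[space.index("u:a")] == expected_a


def test_vectorize_ignores_out_of_vocabulary():
    bags = [extract_features(["a", "b"]), extract_features(["a", "b"])]
    space = build_feature_space(bags, min_df=2, weighting="tf")
    novel = extract_features(["z", "q"])
    assert vectorize(novel, space).nnz == 0
    v = vectorize(extract_features([]), space)
    assert v.shape == (1, len(space)) and v.nnz == 0


def test_vectorize_tfidf_rows_unit_norm():
    bags = [extract_features(["a", "b", "c"]), extract_features(["a", "b"])]
    space = build_feature_space(bags, min_df=1, weighting="tfidf")
    v = vectorize(bags[0], space).toarray().ravel()
    assert np.isclose(np.linalg.norm(v), 1.0)
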