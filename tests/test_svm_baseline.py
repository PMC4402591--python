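import math

import numpy as np
import pytest

from kdse import build_index
from kdse.lexicon_kb import KnownPairKB
from kdse.svm_baseline import (
    SVMConfig,
    analyze,
    build_training_set,
    load_model,
    make_vectorizer,
    porter_stem,
    save_model,
    svm_extract,
    train,
)
from kdse.synthetic_corpus import SynthParams, generate


@pytest.mark.parametrize(
    "word,stem",
    [
        ("caresses", "caress"),
        ("ponies", "poni"),
        ("running", "run"),
        ("agreed", "agre"),
        ("relational", "relat"),
        ("conditional", "condit"),
        ("toxicity", "toxic"),
        ("vomiting", "vomit"),
        ("hopeful", "hope"),
        ("nausea", "nausea"),
        ("sky", "sky"),
    ],
)
def test_porter_stemmer_canonical_cases(word, stem):
    assert porter_stem(word) == stem


def test_analyzer_drops_stopwords_and_stems():
    assert analyze("The toxicity was observed in patients") == [
        "toxic",
        "observ",
        "patient",
    ]
    assert analyze("the and of was") == []


def test_tfidf_matches_hand_computation():
    """TF-IDF equals the closed form idf=ln((1+N)/(1+df))+1 with L2 rows."""
    docs = ["nausea vomiting", "nausea fatigue", "severe fatigue"]
    vec = make_vectorizer()
    X = vec.fit_transform(docs).toarray()
    vocab = vec.vocabulary_
    n = len(docs)
    tokens = [analyze(d) for d in docs]
    df = {t: sum(t in doc for doc in tokens) for t in vocab}
    expected = np.zeros_like(X)
    for i, doc in enumerate(tokens):
        for t in doc:
            expected[i, vocab[t]] += math.log((1 + n) / (1 + df[t])) + 1
        norm = np.linalg.norm(expected[i])
        if norm:
            expected[i] /= norm
    assert np.allclose(X, expected)


def test_stopword_only_sentence_gives_zero_vector():
    vec = make_vectorizer()
    X = vec.fit_transform(["nausea was seen", "the and of"])
    assert X[1].nnz == 0
    Y = vec.fit_transform(["same nausea text", "same nausea text"])
    assert np.allclose(Y[0].toarray(), Y[1].toarray())


@pytest.fixture(scope="module")
def trained():
    bundle = generate(
        SynthParams(n_drugs=15, n_ses=36, n_abstracts=60, confound_rate=0.3, seed=21)
    )
    idx = build_index(bundle.corpus, bundle.drugs, bundle.ses)
    ls = build_training_set(idx, bundle.truth, seed=21)
    model = train(ls, SVMConfig(seed=21))
    return bundle, idx, ls, model


def test_training_set_matches_brute_force_and_is_balanced(trained):
    from test_corpus_index import _contains_term

    bundle, idx, ls, _ = trained
    expected_pos = set()
    for ab in bundle.corpus:
        for s in ab.sentences:
            if any(
                _contains_term(s.text, d) and _contains_term(s.text, se)
                for d, se in bundle.truth
            ):
                expected_pos.add(s.unit_id)
    assert set(ls.positive_ids) == expected_pos
    assert len(ls.positive_ids) == len(ls.negative_ids)
    assert not set(ls.negative_ids) & expected_pos


def test_training_set_deterministic(trained):
    bundle, idx, ls, _ = trained
    again = build_training_set(idx, bundle.truth, seed=21)
    assert again.positive_ids == ls.positive_ids
    assert again.negative_ids == ls.negative_ids


def test_no_negatives_is_an_error():
    """A corpus where every sentence carries a known pair has no negatives."""
    from kdse.corpus_index import make_abstract
    from kdse.lexicon_kb import Lexicon

    drugs = Lexicon(kind="drug")
    drugs.add("alphaol", "alphaol")
    ses = Lexicon(kind="side_effect")
    ses.add("betaemia", "betaemia")
    corpus = [
        make_abstract(f"p{i}", ["Alphaol toxicity included betaemia."])
        for i in range(4)
    ]
    idx = build_index(corpus, drugs, ses)
    kb = KnownPairKB(frozenset({("alphaol", "betaemia")}))
    with pytest.raises(ValueError, match="insufficient negatives"):
        build_training_set(idx, kb, seed=0)


def test_separable_toy_problem_cross_validates_perfectly():
    pos = [f"severe nausea and vomiting case {i}" for i in range(12)]
    neg = [f"enrollment criteria and consent form {i}" for i in range(12)]
    from kdse.svm_baseline import LabeledSentenceSet

    texts = {f"p:{i}": t for i, t in enumerate(pos)}
    texts |= {f"n:{i}": t for i, t in enumerate(neg)}
    ls = LabeledSentenceSet(
        positive_ids=sorted(t for t in texts if t.startswith("p")),
        negative_ids=sorted(t for t in texts if t.startswith("n")),
        texts=texts,
        labeling_pairs=frozenset({("d", "s")}),
    )
    model = train(ls, SVMConfig(seed=0))
    assert model.metadata["cv_accuracy"] == 1.0


def test_shuffled_labels_cross_validate_near_chance():
    import random

    rng = random.Random(0)
    words = ["alpha", "beta", "gamma", "delta", "omega", "kappa", "sigma", "zeta"]
    texts = {
        f"u:{i}": " ".join(rng.choices(words, k=6)) for i in range(120)
    }
    ids = sorted(texts)
    rng.shuffle(ids)
    from kdse.svm_baseline import LabeledSentenceSet

    ls = LabeledSentenceSet(
        positive_ids=ids[:60],
        negative_ids=ids[60:],
        texts=texts,
        labeling_pairs=frozenset({("d", "s")}),
    )
    model = train(ls, SVMConfig(seed=0))
    assert abs(model.metadata["cv_accuracy"] - 0.5) < 0.15


def test_single_class_input_is_an_error():
    from kdse.svm_baseline import LabeledSentenceSet

    with pytest.raises(ValueError, match="class counts"):
        LabeledSentenceSet(
            positive_ids=["a"], negative_ids=[], texts={"a": "x"}, labeling_pairs=frozenset()
        )


def test_training_is_deterministic_given_seed(trained):
    bundle, idx, ls, model = trained
    model2 = train(ls, SVMConfig(seed=21))
    probe = ls.sentences[:25]
    assert np.allclose(model.decision_function(probe), model2.decision_function(probe))


def test_model_roundtrip_preserves_decisions(tmp_path, trained):
    _, _, ls, model = trained
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    probe = ls.sentences[:25]
    assert np.allclose(
        model.decision_function(probe), back.decision_function(probe)
    )
    assert (model.predict(probe) == back.predict(probe)).all()


class _ConstantModel:
    """Stub classifier used to check the reduction properties."""

    def __init__(self, value: bool):
        self.value = value

    def predict(self, sentences):
        return np.full(len(sentences), self.value, dtype=bool)


def test_all_negative_classifier_extracts_nothing(trained):
    _, idx, _, _ = trained
    result = svm_extract(idx, _ConstantModel(False))
    assert result.all_candidates == []


def test_all_positive_classifier_equals_ungated_extraction(trained):
    from kdse.kd_extraction import naive_cooccurrence

    bundle, idx, _, _ = trained
    result = svm_extract(idx, _ConstantModel(True))
    naive = naive_cooccurrence(idx)
    assert result.all_pairs() == naive.all_pairs()
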