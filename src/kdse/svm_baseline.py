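"""Supervised baseline: a distantly-labeled TF-IDF + polynomial-kernel SVM.

The comparison system classifies sentences as side-effect-related or not with
a support vector machine over bag-of-words features (TF-IDF weighting,
stopword removal, Porter stemming), trained on distant labels: positives are
sentences containing at least one known drug-SE pair, negatives an equal-size
random sample of the remaining sentences.  Extraction then applies the same
co-occurrence enumeration as the knowledge-driven method, but to positively
classified sentences.

The kernel degree and cost parameter are configuration (defaults: degree 1,
C 1) — the original description names a polynomial kernel without fixing
either.  Featurization is deterministic; a model's training matrix is
reproduced bit-for-bit by re-featurizing its training sentences, and this is
asserted on every training run.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .corpus_index import CorpusIndex, query_pair
from .kd_extraction import CandidatePair, ExtractionResult, enumerate_candidates
from .lexicon_kb import DEFAULT_SEED, KnownPairKB, Lexicon
from .np_matching import NPConfig

# ---------------------------------------------------------------------------
# Tokenization: stopword removal + Porter stemming
# ---------------------------------------------------------------------------

#: In-repo English stopword list (function words only), versioned with the
#: package so featurization is reproducible bit-for-bit.
STOPWORDS = frozenset(
    """
    a about above after again against all am an and any are as at be because
    been before being below between both but by could did do does doing down
    during each few for from further had has have having he her here hers
    herself him himself his how i if in into is it its itself just me more
    most my myself no nor not now of off on once only or other our ours
    ourselves out over own same she should so some such than that the their
    theirs them themselves then there these they this those through to too
    under until up very was we were what when where which while who whom why
    will with you your yours yourself yourselves
    """.split()
)

_VOWELS = set("aeiou")


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions (the Porter 'm')."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Porter's suffix-stripping stemmer (the standard 1980 algorithm)."""
    w = word.lower()
    if len(w) <= 2:
        return w
    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]
    # step 1b
    flag = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed") and _has_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _has_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_cons(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _cvc(w):
            w += "e"
    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"
    # step 2
    for suf, rep in _STEP2:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + rep
            break
    # step 3
    for suf, rep in _STEP3:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + rep
            break
    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if suf == "ion" and (not stem or stem[-1] not in "st"):
                continue
            if _measure(stem) > 1:
                w = stem
            break
    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem
    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]
    return w


_WORD = re.compile(r"[a-z0-9]+")


def analyze(text: str) -> list[str]:
    """Tokenize on non-alphanumerics, drop stopwords, Porter-stem the rest."""
    return [
        porter_stem(tok)
        for tok in _WORD.findall(text.lower())
        if tok not in STOPWORDS
    ]


# ---------------------------------------------------------------------------
# Training data from distant labels
# ---------------------------------------------------------------------------


@dataclass
class LabeledSentenceSet:
    """Distantly labeled sentences; positives contain >=1 labeling KB pair."""

    positive_ids: list[str]
    negative_ids: list[str]
    texts: dict[str, str]
    labeling_pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.positive_ids) != len(self.negative_ids):
            raise ValueError("class counts must be equal")

    @property
    def unit_ids(self) -> list[str]:
        return self.positive_ids + self.negative_ids

    @property
    def labels(self) -> np.ndarray:
        return np.array(
            [1] * len(self.positive_ids) + [0] * len(self.negative_ids), dtype=int
        )

    @property
    def sentences(self) -> list[str]:
        return [self.texts[u] for u in self.unit_ids]


def build_training_set(
    index: CorpusIndex,
    kb: KnownPairKB,
    excluded_pairs: KnownPairKB | None = None,
    seed: int = DEFAULT_SEED,
) -> LabeledSentenceSet:
    """Distant labeling: positives contain a (kb - excluded) pair.

    Negatives are a uniform sample without replacement, of equal size, from
    the sentences containing none of the labeling pairs.  Deterministic given
    ``seed``.
    """
    labeling = kb.pairs - (excluded_pairs.pairs if excluded_pairs else frozenset())
    if not labeling:
        raise ValueError("no labeling pairs left after exclusion")
    positives: set[str] = set()
    for drug_id, se_id in labeling:
        positives |= query_pair(index, drug_id, se_id, "sentence")
    pos_ids = sorted(positives)
    if not pos_ids:
        raise ValueError("no positive sentences: no labeling pair occurs in corpus")
    pool = [u for u in index.all_unit_ids() if u not in positives]
    if len(pool) < len(pos_ids):
        raise ValueError(
            f"insufficient negatives: need {len(pos_ids)}, corpus offers {len(pool)}"
        )
    rng = random.Random(seed)
    neg_ids = sorted(rng.sample(pool, len(pos_ids)))
    texts = {u: index.sentence(u).text for u in pos_ids + neg_ids}
    return LabeledSentenceSet(
        positive_ids=pos_ids,
        negative_ids=neg_ids,
        texts=texts,
        labeling_pairs=frozenset(labeling),
    )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class SVMConfig:
    degree: int = 1
    C: float = 1.0
    coef0: float = 1.0
    gamma: float = 1.0
    cv_folds: int = 10
    seed: int = DEFAULT_SEED


@dataclass
class ClassifierModel:
    """Fitted vectorizer + SVM with training metadata."""

    vectorizer: TfidfVectorizer
    svc: SVC
    config: SVMConfig
    metadata: dict = field(default_factory=dict)

    def featurize(self, sentences: Sequence[str]):
        """TF-IDF features in the model's vocabulary; OOV tokens ignored."""
        return self.vectorizer.transform(sentences)

    def decision_function(self, sentences: Sequence[str]) -> np.ndarray:
        """Explicit polynomial-kernel decision values.

        f(x) = sum_i a_i (gamma <x, sv_i> + coef0)^degree + b, computed from
        the stored support vectors so trained and reloaded models behave
        identically.
        """
        X = self.featurize(sentences)
        sv = self.svc.support_vectors_
        gram = X @ sv.T
        if hasattr(gram, "toarray"):
            gram = gram.toarray()
        K = (self.config.gamma * gram + self.config.coef0) ** self.config.degree
        dual = self.svc.dual_coef_
        if hasattr(dual, "toarray"):
            dual = dual.toarray()
        dual = np.asarray(dual)
        intercept = self.svc.intercept_
        if hasattr(intercept, "toarray"):  # pragma: no cover - dense in practice
            intercept = intercept.toarray()
        return (K @ dual.T).ravel() + float(np.asarray(intercept).ravel()[0])

    def predict(self, sentences: Sequence[str]) -> np.ndarray:
        classes = np.asarray(self.svc.classes_)
        return classes[(self.decision_function(sentences) > 0).astype(int)].astype(bool)

    @property
    def vocabulary(self) -> dict[str, int]:
        return {t: int(i) for t, i in self.vectorizer.vocabulary_.items()}


def make_vectorizer() -> TfidfVectorizer:
    """Bag-of-words TF-IDF: idf = ln((1+N)/(1+df)) + 1, L2-normalized rows."""
    return TfidfVectorizer(analyzer=analyze, norm="l2", smooth_idf=True)


def featurize(sentences: Sequence[str], model: ClassifierModel | None = None):
    """Fit-transform with a fresh vectorizer, or transform with a model's."""
    if model is not None:
        return model.featurize(sentences)
    return make_vectorizer().fit_transform(sentences)


def train(ls: LabeledSentenceSet, config: SVMConfig | None = None) -> ClassifierModel:
    """Fit the polynomial-kernel SVM with k-fold cross-validated accuracy.

    Raises on single-class input.  The fold count drops below ``cv_folds``
    only when a class has fewer members than folds.
    """
    config = config or SVMConfig()
    y = ls.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    vec = make_vectorizer()
    vec.fit(ls.sentences)
    # train on the transform-path vectors so a training sentence's features
    # reproduce bit-for-bit at predict time (fit_transform differs by 1 ulp)
    X = vec.transform(ls.sentences)
    svc = SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        coef0=config.coef0,
        gamma=config.gamma,
    )
    n_per_class = int(min(np.bincount(y)))
    folds = max(2, min(config.cv_folds, n_per_class))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    scores = cross_val_score(SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        coef0=config.coef0,
        gamma=config.gamma,
    ), X, y, cv=cv, scoring="accuracy")
    svc.fit(X, y)
    model = ClassifierModel(
        vectorizer=vec,
        svc=svc,
        config=config,
        metadata={
            "seed": config.seed,
            "cv_folds": folds,
            "cv_accuracy": float(scores.mean()),
            "fold_scores": [float(s) for s in scores],
            "n_train": int(X.shape[0]),
        },
    )
    # featurization determinism invariant: training vectors reproduce exactly
    X2 = model.featurize(ls.sentences)
    if (X != X2).nnz != 0:
        raise AssertionError("featurization is not deterministic")
    return model


def svm_extract(
    index: CorpusIndex,
    model: ClassifierModel,
    drugs: Lexicon | None = None,
    ses: Lexicon | None = None,
    unit_filter: set[str] | None = None,
    np_cfg: NPConfig = NPConfig(),
    exclude: KnownPairKB | None = None,
) -> ExtractionResult:
    """Co-occurrence extraction from positively classified sentences.

    Same output contract as the knowledge-driven ``extract``; ``exclude``
    plays the role of the prior in defining the ``novel`` list (the
    evaluation protocol passes the train split).
    """
    drugs = drugs if drugs is not None else index.drugs
    ses = ses if ses is not None else index.ses
    unit_ids = sorted(unit_filter) if unit_filter is not None else index.all_unit_ids()
    result_support: dict[tuple[str, str], set[str]] = {}
    if unit_ids:
        texts = [index.sentence(u).text for u in unit_ids]
        positive = model.predict(texts)
        for uid, pos in zip(unit_ids, positive):
            if not pos:
                continue
            for cand in enumerate_candidates(index.sentence(uid), drugs, ses, np_cfg):
                result_support.setdefault(cand.pair, set()).add(uid)
    all_candidates = [
        CandidatePair(drug_id=d, se_id=s, support=u)
        for (d, s), u in result_support.items()
    ]
    all_candidates.sort(key=lambda c: (-c.count, c.drug_id, c.se_id))
    excluded = exclude.pairs if exclude is not None else frozenset()
    novel = [c for c in all_candidates if c.pair not in excluded]
    return ExtractionResult(
        level="sentence", all_candidates=all_candidates, novel=novel
    )


# ---------------------------------------------------------------------------
# Persistence: one JSON archive (vocabulary + idf + SVM weights + config)
# ---------------------------------------------------------------------------


def _dense(a) -> list:
    if hasattr(a, "toarray"):
        a = a.toarray()
    return np.asarray(a).tolist()


def save_model(model: ClassifierModel, path: str | Path) -> None:
    vec = model.vectorizer
    svc = model.svc
    doc = {
        "config": vars(model.config),
        "metadata": model.metadata,
        "vocabulary": model.vocabulary,
        "idf": [float(v) for v in vec.idf_],
        "svm": {
            "support_vectors": _dense(svc.support_vectors_),
            "dual_coef": _dense(svc.dual_coef_),
            "intercept": _dense(svc.intercept_),
            "classes": _dense(svc.classes_),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> ClassifierModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    config = SVMConfig(**doc["config"])
    vec = make_vectorizer()
    vocab = {t: int(i) for t, i in doc["vocabulary"].items()}
    vec.vocabulary_ = vocab
    vec.fixed_vocabulary_ = True
    idf = np.asarray(doc["idf"], dtype=float)
    vec.idf_ = idf
    svc = SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        coef0=config.coef0,
        gamma=config.gamma,
    )
    # Only the attributes the explicit decision function reads are restored.
    svc.support_vectors_ = np.asarray(doc["svm"]["support_vectors"], dtype=float)
    svc.dual_coef_ = np.asarray(doc["svm"]["dual_coef"], dtype=float)
    svc.intercept_ = np.asarray(doc["svm"]["intercept"], dtype=float)
    svc.classes_ = np.asarray(doc["svm"]["classes"])
    return ClassifierModel(
        vectorizer=vec, svc=svc, config=config, metadata=doc["metadata"]
    )
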