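import pytest

from kdse.kd_extraction import (
    classify_units,
    enumerate_candidates,
    extract,
    naive_cooccurrence,
)
from kdse.lexicon_kb import KnownPairKB
from kdse.np_matching import NPConfig
from kdse.synthetic_corpus import SynthParams, generate
from kdse import build_index


def test_gate_classifies_reporting_sentence_not_title(fixtures_index, fixtures_bundle):
    """A sentence is SE-related iff it contains a known drug-SE pair."""
    prior = KnownPairKB(frozenset({("irinotecan", "diarrhea")}))
    related = classify_units(fixtures_index, prior, "sentence")
    assert "19139178:0" in related
    assert "tpc-title:0" not in related  # three drugs, no known pair


def test_prior_pair_absent_from_corpus_classifies_nothing(fixtures_index):
    prior = KnownPairKB(frozenset({("docetaxel", "anorexia")}))
    assert classify_units(fixtures_index, prior, "sentence") == set()


def test_empty_prior_is_an_error(fixtures_index):
    with pytest.raises(ValueError, match="empty prior"):
        classify_units(fixtures_index, KnownPairKB(frozenset()), "sentence")


def test_classification_equals_linear_scan(small_bundle, small_index):
    from test_corpus_index import _contains_term

    prior = small_bundle.prior
    got = classify_units(small_index, prior, "sentence")
    expected = set()
    for ab in small_bundle.corpus:
        for s in ab.sentences:
            if any(
                _contains_term(s.text, d) and _contains_term(s.text, se)
                for d, se in prior
            ):
                expected.add(s.unit_id)
    assert got == expected


def test_single_drug_sentence_enumerates_cross_product(fixtures_index, fixtures_bundle):
    unit = fixtures_index.sentence("19139178:0")
    cands = enumerate_candidates(unit, fixtures_bundle.drugs, fixtures_bundle.ses)
    assert len(cands) == 6  # 1 drug x 6 SE terms
    assert all(c.drug_id == "irinotecan" for c in cands)


def test_nxm_sentence_enumerates_nine_candidates(fixtures_index, fixtures_bundle):
    unit = fixtures_index.sentence("17577624:0")
    cands = enumerate_candidates(unit, fixtures_bundle.drugs, fixtures_bundle.ses)
    assert len(cands) == 9  # 3 drugs x 3 SEs, valid pairs unresolvable by design


def test_drug_only_unit_enumerates_nothing(fixtures_index, fixtures_bundle):
    unit = fixtures_index.sentence("tpc-title:0")
    assert enumerate_candidates(unit, fixtures_bundle.drugs, fixtures_bundle.ses) == []


def test_worked_examples_novel_pairs(fixtures_index, fixtures_bundle):
    """Known-pair gating propagates knowledge-base errors but blocks titles."""
    result = extract(fixtures_index, fixtures_bundle.prior, level="sentence")
    novel = result.novel_pairs()
    assert {
        ("irinotecan", se)
        for se in ["neutropenia", "nausea", "fatigue", "anorexia", "thrombosis/embolism"]
    } <= novel
    # the mislabeled treatment pair drags in three false extractions
    assert {
        ("lidocaine", "pain"),
        ("tramadol", "pain"),
        ("fentanyl", "pain"),
    } <= novel
    assert len(novel) == 8
    assert not novel & set(fixtures_bundle.prior.pairs)


def test_truth_complete_prior_leaves_nothing_novel():
    bundle = generate(SynthParams(n_abstracts=40, confound_rate=0.0, prior_coverage=1.0, seed=2))
    idx = build_index(bundle.corpus, bundle.drugs, bundle.ses)
    result = extract(idx, bundle.truth)
    assert result.novel == []
    assert result.all_pairs() == set(bundle.truth.pairs)


def test_gating_monotone_in_prior(small_bundle, small_index):
    """Growing the prior never shrinks the classified set or the candidates."""
    pairs = sorted(small_bundle.truth.pairs)
    small = KnownPairKB(frozenset(pairs[: len(pairs) // 4]))
    large = KnownPairKB(frozenset(pairs[: len(pairs) // 2]))
    rel_small = classify_units(small_index, small, "sentence")
    rel_large = classify_units(small_index, large, "sentence")
    assert rel_small <= rel_large
    ex_small = extract(small_index, small)
    ex_large = extract(small_index, large)
    assert ex_small.all_pairs() <= ex_large.all_pairs()


def test_kd_novel_subset_of_ungated_cooccurrence(small_bundle, small_index):
    kd = extract(small_index, small_bundle.prior)
    naive = naive_cooccurrence(small_index)
    assert kd.novel_pairs() <= naive.all_pairs()
    assert kd.all_pairs() <= naive.all_pairs()


def test_sentence_pairs_survive_at_abstract_level(small_bundle, small_index):
    kd_s = extract(small_index, small_bundle.prior, level="sentence")
    kd_a = extract(small_index, small_bundle.prior, level="abstract")
    # per-abstract containment: each sentence-extracted pair reappears among
    # the same abstract's abstract-level candidates
    abs_support = {c.pair: c.support for c in kd_a.all_candidates}
    for c in kd_s.all_candidates:
        pmids = {u.split(":")[0] for u in c.support}
        assert c.pair in abs_support
        assert pmids <= abs_support[c.pair]


def test_synthetic_recovery_with_covering_prior():
    """No confounders + one known pair per abstract => every pair surfaces.

    Abstract-level extraction recovers the full planted truth whenever the
    prior touches each SE-reporting abstract at least once.
    """
    bundle = generate(
        SynthParams(n_abstracts=200, confound_rate=0.0, prior_coverage=0.5, seed=9)
    )
    idx = build_index(bundle.corpus, bundle.drugs, bundle.ses)
    # premise of the property: the prior gates every abstract
    gated = classify_units(idx, bundle.prior, "abstract")
    assert gated == set(idx.abstracts)
    result = extract(idx, bundle.prior, level="abstract")
    recovered = result.novel_pairs() | set(bundle.prior.pairs)
    assert recovered >= set(bundle.truth.pairs)


def test_support_counts_units_once(small_bundle, small_index):
    result = extract(small_index, small_bundle.prior)
    for c in result.all_candidates:
        assert c.count == len(c.support) >= 1


def test_np_gate_drops_unannotated_sentences_in_require_mode(fixtures_bundle):
    corpus = []
    for ab in fixtures_bundle.corpus:
        from kdse.corpus_index import AbstractRecord, SentenceRecord

        bare = [
            SentenceRecord(unit_id=s.unit_id, pmid=s.pmid, text=s.text, np_spans=None)
            for s in ab.sentences
        ]
        corpus.append(AbstractRecord(pmid=ab.pmid, sentences=bare))
    idx = build_index(corpus, fixtures_bundle.drugs, fixtures_bundle.ses)
    strict = NPConfig(mode="require")
    assert classify_units(idx, fixtures_bundle.prior, "sentence", strict) == set()
    off = NPConfig(mode="off")
    assert len(classify_units(idx, fixtures_bundle.prior, "sentence", off)) == 2
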