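"""Knowledge-driven drug-side-effect pair extraction.

The method rests on two observations about the side-effect literature: a
drug's side effects tend to be reported several at a time in one sentence or
abstract, and a sentence that contains one *known* drug-SE pair is very likely
to be reporting side effects.  Known pairs therefore act as a classifier:

1. every text unit (sentence or whole abstract) containing at least one
   known pair is marked SE-related; all other units are discarded;
2. within each SE-related unit, every co-occurring (drug, SE) combination —
   the cross product of matched drug ids and SE ids, under the noun-phrase
   restriction — becomes a candidate pair;
3. candidates not already in the prior knowledge base are reported as novel,
   each with the set of supporting units.

No classifier is trained: the prior knowledge base *is* the classifier, so
updated priors propagate to extraction immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .corpus_index import AbstractRecord, CorpusIndex, Level, SentenceRecord, query_pair
from .lexicon_kb import KnownPairKB, Lexicon
from .np_matching import NPConfig, filtered_matches


@dataclass
class CandidatePair:
    """An extracted (drug, SE) pair with its supporting units."""

    drug_id: str
    se_id: str
    support: set[str] = field(default_factory=set)

    @property
    def count(self) -> int:
        return len(self.support)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.se_id)


@dataclass
class ExtractionResult:
    level: Level
    all_candidates: list[CandidatePair]
    novel: list[CandidatePair]

    def novel_pairs(self) -> set[tuple[str, str]]:
        return {c.pair for c in self.novel}

    def all_pairs(self) -> set[tuple[str, str]]:
        return {c.pair for c in self.all_candidates}


def classify_units(
    index: CorpusIndex,
    prior: KnownPairKB,
    level: Level = "sentence",
    np: NPConfig = NPConfig(),
    abstract_scope: str = "anywhere",
) -> set[str]:
    """Units (sentence ids or pmids) containing at least one prior pair.

    With ``np.gate`` enabled, retrieval hits are verified against the
    noun-phrase restriction: the pair counts only if both its drug and SE
    match survive the NP filter (in the same sentence at sentence level; in
    any sentences of the abstract at abstract level).
    """
    if len(prior) == 0:
        raise ValueError("empty prior knowledge base")
    related: set[str] = set()
    for drug_id, se_id in prior:
        hits = query_pair(index, drug_id, se_id, level, abstract_scope)
        if not (np.gate and np.mode != "off"):
            related |= hits
            continue
        for uid in hits - related:
            if level == "sentence":
                ok = _pair_in_sentence(index.sentence(uid), index, drug_id, se_id, np)
            else:
                ab = index.abstract(uid)
                ok = _id_in_abstract(ab, index.drugs, drug_id, np) and _id_in_abstract(
                    ab, index.ses, se_id, np
                )
            if ok:
                related.add(uid)
    return related


def _pair_in_sentence(
    sent: SentenceRecord,
    index: CorpusIndex,
    drug_id: str,
    se_id: str,
    np: NPConfig,
) -> bool:
    drugs = {m.term_id for m in filtered_matches(sent, index.drugs, np)}
    if drug_id not in drugs:
        return False
    ses = {m.term_id for m in filtered_matches(sent, index.ses, np)}
    return se_id in ses


def _id_in_abstract(
    ab: AbstractRecord, lexicon: Lexicon, term_id: str, np: NPConfig
) -> bool:
    return any(
        term_id in {m.term_id for m in filtered_matches(s, lexicon, np)}
        for s in ab.sentences
    )


def enumerate_candidates(
    unit: SentenceRecord | AbstractRecord,
    drugs: Lexicon,
    ses: Lexicon,
    np: NPConfig = NPConfig(),
) -> list[CandidatePair]:
    """Cross product of distinct drug ids x SE ids matched in one unit.

    For a sentence the matches come from that sentence alone; for an abstract
    the drug and SE may sit in different sentences.  Pairs are deduplicated
    within the unit.
    """
    if isinstance(unit, SentenceRecord):
        sentences = [unit]
        unit_id = unit.unit_id
    else:
        sentences = unit.sentences
        unit_id = unit.pmid
    drug_ids: set[str] = set()
    se_ids: set[str] = set()
    for sent in sentences:
        drug_ids |= {m.term_id for m in filtered_matches(sent, drugs, np)}
        se_ids |= {m.term_id for m in filtered_matches(sent, ses, np)}
    return [
        CandidatePair(drug_id=d, se_id=s, support={unit_id})
        for d in sorted(drug_ids)
        for s in sorted(se_ids)
    ]


def extract(
    index: CorpusIndex,
    prior: KnownPairKB,
    drugs: Lexicon | None = None,
    ses: Lexicon | None = None,
    level: Level = "sentence",
    np: NPConfig = NPConfig(),
    unit_filter: set[str] | None = None,
    abstract_scope: str = "anywhere",
) -> ExtractionResult:
    """Full knowledge-driven extraction over an indexed corpus.

    ``unit_filter``, when given, restricts extraction to those unit ids
    (sentence ids or pmids, matching ``level``) — used by the evaluation
    protocol, which feeds both methods the same input sentences.

    A unit contributes at most once to each pair's support count regardless
    of repeated mentions.  ``novel`` lists candidates absent from the prior;
    ``all_candidates`` retains everything (including prior pairs), since the
    pre-filter enumeration is what co-occurrence counts refer to.
    """
    drugs = drugs if drugs is not None else index.drugs
    ses = ses if ses is not None else index.ses
    related = classify_units(index, prior, level, np, abstract_scope)
    if unit_filter is not None:
        related &= unit_filter
    support: dict[tuple[str, str], set[str]] = {}
    for uid in sorted(related):
        unit = index.sentence(uid) if level == "sentence" else index.abstract(uid)
        for cand in enumerate_candidates(unit, drugs, ses, np):
            support.setdefault(cand.pair, set()).add(uid)
    all_candidates = [
        CandidatePair(drug_id=d, se_id=s, support=u) for (d, s), u in support.items()
    ]
    all_candidates.sort(key=lambda c: (-c.count, c.drug_id, c.se_id))
    novel = [c for c in all_candidates if c.pair not in prior]
    return ExtractionResult(level=level, all_candidates=all_candidates, novel=novel)


def naive_cooccurrence(
    index: CorpusIndex,
    drugs: Lexicon | None = None,
    ses: Lexicon | None = None,
    level: Level = "sentence",
    np: NPConfig = NPConfig(),
    unit_filter: set[str] | None = None,
) -> ExtractionResult:
    """Ungated co-occurrence extraction over *all* units (the KD baseline).

    Identical to :func:`extract` with the knowledge gate removed; the
    knowledge-driven novel set is always a subset of this result.
    """
    drugs = drugs if drugs is not None else index.drugs
    ses = ses if ses is not None else index.ses
    if level == "sentence":
        unit_ids: Iterable[str] = index.all_unit_ids()
    else:
        unit_ids = sorted(index.abstracts)
    if unit_filter is not None:
        unit_ids = [u for u in unit_ids if u in unit_filter]
    support: dict[tuple[str, str], set[str]] = {}
    for uid in unit_ids:
        unit = index.sentence(uid) if level == "sentence" else index.abstract(uid)
        for cand in enumerate_candidates(unit, drugs, ses, np):
            support.setdefault(cand.pair, set()).add(uid)
    all_candidates = [
        CandidatePair(drug_id=d, se_id=s, support=u) for (d, s), u in support.items()
    ]
    all_candidates.sort(key=lambda c: (-c.count, c.drug_id, c.se_id))
    return ExtractionResult(
        level=level, all_candidates=all_candidates, novel=list(all_candidates)
    )


def write_extraction_tsv(result: ExtractionResult, path: str | Path, novel_only: bool = True) -> None:
    """``drug_id<TAB>se_id<TAB>count<TAB>unit,ids`` sorted by count desc then ids."""
    rows = result.novel if novel_only else result.all_candidates
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tse_id\tcount\tunits\n")
        for c in rows:
            fh.write(f"{c.drug_id}\t{c.se_id}\t{c.count}\t{','.join(sorted(c.support))}\n")
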