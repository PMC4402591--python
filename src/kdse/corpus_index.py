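"""Sentence-segmented corpus storage and pair-query retrieval.

This module plays the role of a local literature search engine: an inverted
index from lexicon terms to the sentences (and abstracts) containing them,
supporting the pair queries that drive the knowledge-driven gate.  Sentences
carry optional noun-phrase character spans (the surrogate for per-sentence
parse trees); coordinates are 0-based half-open character offsets throughout.

Corpus interchange format is JSON Lines, one abstract per line::

    {"pmid": "...", "sentences": [{"text": "...", "np_spans": [[s,e],...]}]}

``np_spans`` is optional.  The title, if supplied, is sentence 0.
"""

from __future__ import annotations

import json
import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .lexicon_kb import Lexicon, normalize_term
from .np_matching import find_term_matches

Level = Literal["sentence", "abstract"]


@dataclass
class SentenceRecord:
    """One corpus sentence; ``unit_id`` is ``"pmid:k"`` (0-based index k)."""

    unit_id: str
    pmid: str
    text: str
    np_spans: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.np_spans is not None:
            spans = [tuple(s) for s in self.np_spans]
            prev_end = -1
            for s, e in spans:
                if not (0 <= s < e <= len(self.text)):
                    raise ValueError(
                        f"{self.unit_id}: np span [{s},{e}) out of bounds"
                    )
                if s < prev_end:
                    raise ValueError(f"{self.unit_id}: np spans overlap or unsorted")
                prev_end = e
            self.np_spans = spans


@dataclass
class AbstractRecord:
    pmid: str
    sentences: list[SentenceRecord]

    def __post_init__(self) -> None:
        for k, sent in enumerate(self.sentences):
            expected = f"{self.pmid}:{k}"
            if sent.unit_id != expected:
                raise ValueError(
                    f"sentence unit_id {sent.unit_id!r} != expected {expected!r}"
                )


def make_abstract(
    pmid: str,
    sentences: Iterable[str | dict],
) -> AbstractRecord:
    """Build an AbstractRecord from raw sentence strings or JSONL dicts."""
    records = []
    for k, s in enumerate(sentences):
        if isinstance(s, str):
            text, spans = s, None
        else:
            text = s["text"]
            spans = s.get("np_spans")
            if spans is not None:
                spans = [tuple(x) for x in spans]
        records.append(
            SentenceRecord(unit_id=f"{pmid}:{k}", pmid=pmid, text=text, np_spans=spans)
        )
    return AbstractRecord(pmid=pmid, sentences=records)


_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"])")


def segment_abstract(text: str) -> list[str]:
    """Split abstract text into sentences.

    Splits after sentence-final punctuation followed by whitespace and an
    uppercase letter or digit; never splits inside parentheses.  The
    concatenation of the returned sentences reconstructs the text modulo
    inter-sentence whitespace.
    """
    if not text.strip():
        return []
    depths = []
    d = 0
    for ch in text:
        if ch == "(":
            d += 1
        elif ch == ")":
            d = max(0, d - 1)
        depths.append(d)
    pieces: list[str] = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        if depths[m.start()] == 0:
            pieces.append(text[start : m.start()])
            start = m.end()
    pieces.append(text[start:])
    return [p for p in (p.strip() for p in pieces) if p]


def load_corpus_jsonl(path: str | Path) -> list[AbstractRecord]:
    abstracts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            abstracts.append(make_abstract(obj["pmid"], obj["sentences"]))
    return abstracts


def write_corpus_jsonl(abstracts: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ab in abstracts:
            obj = {
                "pmid": ab.pmid,
                "sentences": [
                    {"text": s.text}
                    if s.np_spans is None
                    else {"text": s.text, "np_spans": [list(sp) for sp in s.np_spans]}
                    for s in ab.sentences
                ],
            }
            fh.write(json.dumps(obj) + "\n")


@dataclass
class CorpusIndex:
    """Inverted index: normalized lexicon term -> unit ids containing it."""

    drugs: Lexicon
    ses: Lexicon
    postings: dict[str, set[str]] = field(default_factory=dict)
    units: dict[str, SentenceRecord] = field(default_factory=dict)
    abstracts: dict[str, AbstractRecord] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def _lexicon_for(self, kind: str) -> Lexicon:
        return self.drugs if kind == "drug" else self.ses

    def units_with_id(self, term_id: str, kind: str) -> set[str]:
        """Sentence unit ids containing any surface term of ``term_id``."""
        lex = self._lexicon_for(kind)
        if term_id not in lex:
            raise KeyError(f"unknown {kind} id: {term_id!r}")
        out: set[str] = set()
        for term in lex.terms_for(term_id):
            out |= self.postings.get(term, set())
        return out

    def pmids_with_id(self, term_id: str, kind: str) -> set[str]:
        return {self.units[u].pmid for u in self.units_with_id(term_id, kind)}

    def sentence(self, unit_id: str) -> SentenceRecord:
        return self.units[unit_id]

    def abstract(self, pmid: str) -> AbstractRecord:
        return self.abstracts[pmid]

    def all_unit_ids(self) -> list[str]:
        return sorted(self.units)


def build_index(
    abstracts: list[AbstractRecord], drugs: Lexicon, ses: Lexicon
) -> CorpusIndex:
    """Index every lexicon term occurrence (whole-term match, no NP filter).

    The noun-phrase restriction is applied downstream at classification and
    extraction time; retrieval itself is term containment, mirroring a plain
    keyword search engine.
    """
    index = CorpusIndex(drugs=drugs, ses=ses)
    for ab in abstracts:
        if ab.pmid in index.abstracts:
            raise ValueError(f"duplicate pmid {ab.pmid!r}")
        index.abstracts[ab.pmid] = ab
        for sent in ab.sentences:
            if sent.unit_id in index.units:
                raise ValueError(f"duplicate unit id {sent.unit_id!r}")
            index.units[sent.unit_id] = sent
            for lex in (drugs, ses):
                for m in find_term_matches(sent, lex):
                    term = normalize_term(m.surface)
                    index.postings.setdefault(term, set()).add(sent.unit_id)
    return index


def query_pair(
    index: CorpusIndex,
    drug_id: str,
    se_id: str,
    level: Level = "sentence",
    abstract_scope: str = "anywhere",
) -> set[str]:
    """Units containing both members of a known drug-SE pair.

    Sentence level returns sentence unit ids whose text contains both terms.
    Abstract level returns pmids; with ``abstract_scope="anywhere"`` (default)
    the drug and SE may sit in different sentences of the abstract, with
    ``"same_sentence"`` the pair must co-occur within one of its sentences.
    """
    if level == "sentence":
        return index.units_with_id(drug_id, "drug") & index.units_with_id(
            se_id, "side_effect"
        )
    if level == "abstract":
        if abstract_scope == "same_sentence":
            hits = index.units_with_id(drug_id, "drug") & index.units_with_id(
                se_id, "side_effect"
            )
            return {index.units[u].pmid for u in hits}
        if abstract_scope == "anywhere":
            return index.pmids_with_id(drug_id, "drug") & index.pmids_with_id(
                se_id, "side_effect"
            )
        raise ValueError(f"unknown abstract scope: {abstract_scope!r}")
    raise ValueError(f"unknown level: {level!r}")


def save_index(index: CorpusIndex, path: str | Path) -> None:
    patterns = (index.drugs._pattern, index.ses._pattern)
    index.drugs._pattern = index.ses._pattern = None  # compiled regex: rebuildable
    try:
        with open(path, "wb") as fh:
            pickle.dump(index, fh)
    finally:
        index.drugs._pattern, index.ses._pattern = patterns


def load_index(path: str | Path) -> CorpusIndex:
    with open(path, "rb") as fh:
        index = pickle.load(fh)
    if not isinstance(index, CorpusIndex):
        raise TypeError(f"{path}: not a saved corpus index")
    return index
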