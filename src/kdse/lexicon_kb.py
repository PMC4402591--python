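"""Drug / side-effect lexicons and the known-pair knowledge base.

A :class:`Lexicon` maps normalized surface terms (e.g. ``"irinotecan"``,
``"thrombosis/embolism"``) to canonical identifiers; one lexicon holds drug
generic names, the other side-effect (SE) terms.  A :class:`KnownPairKB` is a
set of known (drug_id, se_id) associations — the prior knowledge that gates
the knowledge-driven extraction — and also serves as the gold standard in the
per-drug evaluation protocol, where each evaluated drug's pairs are split into
a train half (used as prior) and a held-out test half.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_SEED = 17

_WS = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Canonicalize a surface term: lowercase, strip, collapse whitespace.

    Punctuation is preserved so that composite terms such as
    ``"thrombosis/embolism"`` survive intact.  Idempotent.
    """
    return _WS.sub(" ", raw.strip()).lower()


@dataclass
class Lexicon:
    """A dictionary of surface terms of one kind (drug or side effect).

    Attributes
    ----------
    kind:
        ``"drug"`` or ``"side_effect"``.
    entries:
        Normalized surface term -> canonical id.  Within one lexicon a term
        maps to exactly one id; several terms may share an id (synonyms).
    canonical_name:
        id -> display string (the first surface form seen for that id).
    """

    kind: str
    entries: dict[str, str] = field(default_factory=dict)
    canonical_name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("drug", "side_effect"):
            raise ValueError(f"unknown lexicon kind: {self.kind!r}")
        self._pattern = None  # compiled matcher cache, built lazily

    def add(self, term: str, term_id: str) -> None:
        norm = normalize_term(term)
        if not norm:
            raise ValueError("empty term in lexicon")
        if not term_id:
            raise ValueError(f"empty id for term {term!r}")
        existing = self.entries.get(norm)
        if existing is not None and existing != term_id:
            raise ValueError(
                f"ambiguous term {norm!r}: maps to both {existing!r} and {term_id!r}"
            )
        self.entries[norm] = term_id
        self.canonical_name.setdefault(term_id, norm)
        self._pattern = None

    @property
    def ids(self) -> set[str]:
        return set(self.entries.values())

    def terms_for(self, term_id: str) -> list[str]:
        return sorted(t for t, i in self.entries.items() if i == term_id)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.canonical_name

    def __len__(self) -> int:
        return len(self.entries)


def load_lexicon(path: str | Path, kind: str) -> Lexicon:
    """Read a ``term<TAB>id`` TSV (UTF-8, optional ``#`` header lines).

    Duplicate (term, id) rows collapse; a term mapping to two different ids is
    a hard error naming the term.
    """
    lex = Lexicon(kind=kind)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected term<TAB>id, got {line!r}")
            lex.add(parts[0], parts[1].strip())
    return lex


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write sorted ``term<TAB>id`` rows (diff-stable round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# term\tid ({lex.kind})\n")
        for term in sorted(lex.entries):
            fh.write(f"{term}\t{lex.entries[term]}\n")


@dataclass(frozen=True)
class KnownPairKB:
    """A set of known (drug_id, se_id) pairs with set semantics."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(self.pairs)

    def pairs_for_drug(self, drug_id: str) -> set[tuple[str, str]]:
        return {p for p in self.pairs if p[0] == drug_id}

    def drug_ids(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def union(self, other: "KnownPairKB") -> "KnownPairKB":
        return KnownPairKB(self.pairs | other.pairs)

    def difference(self, other: "KnownPairKB") -> "KnownPairKB":
        return KnownPairKB(self.pairs - other.pairs)


def load_known_pairs(
    path: str | Path, drugs: Lexicon, ses: Lexicon
) -> KnownPairKB:
    """Read ``drug<TAB>se`` rows; each field may be a surface term or an id.

    Unresolvable rows are counted, logged and skipped; zero resolvable rows is
    a hard error because an empty prior makes the knowledge-driven gate
    vacuous.
    """
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                skipped += 1
                continue
            d = _resolve(parts[0], drugs)
            s = _resolve(parts[1], ses)
            if d is None or s is None:
                skipped += 1
                continue
            pairs.add((d, s))
    if skipped:
        logger.warning("load_known_pairs: skipped %d unresolvable rows", skipped)
    if not pairs:
        raise ValueError(f"{path}: no resolvable drug-SE pairs")
    return KnownPairKB(frozenset(pairs))


def _resolve(field_value: str, lex: Lexicon) -> str | None:
    norm = normalize_term(field_value)
    if norm in lex.entries:
        return lex.entries[norm]
    if field_value.strip() in lex.canonical_name:
        return field_value.strip()
    return None


def write_known_pairs(kb: KnownPairKB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# drug_id\tse_id\n")
        for d, s in sorted(kb.pairs):
            fh.write(f"{d}\t{s}\n")


def split_pairs_per_drug(
    kb: KnownPairKB,
    drugs: list[str],
    fraction: float = 0.5,
    seed: int = DEFAULT_SEED,
) -> tuple[KnownPairKB, KnownPairKB]:
    """Per-drug random train/test split of known pairs.

    For each listed drug its pairs are partitioned disjointly, ``round(
    fraction * n)`` into train; pairs of non-listed drugs go entirely to
    train.  The per-drug shuffle is seeded from ``(seed, drug_id)`` so the
    partition is deterministic and independent of the drug list order.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    listed = set(drugs)
    train: set[tuple[str, str]] = {p for p in kb.pairs if p[0] not in listed}
    test: set[tuple[str, str]] = set()
    for drug_id in sorted(listed):
        drug_pairs = sorted(kb.pairs_for_drug(drug_id))
        if len(drug_pairs) < 2:
            raise ValueError(
                f"drug {drug_id!r} has {len(drug_pairs)} known pair(s); "
                "need at least 2 to split"
            )
        rng = random.Random(f"{seed}:{drug_id}")
        rng.shuffle(drug_pairs)
        n_train = round(fraction * len(drug_pairs))
        n_train = min(max(n_train, 1), len(drug_pairs) - 1)  # both halves non-empty
        train.update(drug_pairs[:n_train])
        test.update(drug_pairs[n_train:])
    return KnownPairKB(frozenset(train)), KnownPairKB(frozenset(test))
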