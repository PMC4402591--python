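"""Shared-side-effect correlation curves.

Given an extracted set of (drug, SE) pairs, drugs that share many side
effects are hypothesized to share lower-level properties: gene targets,
metabolism genes, chemical neighborhoods, and disease indications.  The
analysis computes, for every unordered drug pair, the number of shared SEs,
then — at increasing shared-SE cutoffs k — the mean of a drug-pair property
over pairs sharing at least k SEs: either the size of an attribute-set
intersection (targets / metabolism genes / indications) or a pairwise score
(pathway-database, structural-similarity or expression-based chemical
association scores).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Shared-SE cutoff grid used in the published analyses.
DEFAULT_CUTOFFS = (0, 1, 10, 50, 100)

Pair = tuple[str, str]


@dataclass
class AttributeTable:
    """drug_id -> set of attribute ids (gene targets, indications, ...)."""

    kind: str  # "targets" | "metabolism" | "indications" | free label
    attributes: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [d for d, a in self.attributes.items() if not a]
        if empty:
            raise ValueError(f"drugs with empty attribute sets: {sorted(empty)[:5]}")

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.attributes

    def shared(self, d1: str, d2: str) -> int:
        return len(self.attributes[d1] & self.attributes[d2])


@dataclass
class ScoreTable:
    """Unordered drug pair -> non-negative score; symmetric, no self-pairs."""

    kind: str  # "database" | "similarity" | "experimental" | free label
    scores: dict[frozenset[str], float]

    def __post_init__(self) -> None:
        for key, v in self.scores.items():
            if len(key) != 2:
                raise ValueError(f"self-pair or malformed key: {set(key)}")
            if v < 0:
                raise ValueError(f"negative score for {set(key)}: {v}")

    def get(self, d1: str, d2: str, default: float = 0.0) -> float:
        return self.scores.get(frozenset((d1, d2)), default)

    def __contains__(self, key: frozenset[str]) -> bool:
        return key in self.scores


@dataclass
class CurvePoint:
    cutoff: int
    n_pairs: int
    mean: float | None  # None when no pair qualifies


@dataclass
class SharedSECurve:
    """Mean drug-pair property vs shared-SE cutoff."""

    kind: str
    points: list[CurvePoint]

    def __post_init__(self) -> None:
        counts = [p.n_pairs for p in self.points]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("qualifying-pair counts must be non-increasing in cutoff")

    def means(self) -> list[float | None]:
        return [p.mean for p in self.points]


def shared_se_counts(pairs: Iterable[Pair]) -> dict[frozenset[str], int]:
    """|shared SEs| for every unordered pair of drugs in the input pair set.

    Every drug appearing in the input contributes, including pairs sharing
    zero SEs (the all-pairs cutoff-0 denominator).
    """
    se_sets: dict[str, set[str]] = {}
    for drug, se in pairs:
        se_sets.setdefault(drug, set()).add(se)
    out: dict[frozenset[str], int] = {}
    for d1, d2 in itertools.combinations(sorted(se_sets), 2):
        out[frozenset((d1, d2))] = len(se_sets[d1] & se_sets[d2])
    return out


def attribute_overlap_curve(
    shared: dict[frozenset[str], int],
    table: AttributeTable,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> SharedSECurve:
    """Mean shared-attribute count over drug pairs sharing >= k SEs.

    Only drug pairs with both drugs present in the attribute table enter the
    means (extracted drugs missing from the external resource are excluded).
    A cutoff with no qualifying pair yields an undefined mean, not 0.
    """
    _check_cutoffs(cutoffs)
    eligible = {
        pair: n for pair, n in shared.items() if all(d in table for d in pair)
    }
    points = []
    for k in cutoffs:
        values = [
            table.shared(*sorted(pair)) for pair, n in eligible.items() if n >= k
        ]
        points.append(_point(k, values, table.kind))
    return SharedSECurve(kind=table.kind, points=points)


def score_curve(
    shared: dict[frozenset[str], int],
    table: ScoreTable,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    missing: str = "zero",
) -> SharedSECurve:
    """Mean pairwise score over drug pairs sharing >= k SEs.

    ``missing`` controls pairs absent from the score table: ``"zero"``
    (default) scores them 0, ``"skip"`` drops them from the mean.
    """
    _check_cutoffs(cutoffs)
    if missing not in ("zero", "skip"):
        raise ValueError(f"unknown missing policy: {missing!r}")
    points = []
    for k in cutoffs:
        qualifying = [pair for pair, n in shared.items() if n >= k]
        if missing == "skip":
            values = [table.scores[p] for p in qualifying if p in table]
        else:
            values = [table.scores.get(p, 0.0) for p in qualifying]
        points.append(_point(k, values, table.kind))
    return SharedSECurve(kind=table.kind, points=points)


def _check_cutoffs(cutoffs: Sequence[int]) -> None:
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")


def _point(k: int, values: list, kind: str) -> CurvePoint:
    if not values:
        logger.warning("curve %s: no qualifying drug pairs at cutoff %d", kind, k)
        return CurvePoint(cutoff=k, n_pairs=0, mean=None)
    return CurvePoint(cutoff=k, n_pairs=len(values), mean=sum(values) / len(values))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_attribute_table(path: str | Path, kind: str) -> AttributeTable:
    """TSV ``drug<TAB>attribute`` (one association per row)."""
    attrs: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            drug, attr = line.split("\t")[:2]
            attrs.setdefault(drug.strip(), set()).add(attr.strip())
    return AttributeTable(kind=kind, attributes=attrs)


def load_score_table(path: str | Path, kind: str) -> ScoreTable:
    """TSV ``drug1<TAB>drug2<TAB>score``; symmetric duplicates must agree."""
    scores: dict[frozenset[str], float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            d1, d2, s = line.split("\t")[:3]
            key = frozenset((d1.strip(), d2.strip()))
            value = float(s)
            if key in scores and scores[key] != value:
                raise ValueError(f"conflicting scores for pair {set(key)}")
            scores[key] = value
    return ScoreTable(kind=kind, scores=scores)


def load_pairs_tsv(path: str | Path) -> set[Pair]:
    """TSV with ``drug<TAB>se`` in the first two columns (extraction output)."""
    pairs: set[Pair] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            d, s = line.split("\t")[:2]
            pairs.add((d.strip(), s.strip()))
    return pairs


def write_curve(curve: SharedSECurve, path: str | Path) -> None:
    """TSV ``cutoff<TAB>n_pairs<TAB>mean`` (mean blank when undefined)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {curve.kind}\n# cutoff\tn_pairs\tmean\n")
        for p in curve.points:
            mean = "" if p.mean is None else f"{p.mean:.6g}"
            fh.write(f"{p.cutoff}\t{p.n_pairs}\t{mean}\n")
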