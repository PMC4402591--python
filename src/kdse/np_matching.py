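"""Dictionary matching of lexicon terms with a noun-phrase restriction.

Matching is case-insensitive whole-term matching at word boundaries, where a
boundary is the start/end of the text or any non-alphanumeric character;
``/`` and ``-`` count as internal when they are part of a lexicon term (so
``thrombosis/embolism`` matches as one term).  Overlapping candidates resolve
longest-match-leftmost, so a multi-word side-effect term such as
``"decreases in hemoglobin"`` beats its embedded unigrams.

The noun-phrase (NP) restriction keeps a match only if its span lies inside a
base-NP span of the sentence.  NP spans normally arrive with the corpus (they
stand in for constituency-parse trees); when absent, a deterministic
rule-based chunker supplies them, a sentence is rejected outright, or the
restriction is waived, depending on ``mode``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from .lexicon_kb import Lexicon, normalize_term

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_index import SentenceRecord

_ALNUM = r"A-Za-z0-9"


@dataclass(frozen=True)
class NPConfig:
    """Noun-phrase restriction settings.

    ``mode``: ``"require"`` (drop matches in unannotated sentences),
    ``"fallback"`` (default; chunk unannotated sentences with
    :func:`default_np_spans`) or ``"off"`` (no restriction).
    ``strict``: require the match span to equal an NP span exactly.
    ``gate``: also apply the restriction when classifying units as SE-related,
    not only when enumerating candidate pairs.
    """

    mode: str = "fallback"
    strict: bool = False
    gate: bool = True


@dataclass(frozen=True)
class TermMatch:
    """One whole-term lexicon hit inside a sentence."""

    unit_id: str
    kind: str  # "drug" | "side_effect"
    term_id: str
    start: int
    end: int
    surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _lexicon_pattern(lex: Lexicon) -> re.Pattern | None:
    """Compile one alternation over all lexicon terms, longest first.

    Sorting alternatives by descending length makes the regex engine prefer
    the longest term starting at each position; ``finditer`` then yields a
    leftmost, non-overlapping cover — exactly longest-match-leftmost.
    """
    if getattr(lex, "_pattern", None) is not None:
        return lex._pattern
    if not lex.entries:
        return None
    alts = []
    for term in sorted(lex.entries, key=lambda t: (-len(t), t)):
        esc = re.escape(term).replace(r"\ ", " ").replace(" ", r"\s+")
        alts.append(esc)
    pat = re.compile(
        rf"(?<![{_ALNUM}])(?:{'|'.join(alts)})(?![{_ALNUM}])", re.IGNORECASE
    )
    lex._pattern = pat
    return pat


def find_term_matches(sentence: "SentenceRecord", lexicon: Lexicon) -> list[TermMatch]:
    """All whole-term lexicon matches in a sentence, longest-match-leftmost.

    Each text position belongs to at most one match per lexicon.
    """
    pat = _lexicon_pattern(lexicon)
    if pat is None:
        return []
    out: list[TermMatch] = []
    for m in pat.finditer(sentence.text):
        surface = m.group(0)
        term_id = lexicon.entries.get(normalize_term(surface))
        if term_id is None:  # pragma: no cover - pattern and entries co-vary
            continue
        out.append(
            TermMatch(
                unit_id=sentence.unit_id,
                kind=lexicon.kind,
                term_id=term_id,
                start=m.start(),
                end=m.end(),
                surface=surface,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rule-based base-NP chunker (surrogate for parse-derived NP spans)
# ---------------------------------------------------------------------------

#: Closed-class stoplist: prepositions, conjunctions, determiners, auxiliary
#: and common reporting verbs.  A token on this list terminates a base NP.
NP_STOPLIST = frozenset(
    """
    a an the this that these those
    and or but nor than as
    of in on at by with without for to from into after before during per
    over under between among within
    is are was were be been being am
    has have had having do does did done
    can could may might must shall should will would
    include includes included including
    observe observes observed report reports reported reporting
    show shows showed shown occur occurs occurred
    receive receives received treat treats treated
    develop develops developed experience experiences experienced
    cause causes caused associate associated
    use used using administer administered
    prevent preventing decrease decreasing increase increasing
    influence influenced respectively not no
    """.split()
)

_TOKEN = re.compile(r"[A-Za-z0-9][A-Za-z0-9/%.'-]*")
_BREAKERS = set(",;:()[]{}\"")


def default_np_spans(
    text: str, matches: Iterable[TermMatch] | None = None
) -> list[tuple[int, int]]:
    """Deterministic base-NP spans for a sentence without parse annotations.

    A base NP is a maximal run of word tokens none of which is in the
    closed-class stoplist, split additionally at commas, parentheses and
    similar punctuation.  Spans are sorted and non-overlapping.
    """
    spans: list[tuple[int, int]] = []
    run_start: int | None = None
    run_end = 0
    prev_end = 0
    for tok in _TOKEN.finditer(text):
        word = tok.group(0).lower().rstrip(".")
        gap = text[prev_end : tok.start()]
        breaks = any(c in _BREAKERS for c in gap)
        if word in NP_STOPLIST or (breaks and run_start is not None):
            if run_start is not None:
                spans.append((run_start, run_end))
                run_start = None
            if word not in NP_STOPLIST:
                run_start, run_end = tok.start(), tok.end()
        else:
            if run_start is None:
                run_start = tok.start()
            run_end = tok.end()
        prev_end = tok.end()
    if run_start is not None:
        spans.append((run_start, run_end))
    return spans


def np_filter(
    matches: Sequence[TermMatch],
    np_spans: Sequence[tuple[int, int]] | None,
    *,
    text: str = "",
    mode: str = "fallback",
    strict: bool = False,
) -> list[TermMatch]:
    """Keep matches whose span lies inside some noun-phrase span.

    ``mode`` governs sentences with no NP annotation: ``"require"`` drops all
    matches, ``"fallback"`` (default) chunks the text with
    :func:`default_np_spans`, ``"off"`` disables the restriction entirely.
    With ``strict=True`` the match span must equal an NP span exactly rather
    than merely be contained in one.  Output is a subset of the input and the
    filter is idempotent.
    """
    if mode not in ("require", "fallback", "off"):
        raise ValueError(f"unknown np mode: {mode!r}")
    if mode == "off":
        return list(matches)
    if np_spans is None:
        if mode == "require":
            return []
        np_spans = default_np_spans(text)
    if strict:
        keep = set(map(tuple, np_spans))
        return [m for m in matches if m.span in keep]
    return [
        m
        for m in matches
        if any(s <= m.start and m.end <= e for s, e in np_spans)
    ]


def filtered_matches(
    sentence: "SentenceRecord", lexicon: Lexicon, cfg: NPConfig
) -> list[TermMatch]:
    """Dictionary matches of one lexicon after the NP restriction."""
    matches = find_term_matches(sentence, lexicon)
    return np_filter(
        matches,
        sentence.np_spans,
        text=sentence.text,
        mode=cfg.mode,
        strict=cfg.strict,
    )
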