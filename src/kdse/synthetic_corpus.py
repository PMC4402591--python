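"""Synthetic corpora with the statistical structure the method assumes.

The generator emulates the two sentence archetypes that motivate the
knowledge-driven gate: *SE-reporting* sentences, in which a drug is listed
together with several of its true side effects, and *confounding* sentences,
in which a drug co-occurs with side-effect-lexicon terms that are NOT its
side effects (conditions it treats, findings about other drugs) — the
failure mode that makes ungated co-occurrence extraction imprecise.  Both
archetypes draw their wording from one shared template pool, so surface
features alone cannot separate them; only the prior knowledge can, which is
precisely the regime in which knowledge gating pays off over a trained
sentence classifier.

Drugs belong to latent classes that drive three things simultaneously:
which side effects a drug tends to have (within-class sharing), which
attributes (targets / metabolism genes / indications) it carries, and its
pairwise chemical scores.  Shared-SE counts therefore co-vary with shared
attributes and with class-linked scores, while one score table is generated
independently of the classes to provide a flat control curve.

Every true pair is emitted in at least one sentence, every emitted term is
covered by a gold noun-phrase span, and the prior knowledge base is a nested
deterministic subset of the truth (so recall is monotone in coverage by
construction of the experiment, not of the assertion).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_index import AbstractRecord, SentenceRecord
from .correlation import AttributeTable, ScoreTable
from .lexicon_kb import DEFAULT_SEED, KnownPairKB, Lexicon
from .np_matching import find_term_matches


@dataclass
class SynthParams:
    """Study conditions for one synthetic bundle.

    ``true_pair_density`` is the fraction of the SE lexicon that is a true
    side effect of each drug; ``confound_rate`` the fraction of body
    sentences that are confounding treatment-style sentences;
    ``prior_coverage`` the fraction of true pairs given to the method as
    prior knowledge.
    """

    n_drugs: int = 30
    n_ses: int = 60
    n_abstracts: int = 200
    true_pair_density: float = 0.2
    ses_per_sentence: int = 3
    confound_rate: float = 0.2
    prior_coverage: float = 0.5
    n_latent_classes: int = 3
    filler_per_abstract: int = 3
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 < self.true_pair_density < 1.0:
            raise ValueError("true_pair_density must be in (0,1)")
        for name in ("confound_rate", "prior_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.confound_rate > 0.9:
            raise ValueError(
                "confound_rate > 0.9 leaves no room for SE-reporting sentences"
            )
        if self.ses_per_sentence < 2:
            raise ValueError("ses_per_sentence must be >= 2")
        if self.n_latent_classes > self.n_drugs:
            raise ValueError("n_latent_classes must be <= n_drugs")
        if min(self.n_drugs, self.n_ses, self.n_abstracts, self.n_latent_classes) < 1:
            raise ValueError("sizes must be positive")


@dataclass
class SynthBundle:
    corpus: list[AbstractRecord]
    truth: KnownPairKB
    prior: KnownPairKB
    drugs: Lexicon
    ses: Lexicon
    attribute_tables: dict[str, AttributeTable] = field(default_factory=dict)
    score_tables: dict[str, ScoreTable] = field(default_factory=dict)
    latent_class: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.prior.pairs <= self.truth.pairs:
            raise ValueError("prior must be a subset of truth")


# ---------------------------------------------------------------------------
# Pseudo-name generation
# ---------------------------------------------------------------------------

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v", "z"]
_NUCLEI = ["a", "e", "i", "o", "u"]
_DRUG_SUFFIX = ["ib", "ol", "ine", "ate", "mab", "pril"]
_SE_SUFFIX = ["emia", "osis", "algia", "penia", "itis", "pathy"]
_SE_MODIFIERS = ["acute", "severe", "transient", "persistent"]

#: Words used by the sentence templates; generated names must avoid them.
_RESERVED = frozenset(
    "toxicity included and was effective in treating study of clinical"
    " patients a the common adverse events with were treatment followed by".split()
)


def _pseudo_word(rng: random.Random, suffixes: list[str]) -> str:
    word = ""
    for _ in range(2):
        word += rng.choice(_ONSETS) + rng.choice(_NUCLEI)
    return word + rng.choice(suffixes)


def _unique_names(
    rng: random.Random, n: int, suffixes: list[str], taken: set[str], two_word_frac: float = 0.0
) -> list[str]:
    names = []
    while len(names) < n:
        name = _pseudo_word(rng, suffixes)
        if two_word_frac and rng.random() < two_word_frac:
            name = f"{rng.choice(_SE_MODIFIERS)} {name}"
        if name in taken or name in _RESERVED or name in _filler_words():
            continue
        head = name.split()[-1]
        if any(head == t.split()[-1] for t in taken):
            continue  # keep head words unique so no term embeds another
        taken.add(name)
        names.append(name)
    return names


# ---------------------------------------------------------------------------
# Sentence assembly with gold NP spans
# ---------------------------------------------------------------------------


def _compose(template_parts: list[tuple[str, bool]]) -> tuple[str, list[tuple[int, int]]]:
    """Join (text, is_term) parts; return the sentence and term spans."""
    text = ""
    spans = []
    for part, is_term in template_parts:
        if is_term:
            spans.append((len(text), len(text) + len(part)))
        text += part
    return text, spans


def _term_list_parts(se_terms: list[str]) -> list[tuple[str, bool]]:
    parts: list[tuple[str, bool]] = []
    for i, se in enumerate(se_terms):
        if i:
            if i == len(se_terms) - 1:
                parts.append((" and " if len(se_terms) == 2 else ", and ", False))
            else:
                parts.append((", ", False))
        parts.append((se, True))
    return parts


#: Shared surface templates for drug + SE-term sentences.  Both SE-reporting
#: and confounding sentences draw from this pool, so bag-of-words features
#: carry no signal about which co-mentions are genuine side effects — only
#: the prior knowledge does.  This mirrors the real failure mode: a sentence
#: listing conditions a drug treats reads just like one listing its
#: toxicities.
def _drug_se_sentence(
    template: int, drug: str, se_terms: list[str]
) -> tuple[str, list[tuple[int, int]]]:
    body = _term_list_parts(se_terms)
    if template == 0:
        parts = [(drug.capitalize(), True), (" toxicity included ", False), *body]
    elif template == 1:
        parts = [
            ("Common adverse events with ", False),
            (drug, True),
            (" were ", False),
            *body,
        ]
    else:
        parts = [(drug.capitalize(), True), (" treatment was followed by ", False), *body]
    parts.append((".", False))
    return _compose(parts)


#: Background sentences containing no lexicon term, standing in for the bulk
#: of the literature (methods, enrolment, statistics).  They are the negative
#: pool for distant supervision.
_FILLER = [
    "Patients were enrolled at twelve centers and followed for two years.",
    "The primary endpoint was assessed by blinded review.",
    "Median follow up was eighteen months.",
    "Informed consent was obtained from all participants.",
    "Baseline characteristics were balanced between groups.",
    "Statistical analyses were performed on the intention to treat population.",
]


def _filler_words() -> frozenset[str]:
    return frozenset(w.lower().strip(".") for s in _FILLER for w in s.split())




# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def generate(params: SynthParams) -> SynthBundle:
    """Deterministic synthetic bundle for the given study conditions."""
    rng = random.Random(params.seed)
    taken: set[str] = set()
    drug_names = _unique_names(rng, params.n_drugs, _DRUG_SUFFIX, taken)
    se_names = _unique_names(rng, params.n_ses, _SE_SUFFIX, taken, two_word_frac=0.25)

    drugs = Lexicon(kind="drug")
    for name in drug_names:
        drugs.add(name, name)
    ses = Lexicon(kind="side_effect")
    for name in se_names:
        ses.add(name, name)

    # latent classes partition the SE lexicon into class pools
    n_cls = params.n_latent_classes
    pool_size = params.n_ses // n_cls
    class_pools = [
        se_names[c * pool_size : (c + 1) * pool_size] for c in range(n_cls)
    ]
    leftover = se_names[n_cls * pool_size :]
    if leftover:
        class_pools[-1] = class_pools[-1] + leftover

    latent_class = {d: i % n_cls for i, d in enumerate(drug_names)}
    fidelity = {d: rng.uniform(0.5, 1.0) for d in drug_names}

    k_true = max(params.ses_per_sentence, round(params.true_pair_density * params.n_ses))
    true_ses: dict[str, list[str]] = {}
    truth_pairs: set[tuple[str, str]] = set()
    for d in drug_names:
        pool = class_pools[latent_class[d]]
        n_in_class = min(len(pool), max(1, round(fidelity[d] * k_true)))
        chosen = rng.sample(pool, n_in_class)
        others = [s for s in se_names if s not in pool]
        n_out = min(len(others), k_true - n_in_class)
        if n_out > 0:
            chosen += rng.sample(others, n_out)
        true_ses[d] = chosen
        truth_pairs.update((d, s) for s in chosen)

    corpus = _build_corpus(params, rng, drug_names, se_names, true_ses)
    prior = _nested_prior(truth_pairs, params.prior_coverage)

    attribute_tables = {
        kind: _attribute_table(rng, kind, n_attr, drug_names, latent_class, fidelity, n_cls)
        for kind, n_attr in (("targets", 8), ("metabolism", 6), ("indications", 8))
    }
    score_tables = {
        "database": _class_score_table(rng, "database", drug_names, latent_class, fidelity, scale=10.0, noise=2.0),
        "similarity": _class_score_table(rng, "similarity", drug_names, latent_class, fidelity, scale=4.0, noise=1.0),
        "experimental": _flat_score_table(rng, "experimental", drug_names, high=5.0),
    }

    return SynthBundle(
        corpus=corpus,
        truth=KnownPairKB(frozenset(truth_pairs)),
        prior=prior,
        drugs=drugs,
        ses=ses,
        attribute_tables=attribute_tables,
        score_tables=score_tables,
        latent_class=latent_class,
    )


def _build_corpus(
    params: SynthParams,
    rng: random.Random,
    drug_names: list[str],
    se_names: list[str],
    true_ses: dict[str, list[str]],
) -> list[AbstractRecord]:
    corpus = []
    for a in range(params.n_abstracts):
        pmid = f"syn{a:05d}"
        drug = drug_names[a % len(drug_names)]
        sentences: list[tuple[str, list[tuple[int, int]]]] = []
        title = f"A clinical study of {drug} in patients."
        t_start = title.index(drug)
        sentences.append((title, [(t_start, t_start + len(drug))]))

        ses_list = list(true_ses[drug])
        rng.shuffle(ses_list)
        chunks = [
            ses_list[i : i + params.ses_per_sentence]
            for i in range(0, len(ses_list), params.ses_per_sentence)
        ]
        if chunks and len(chunks[-1]) < 2:
            # keep the >=2-SEs-per-reporting-sentence invariant
            extra = next(s for s in ses_list if s not in chunks[-1])
            chunks[-1].append(extra)
        body = [
            _drug_se_sentence(rng.randrange(3), drug, chunk) for chunk in chunks
        ]

        n_se_sent = len(body)
        if params.confound_rate > 0 and n_se_sent:
            n_conf = round(
                params.confound_rate / (1.0 - params.confound_rate) * n_se_sent
            )
            for _ in range(n_conf):
                c_drug = rng.choice(drug_names)
                non_ses = [s for s in se_names if s not in true_ses[c_drug]]
                if len(non_ses) < params.ses_per_sentence:
                    raise ValueError(
                        "cannot build a confounding sentence: drug "
                        f"{c_drug!r} has almost every SE term as a true SE"
                    )
                body.append(
                    _drug_se_sentence(
                        rng.randrange(3),
                        c_drug,
                        rng.sample(non_ses, params.ses_per_sentence),
                    )
                )
        for _ in range(params.filler_per_abstract):
            body.append((rng.choice(_FILLER), []))
        rng.shuffle(body)
        sentences.extend(body)

        records = [
            SentenceRecord(unit_id=f"{pmid}:{k}", pmid=pmid, text=text, np_spans=spans)
            for k, (text, spans) in enumerate(sentences)
        ]
        corpus.append(AbstractRecord(pmid=pmid, sentences=records))
    return corpus


def _nested_prior(truth_pairs: set[tuple[str, str]], coverage: float) -> KnownPairKB:
    """Deterministic nested subset: coverage c' > c always contains c's pairs."""
    if coverage == 0:
        return KnownPairKB(frozenset())
    ordered = sorted(truth_pairs, key=lambda p: _priority(p))
    n = math.ceil(coverage * len(ordered))
    return KnownPairKB(frozenset(ordered[:n]))


def _priority(pair: tuple[str, str]) -> float:
    # seed-independent deterministic pseudo-priority so priors nest across runs
    return random.Random(f"prior:{pair[0]}:{pair[1]}").random()


def _attribute_table(
    rng: random.Random,
    kind: str,
    n_attr: int,
    drug_names: list[str],
    latent_class: dict[str, int],
    fidelity: dict[str, float],
    n_cls: int,
) -> AttributeTable:
    pool_size = max(n_attr + 4, 12)
    class_pools = [
        [f"{kind[:3]}_c{c}_{j}" for j in range(pool_size)] for c in range(n_cls)
    ]
    noise_pool = [f"{kind[:3]}_x_{j}" for j in range(4 * pool_size)]
    attrs: dict[str, set[str]] = {}
    for d in drug_names:
        pool = class_pools[latent_class[d]]
        n_in = min(len(pool), max(1, round(fidelity[d] * n_attr)))
        chosen = set(rng.sample(pool, n_in))
        n_out = n_attr - n_in
        if n_out > 0:
            chosen |= set(rng.sample(noise_pool, n_out))
        attrs[d] = chosen
    return AttributeTable(kind=kind, attributes=attrs)


def _class_score_table(
    rng: random.Random,
    kind: str,
    drug_names: list[str],
    latent_class: dict[str, int],
    fidelity: dict[str, float],
    scale: float,
    noise: float,
) -> ScoreTable:
    scores: dict[frozenset[str], float] = {}
    for i, d1 in enumerate(drug_names):
        for d2 in drug_names[i + 1 :]:
            base = rng.uniform(0, noise)
            if latent_class[d1] == latent_class[d2]:
                base += scale * fidelity[d1] * fidelity[d2]
            scores[frozenset((d1, d2))] = base
    return ScoreTable(kind=kind, scores=scores)


def _flat_score_table(
    rng: random.Random, kind: str, drug_names: list[str], high: float
) -> ScoreTable:
    scores = {
        frozenset((d1, d2)): rng.uniform(0, high)
        for i, d1 in enumerate(drug_names)
        for d2 in drug_names[i + 1 :]
    }
    return ScoreTable(kind=kind, scores=scores)


# ---------------------------------------------------------------------------
# The worked-example fixtures
# ---------------------------------------------------------------------------

_FIXTURE_DRUGS = [
    "irinotecan", "docetaxel", "cisplatin", "ondansetron",
    "lidocaine", "tramadol", "fentanyl", "mitomycin",
]
# rocuronium is deliberately absent: it is mentioned in one fixture sentence
# but is not part of the drug lexicon, so no rocuronium pair is extracted.

_FIXTURE_SES = [
    "diarrhea", "neutropenia", "nausea", "fatigue", "anorexia",
    "thrombosis/embolism", "pain", "decreases in hemoglobin",
    "nausea/vomiting", "hyperbilirubinemia",
]

_FIXTURE_TEXTS = [
    (
        "19139178",
        "At the final irinotecan dose of 50 mg/m(2), grade 3 or higher "
        "toxicity included diarrhea (26%), neutropenia (21%), nausea (18%), "
        "fatigue (16%), anorexia (13%), and thrombosis/embolism (13%).",
    ),
    (
        "tpc-title",
        "Weekly docetaxel, cisplatin, and irinotecan (TPC): results of a "
        "multicenter phase II trial in patients with metastatic "
        "esophagogastric cancer",
    ),
    (
        "12032018",
        "Ondansetron, lidocaine, tramadol, and fentanyl were effective in "
        "preventing and decreasing the level of rocuronium injection pain.",
    ),
    (
        "17577624",
        "Decreases in hemoglobin, nausea/vomiting, and hyperbilirubinemia "
        "were observed to be influenced by the previous use of irinotecan "
        "(OR = 3.07, P = 0.003), mitomycin (OR = 2.28, P = 0.004), and "
        "cisplatin (OR = 1.60, P = 0.007), respectively.",
    ),
]

_FIXTURE_PRIOR = {("irinotecan", "diarrhea"), ("ondansetron", "pain")}


def paper_fixtures() -> SynthBundle:
    """The packaged worked-example corpus: one known-good unit per archetype.

    Four single-sentence abstracts: a multi-SE reporting sentence, a
    treatment-style title with three drugs and no side effect, a sentence
    whose gate pair is itself a knowledge-base error (a treatment pair
    mislabeled as a side effect), and an n-by-m sentence with three drugs and
    three side effects.  Gold NP spans cover every lexicon term occurrence.
    """
    drugs = Lexicon(kind="drug")
    for name in _FIXTURE_DRUGS:
        drugs.add(name, name)
    ses = Lexicon(kind="side_effect")
    for name in _FIXTURE_SES:
        ses.add(name, name)

    corpus = []
    for pmid, text in _FIXTURE_TEXTS:
        probe = SentenceRecord(unit_id=f"{pmid}:0", pmid=pmid, text=text)
        spans = sorted(
            m.span
            for lex in (drugs, ses)
            for m in find_term_matches(probe, lex)
        )
        record = SentenceRecord(
            unit_id=f"{pmid}:0", pmid=pmid, text=text, np_spans=spans
        )
        corpus.append(AbstractRecord(pmid=pmid, sentences=[record]))

    kb = KnownPairKB(frozenset(_FIXTURE_PRIOR))
    return SynthBundle(
        corpus=corpus, truth=kb, prior=kb, drugs=drugs, ses=ses
    )


# ---------------------------------------------------------------------------
# Bundle export
# ---------------------------------------------------------------------------


def write_bundle(bundle: SynthBundle, out_dir: str | Path) -> None:
    """Write the full bundle in the standard TSV/JSONL interchange formats."""
    from .corpus_index import write_corpus_jsonl
    from .lexicon_kb import write_known_pairs, write_lexicon

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_corpus_jsonl(bundle.corpus, out / "corpus.jsonl")
    write_lexicon(bundle.drugs, out / "drugs.tsv")
    write_lexicon(bundle.ses, out / "ses.tsv")
    write_known_pairs(bundle.truth, out / "truth_pairs.tsv")
    write_known_pairs(bundle.prior, out / "prior_pairs.tsv")
    for kind, table in bundle.attribute_tables.items():
        with open(out / f"attr_{kind}.tsv", "w", encoding="utf-8") as fh:
            fh.write("# drug\tattribute\n")
            for d in sorted(table.attributes):
                for a in sorted(table.attributes[d]):
                    fh.write(f"{d}\t{a}\n")
    for kind, table in bundle.score_tables.items():
        with open(out / f"score_{kind}.tsv", "w", encoding="utf-8") as fh:
            fh.write("# drug1\tdrug2\tscore\n")
            for key in sorted(table.scores, key=sorted):
                d1, d2 = sorted(key)
                fh.write(f"{d1}\t{d2}\t{table.scores[key]:.6g}\n")
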