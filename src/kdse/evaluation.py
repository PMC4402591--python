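"""Per-drug evaluation protocol: knowledge-driven vs SVM extraction.

For a panel of drugs (the original comparison used the ten drugs with the
most known side effects), each drug's known pairs are split in half; the
train halves (plus all other drugs' pairs) act as the knowledge-driven prior
and as the SVM's distant labels, the test halves are the gold standard.  Both
methods see the same input sentences — those containing at least one panel
drug and at least one side-effect term — and are scored per drug by
precision, recall and F1 on pair identity, with unweighted column means and
the per-drug relative F1 increase of the knowledge-driven method over the
SVM.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .corpus_index import CorpusIndex
from .kd_extraction import extract
from .lexicon_kb import DEFAULT_SEED, KnownPairKB, split_pairs_per_drug
from .np_matching import NPConfig
from .svm_baseline import SVMConfig, build_training_set, svm_extract, train


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        for v in (self.precision, self.recall, self.f1):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PRF value out of [0,1]: {v}")


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def prf(p: float, r: float) -> PRF:
    return PRF(precision=p, recall=r, f1=f1(p, r))


def f1_increase(f1_kd: float, f1_svm: float) -> float:
    """Relative F1 gain of the knowledge-driven method, in percent."""
    if f1_svm <= 0:
        raise ValueError("f1_svm must be positive for a relative increase")
    return 100.0 * (f1_kd - f1_svm) / f1_svm


def score_drug(
    extracted: set[tuple[str, str]], test: set[tuple[str, str]]
) -> PRF:
    """Precision/recall/F1 of one drug's extracted pairs against held-out pairs."""
    if not test:
        raise ValueError("empty test set")
    drugs_in = {d for d, _ in extracted} | {d for d, _ in test}
    if len(drugs_in) > 1:
        raise ValueError(f"score_drug got pairs of several drugs: {sorted(drugs_in)}")
    tp = len(extracted & test)
    p = tp / len(extracted) if extracted else 0.0
    r = tp / len(test)
    return prf(p, r)


@dataclass
class DrugRow:
    drug_id: str
    kd: PRF
    svm: PRF
    f1_increase_pct: float | None  # None when the SVM F1 is zero


@dataclass
class EvaluationReport:
    per_drug: dict[str, DrugRow]
    kd_avg: PRF = field(init=False)
    svm_avg: PRF = field(init=False)
    mean_f1_increase_pct: float | None = field(init=False)
    kd_f1_of_means: float = field(init=False)
    svm_f1_of_means: float = field(init=False)

    def __post_init__(self) -> None:
        rows = list(self.per_drug.values())
        if not rows:
            raise ValueError("empty report")
        kd_p = statistics.fmean(r.kd.precision for r in rows)
        kd_r = statistics.fmean(r.kd.recall for r in rows)
        svm_p = statistics.fmean(r.svm.precision for r in rows)
        svm_r = statistics.fmean(r.svm.recall for r in rows)
        # column means: the average F1 is the mean of per-drug F1s ...
        self.kd_avg = PRF(kd_p, kd_r, statistics.fmean(r.kd.f1 for r in rows))
        self.svm_avg = PRF(svm_p, svm_r, statistics.fmean(r.svm.f1 for r in rows))
        # ... but the harmonic mean of the average P and R is also reported,
        # labeled, because the two summaries differ in general.
        self.kd_f1_of_means = f1(kd_p, kd_r)
        self.svm_f1_of_means = f1(svm_p, svm_r)
        increases = [r.f1_increase_pct for r in rows if r.f1_increase_pct is not None]
        self.mean_f1_increase_pct = (
            statistics.fmean(increases) if increases else None
        )


def aggregate(rows: dict[str, tuple[PRF, PRF]]) -> EvaluationReport:
    """Assemble a report from per-drug (kd, svm) PRF pairs.

    The mean F1 increase is the mean of per-drug increases, not the increase
    of the mean F1s; drugs with a zero SVM F1 contribute no increase.
    """
    per_drug = {}
    for drug_id, (kd, svm) in rows.items():
        inc = f1_increase(kd.f1, svm.f1) if svm.f1 > 0 else None
        per_drug[drug_id] = DrugRow(drug_id=drug_id, kd=kd, svm=svm, f1_increase_pct=inc)
    return EvaluationReport(per_drug=per_drug)


def input_sentence_filter(
    index: CorpusIndex, panel_drugs: list[str]
) -> set[str]:
    """Sentences containing >=1 panel drug and >=1 side-effect term."""
    drug_units: set[str] = set()
    for d in panel_drugs:
        drug_units |= index.units_with_id(d, "drug")
    se_units: set[str] = set()
    for term, units in index.postings.items():
        if term in index.ses.entries:
            se_units |= units
    return drug_units & se_units


def run_protocol(
    index: CorpusIndex,
    kb: KnownPairKB,
    panel_drugs: list[str],
    seed: int = DEFAULT_SEED,
    svm_config: SVMConfig | None = None,
    np: NPConfig = NPConfig(),
    fraction: float = 0.5,
) -> EvaluationReport:
    """The full comparison protocol on one indexed corpus.

    Deterministic given ``seed``: the per-drug split, the SVM's negative
    sample and the SVM fit all derive their randomness from it.
    """
    train_kb, test_kb = split_pairs_per_drug(kb, panel_drugs, fraction, seed)
    unit_filter = input_sentence_filter(index, panel_drugs)

    kd_result = extract(index, train_kb, level="sentence", np=np, unit_filter=unit_filter)
    kd_pairs = kd_result.novel_pairs()

    svm_config = svm_config or SVMConfig(seed=seed)
    ls = build_training_set(index, kb, excluded_pairs=test_kb, seed=seed)
    model = train(ls, svm_config)
    svm_result = svm_extract(
        index, model, unit_filter=unit_filter, np_cfg=np, exclude=train_kb
    )
    svm_pairs = svm_result.novel_pairs()

    rows: dict[str, tuple[PRF, PRF]] = {}
    for drug_id in sorted(panel_drugs):
        test_d = {p for p in test_kb if p[0] == drug_id}
        kd_d = {p for p in kd_pairs if p[0] == drug_id}
        svm_d = {p for p in svm_pairs if p[0] == drug_id}
        rows[drug_id] = (score_drug(kd_d, test_d), score_drug(svm_d, test_d))
    report = aggregate(rows)
    report_meta = {
        "seed": seed,
        "n_input_sentences": len(unit_filter),
        "svm_cv_accuracy": model.metadata.get("cv_accuracy"),
    }
    report.meta = report_meta  # type: ignore[attr-defined]
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def report_to_frame(report: EvaluationReport) -> pd.DataFrame:
    """Comparison-table layout: one row per drug plus an Average row."""
    rows = []
    for drug_id, r in sorted(report.per_drug.items()):
        rows.append(
            {
                "drug": drug_id,
                "kd_precision": r.kd.precision,
                "kd_recall": r.kd.recall,
                "kd_f1": r.kd.f1,
                "svm_precision": r.svm.precision,
                "svm_recall": r.svm.recall,
                "svm_f1": r.svm.f1,
                "f1_increase_pct": r.f1_increase_pct,
            }
        )
    rows.append(
        {
            "drug": "Average",
            "kd_precision": report.kd_avg.precision,
            "kd_recall": report.kd_avg.recall,
            "kd_f1": report.kd_avg.f1,
            "svm_precision": report.svm_avg.precision,
            "svm_recall": report.svm_avg.recall,
            "svm_f1": report.svm_avg.f1,
            "f1_increase_pct": report.mean_f1_increase_pct,
        }
    )
    return pd.DataFrame(rows)


def write_report(report: EvaluationReport, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
    frame = report_to_frame(report)
    doc = {
        "per_drug": frame[frame["drug"] != "Average"].to_dict(orient="records"),
        "averages": frame[frame["drug"] == "Average"].iloc[0].to_dict(),
        "kd_f1_of_means": report.kd_f1_of_means,
        "svm_f1_of_means": report.svm_f1_of_means,
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.3f")
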