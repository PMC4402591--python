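import itertools
import random
import statistics

import pytest

from kdse.correlation import (
    AttributeTable,
    ScoreTable,
    attribute_overlap_curve,
    load_attribute_table,
    load_score_table,
    score_curve,
    shared_se_counts,
    write_curve,
)
from kdse.synthetic_corpus import SynthParams, generate


def test_shared_counts_identical_and_disjoint_sets():
    pairs = {("d1", f"s{i}") for i in range(7)} | {("d2", f"s{i}") for i in range(7)}
    shared = shared_se_counts(pairs)
    assert shared[frozenset(("d1", "d2"))] == 7
    pairs |= {("d3", "x1"), ("d3", "x2")}
    shared = shared_se_counts(pairs)
    assert shared[frozenset(("d1", "d3"))] == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_shared_counts_equal_brute_force(seed):
    rng = random.Random(seed)
    pairs = {
        (f"d{rng.randrange(20)}", f"s{rng.randrange(30)}") for _ in range(150)
    }
    shared = shared_se_counts(pairs)
    drugs = sorted({d for d, _ in pairs})
    for d1, d2 in itertools.combinations(drugs, 2):
        expect = len(
            {s for d, s in pairs if d == d1} & {s for d, s in pairs if d == d2}
        )
        assert shared[frozenset((d1, d2))] == expect


def test_attribute_curve_uniform_table_is_flat_at_one():
    pairs = {("d1", "a"), ("d1", "b"), ("d2", "a"), ("d2", "b"), ("d3", "z")}
    table = AttributeTable(
        kind="targets", attributes={d: {"g"} for d in ("d1", "d2", "d3")}
    )
    curve = attribute_overlap_curve(shared_se_counts(pairs), table, [0, 1, 2])
    assert [p.mean for p in curve.points] == [1.0, 1.0, 1.0]


def test_curve_beyond_max_cutoff_is_undefined_not_zero():
    pairs = {("d1", "a"), ("d2", "a")}
    table = AttributeTable(kind="targets", attributes={"d1": {"g"}, "d2": {"g"}})
    curve = attribute_overlap_curve(shared_se_counts(pairs), table, [0, 100])
    assert curve.points[1].n_pairs == 0
    assert curve.points[1].mean is None


def test_score_curve_constant_scores_and_missing_policy():
    pairs = {("d1", "a"), ("d2", "a"), ("d3", "b")}
    shared = shared_se_counts(pairs)
    table = ScoreTable(
        kind="database",
        scores={frozenset(("d1", "d2")): 3.0},
    )
    zero = score_curve(shared, table, [0], missing="zero")
    assert zero.points[0].mean == pytest.approx(3.0 / 3)
    skip = score_curve(shared, table, [0], missing="skip")
    assert skip.points[0].mean == pytest.approx(3.0)
    empty = score_curve(shared, ScoreTable(kind="x", scores={}), [0], missing="zero")
    assert empty.points[0].mean == 0.0


def test_pair_counts_non_increasing_in_cutoff(small_bundle):
    shared = shared_se_counts(set(small_bundle.truth.pairs))
    table = small_bundle.attribute_tables["targets"]
    curve = attribute_overlap_curve(shared, table, [0, 1, 2, 4, 6, 8])
    counts = [p.n_pairs for p in curve.points]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.fixture(scope="module")
def latent_bundle():
    # correlation study conditions: many drugs and dense per-drug SE sets so
    # every cutoff bin keeps enough qualifying pairs for stable means
    return generate(
        SynthParams(
            n_drugs=60, n_ses=60, n_abstracts=60, true_pair_density=0.25, seed=19
        )
    )


CUTOFFS = [0, 2, 4, 6, 8]


def test_class_linked_attribute_curves_increase(latent_bundle):
    """Shared SEs and shared attributes co-vary through the latent classes."""
    shared = shared_se_counts(set(latent_bundle.truth.pairs))
    for kind in ("targets", "metabolism", "indications"):
        curve = attribute_overlap_curve(
            shared, latent_bundle.attribute_tables[kind], CUTOFFS
        )
        means = curve.means()
        assert all(m is not None for m in means)
        assert all(b > a for a, b in zip(means, means[1:])), (kind, means)


def test_class_linked_scores_rise_and_independent_scores_stay_flat(latent_bundle):
    shared = shared_se_counts(set(latent_bundle.truth.pairs))
    for kind in ("database", "similarity"):
        curve = score_curve(shared, latent_bundle.score_tables[kind], CUTOFFS)
        means = curve.means()
        assert all(b > a for a, b in zip(means, means[1:])), (kind, means)
    flat = score_curve(shared, latent_bundle.score_tables["experimental"], CUTOFFS)
    base = flat.points[0]
    top = flat.points[-1]
    values = list(latent_bundle.score_tables["experimental"].scores.values())
    sem = statistics.stdev(values) / (top.n_pairs ** 0.5)
    assert abs(top.mean - base.mean) < 3 * sem


def test_permutation_null_flattens_attribute_curve(latent_bundle):
    """Shuffling drug->attribute assignments destroys the correlation.

    Averaged over many permutations, the high-cutoff mean equals the
    all-pairs mean within the simulation confidence interval, whereas the
    unshuffled table shows a large positive gap.
    """
    shared = shared_se_counts(set(latent_bundle.truth.pairs))
    table = latent_bundle.attribute_tables["targets"]
    true_curve = attribute_overlap_curve(shared, table, [0, CUTOFFS[-1]])
    true_gap = true_curve.points[-1].mean - true_curve.points[0].mean

    rng = random.Random(5)
    drugs = sorted(table.attributes)
    gaps = []
    for _ in range(30):
        perm = drugs[:]
        rng.shuffle(perm)
        shuffled = AttributeTable(
            kind="targets",
            attributes={d: table.attributes[p] for d, p in zip(drugs, perm)},
        )
        curve = attribute_overlap_curve(shared, shuffled, [0, CUTOFFS[-1]])
        gaps.append(curve.points[-1].mean - curve.points[0].mean)
    mean_gap = statistics.fmean(gaps)
    ci = 3 * statistics.stdev(gaps) / len(gaps) ** 0.5
    assert abs(mean_gap) < ci
    assert true_gap > mean_gap + ci  # the real curve is not flat


def test_table_io_roundtrip(tmp_path, latent_bundle):
    table = latent_bundle.attribute_tables["targets"]
    p = tmp_path / "attr.tsv"
    with open(p, "w") as fh:
        for d in sorted(table.attributes):
            for a in sorted(table.attributes[d]):
                fh.write(f"{d}\t{a}\n")
    back = load_attribute_table(p, "targets")
    assert back.attributes == table.attributes

    scores = latent_bundle.score_tables["database"]
    q = tmp_path / "scores.tsv"
    with open(q, "w") as fh:
        for key in sorted(scores.scores, key=sorted):
            d1, d2 = sorted(key)
            fh.write(f"{d1}\t{d2}\t{scores.scores[key]!r}\n")
    back2 = load_score_table(q, "database")
    assert back2.scores == scores.scores

    curve = attribute_overlap_curve(
        shared_se_counts(set(latent_bundle.truth.pairs)), table, [0, 2]
    )
    write_curve(curve, tmp_path / "curve.tsv")
    lines = (tmp_path / "curve.tsv").read_text().strip().splitlines()
    assert len(lines) == 4  # two header lines + two points
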