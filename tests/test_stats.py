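import math
import random

import numpy as np
import pytest
from scipy import stats as sps

from mosaicmito.stats import (
    ContingencyTable2x2,
    fisher_exact_two_sided,
    group_summary,
    location_tally,
    report_p,
    stratified_outcome_test,
    student_t_two_sided,
)


# ---------------------------------------------------------------------------
# Fisher exact

def test_symmetric_table_p1():
    assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)).p_value == 1.0


def test_fixture_euploid_table():
    # stage x euploid-vs-other from the bundled cohort
    r = fisher_exact_two_sided(ContingencyTable2x2(4, 23, 14, 10))
    assert report_p(r.p_value) == 0.002


def test_degenerate_margins():
    r = fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 5))
    assert r.p_value == 1.0 and r.degenerate


def test_invalid_table():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def test_row_and_column_swap_invariance():
    rng = random.Random(17)
    for _ in range(100):
        a, b, c, d = (rng.randint(0, 12) for _ in range(4))
        if not any((a, b, c, d)):
            continue
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
        assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)).p_value == p
        assert fisher_exact_two_sided(ContingencyTable2x2(b, a, d, c)).p_value == p


def test_fisher_matches_scipy_random_tables():
    rng = random.Random(5)
    for _ in range(200):
        a, b, c, d = (rng.randint(0, 15) for _ in range(4))
        table = ContingencyTable2x2(a, b, c, d)
        if table.degenerate:
            continue
        mine = fisher_exact_two_sided(table).p_value
        theirs = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert mine == pytest.approx(theirs, rel=1e-9), (a, b, c, d)


# ---------------------------------------------------------------------------
# Student t

def test_identical_groups_p1():
    r = student_t_two_sided([1.0, 1.0, 1.0], [1.0, 1.0])
    assert r.p_value == 1.0 and r.degenerate


def test_zero_variance_different_means():
    r = student_t_two_sided([1.0, 1.0], [2.0, 2.0])
    assert r.p_value == 0.0 and r.degenerate


def test_group_size_precondition():
    with pytest.raises(ValueError):
        student_t_two_sided([1.0], [1.0, 2.0])


def test_t_matches_textbook_formula():
    rng = np.random.default_rng(12345)
    x = rng.normal(0, 1, 20)
    y = rng.normal(0.4, 1, 20)
    r = student_t_two_sided(x, y)
    # closed-form pooled t and p via the regularized incomplete beta
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    from scipy.special import betainc

    p = betainc(df / 2, 0.5, df / (df + t * t))
    assert r.statistic == pytest.approx(t, rel=1e-12)
    assert r.p_value == pytest.approx(p, rel=1e-10)
    assert r.df == df


def test_t_invariances():
    rng = np.random.default_rng(7)
    x = list(rng.normal(0, 1, 12))
    y = list(rng.normal(1, 2, 9))
    p = student_t_two_sided(x, y).p_value
    assert student_t_two_sided(y, x).p_value == pytest.approx(p, rel=1e-12)
    shifted = student_t_two_sided([v + 5 for v in x], [v + 5 for v in y]).p_value
    assert shifted == pytest.approx(p, rel=1e-9)


# ---------------------------------------------------------------------------
# summaries

def test_group_summary_post_euploid_cells():
    values = [0.0] * 10 + [1.0] * 3 + [2.0]
    s = group_summary(values, "euploid")
    assert round(s.mean, 2) == 0.36
    assert round(s.sd_population, 2) == 0.61


def test_group_summary_single_value():
    s = group_summary([5.0])
    assert (s.mean, s.sd_population, s.sd_sample) == (5.0, 0.0, None)


def test_group_summary_hand_arithmetic():
    s = group_summary([1.0, 2.0, 3.0])
    assert s.mean == 2.0
    assert s.sd_sample == pytest.approx(1.0)
    assert s.sd_population == pytest.approx(math.sqrt(2.0 / 3.0))


def test_group_summary_empty_errors():
    with pytest.raises(ValueError):
        group_summary([])


# ---------------------------------------------------------------------------
# stratified test

def test_stratified_all_below_threshold_degenerate():
    counts = {"a": 0.0, "b": 0.5, "c": 1.0}
    outcomes = {"a": True, "b": False, "c": True}
    r = stratified_outcome_test(counts, outcomes, threshold=1.0)
    assert r.p_value == 1.0 and r.degenerate


def test_stratified_skips_nd():
    counts = {"a": 2.0, "b": None, "c": 0.0, "d": 2.0, "e": 0.0}
    outcomes = {"a": False, "b": True, "c": True, "d": None, "e": True}
    r = stratified_outcome_test(counts, outcomes)
    assert r.inputs["table"] == (0, 1, 2, 0)  # b and d excluded


def test_stratified_threshold_strictly_greater():
    counts = {"a": 1.0, "b": 1.5}
    outcomes = {"a": True, "b": False}
    r = stratified_outcome_test(counts, outcomes, threshold=1.0)
    assert r.inputs["table"] == (0, 1, 1, 0)  # count == threshold goes below


# ---------------------------------------------------------------------------
# location tally

def test_location_tally_small_example():
    gene_counts = {
        "e1": {"MT-ND1": 1.0},
        "e2": {},
        "e3": {"MT-ND1": 0.5, "MT-CYB": 1.0},
        "e4": {},
    }
    groups = {"e1": "culturable", "e2": "culturable", "e3": "non_culturable",
              "e4": None}
    complexes = {"MT-ND1": "I", "MT-CYB": "III"}
    tally = location_tally(gene_counts, groups, complexes)
    per_gene = tally["per_gene"]
    row = per_gene.loc[("culturable", "MT-ND1")]
    assert row["mean"] == pytest.approx(0.5)
    assert row["n_embryos_with_mutation"] == 1
    assert row["rate_embryos_with_mutation"] == pytest.approx(0.5)
    assert per_gene.loc[("non_culturable", "MT-CYB"), "mean"] == pytest.approx(1.0)
    # embryos mapped to None never appear
    assert "e4" not in str(tally)


def test_location_tally_complex_sums_before_averaging():
    gene_counts = {
        "e1": {"MT-ND1": 1.0, "MT-ND2": 1.0},
        "e2": {},
    }
    groups = {"e1": "g", "e2": "g"}
    complexes = {"MT-ND1": "I", "MT-ND2": "I"}
    tally = location_tally(gene_counts, groups, complexes)
    row = tally["per_complex"].loc[("g", "I")]
    # per-embryo complex counts are [2, 0]: mean 1, population SD 1
    assert row["mean"] == pytest.approx(1.0)
    assert row["sd_population"] == pytest.approx(1.0)
    assert row["n_embryos_with_mutation"] == 1
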