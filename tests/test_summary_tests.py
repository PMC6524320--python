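"""Summary-statistic tests and the two clustering-adjustment conventions.

The summary t-test is checked against the independent oracle of rebuilding a
raw dataset with exactly the given n/mean/SD and testing it directly; the
chi-squared scaling identity is checked against a hand-rolled
sum((O-E)^2/E) on the scaled table.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clusterbias import (
    AggregateBaselineTable,
    CategoricalSummaryRow,
    ContinuousSummaryRow,
    ValidationError,
    adjust_categorical,
    adjust_continuous,
    chi_squared_from_counts,
    run_aggregate_table,
    t_test_from_summary,
)
from clusterbias.aggregate_io import ClusterDesign


def raw_data_with_stats(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """A raw sample whose sample mean and SD (ddof=1) equal the targets exactly."""
    x = rng.standard_normal(n)
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z


def pearson_by_hand(observed: np.ndarray) -> float:
    total = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / total
    return float(((observed - expected) ** 2 / expected).sum())


# ---------------------------------------------------------------------------
# t-test from summaries
# ---------------------------------------------------------------------------


def test_identical_arms_give_t_zero_p_one():
    row = ContinuousSummaryRow("x", 30, 5.0, 2.0, 30, 5.0, 2.0)
    res = t_test_from_summary(row)
    assert res.statistic_unadjusted == 0.0
    assert res.p_unadjusted == 1.0


def test_hand_computed_pooled_example():
    res = t_test_from_summary(ContinuousSummaryRow("x", 16, 10.0, 4.0, 16, 6.0, 4.0))
    assert res.statistic_unadjusted == pytest.approx(4.0 / (4.0 * math.sqrt(2.0 / 16.0)))
    assert res.df == 30
    assert res.p_unadjusted == pytest.approx(0.00826, abs=5e-5)


@pytest.mark.parametrize("variant", ["pooled", "welch"])
def test_t_matches_raw_data_oracle(variant):
    rng = np.random.default_rng(7)
    for _ in range(20):
        n1, n2 = int(rng.integers(5, 60)), int(rng.integers(5, 60))
        m1, m2 = rng.normal(size=2)
        s1, s2 = rng.uniform(0.3, 3.0, size=2)
        x1 = raw_data_with_stats(n1, m1, s1, rng)
        x2 = raw_data_with_stats(n2, m2, s2, rng)
        res = t_test_from_summary(
            ContinuousSummaryRow("x", n1, m1, s1, n2, m2, s2), variant=variant
        )
        ref = stats.ttest_ind(x1, x2, equal_var=(variant == "pooled"))
        assert res.statistic_unadjusted == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_unadjusted == pytest.approx(ref.pvalue, rel=1e-10)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    n1=st.integers(3, 200),
    n2=st.integers(3, 200),
    m1=st.floats(-50, 50),
    m2=st.floats(-50, 50),
    s1=st.floats(0.01, 20),
    s2=st.floats(0.01, 20),
)
def test_arm_swap_negates_statistic_preserves_p(n1, n2, m1, m2, s1, s2):
    fwd = t_test_from_summary(ContinuousSummaryRow("x", n1, m1, s1, n2, m2, s2))
    rev = t_test_from_summary(ContinuousSummaryRow("x", n2, m2, s2, n1, m1, s1))
    assert fwd.statistic_unadjusted == pytest.approx(-rev.statistic_unadjusted, rel=1e-12)
    assert fwd.p_unadjusted == pytest.approx(rev.p_unadjusted, rel=1e-12)


def test_degenerate_zero_sd_flagged_not_raised():
    equal = t_test_from_summary(
        ContinuousSummaryRow("x", 10, 2.0, 0.0, 10, 2.0, 0.0, allow_degenerate=True)
    )
    assert equal.degenerate and equal.p_unadjusted == 1.0
    unequal = t_test_from_summary(
        ContinuousSummaryRow("x", 10, 2.0, 0.0, 10, 3.0, 0.0, allow_degenerate=True)
    )
    assert unequal.degenerate and unequal.p_unadjusted == 0.0


# ---------------------------------------------------------------------------
# chi-squared from counts
# ---------------------------------------------------------------------------


def test_balanced_table_gives_chi2_zero_p_one():
    res = chi_squared_from_counts(CategoricalSummaryRow("g", ["a", "b"], [15, 15], [15, 15]))
    assert res.statistic_unadjusted == 0.0
    assert res.p_unadjusted == 1.0


def test_hand_computed_2x2_example():
    res = chi_squared_from_counts(CategoricalSummaryRow("g", ["a", "b"], [10, 20], [20, 10]))
    assert res.statistic_unadjusted == pytest.approx(20.0 / 3.0, rel=1e-12)
    assert res.p_unadjusted == pytest.approx(0.00982, abs=5e-5)
    assert res.statistic_unadjusted == pytest.approx(
        pearson_by_hand(np.array([[10, 20], [20, 10]], float)), rel=1e-12
    )


def test_level_permutation_invariance():
    a = chi_squared_from_counts(
        CategoricalSummaryRow("g", ["a", "b", "c"], [10, 20, 5], [20, 10, 7])
    )
    b = chi_squared_from_counts(
        CategoricalSummaryRow("g", ["c", "a", "b"], [5, 10, 20], [7, 20, 10])
    )
    assert a.statistic_unadjusted == pytest.approx(b.statistic_unadjusted, rel=1e-12)
    assert a.p_unadjusted == pytest.approx(b.p_unadjusted, rel=1e-12)


def test_all_zero_level_dropped_and_one_arm_table_rejected():
    res = chi_squared_from_counts(
        CategoricalSummaryRow("g", ["a", "b", "c"], [10, 20, 0], [20, 10, 0])
    )
    assert res.df == 1  # third level dropped
    with pytest.raises(ValidationError, match="one-arm"):
        # arm margins [0, 30]: the first arm saw nobody
        from clusterbias.summary_tests import _pearson_chi2

        _pearson_chi2(np.array([[0.0, 0.0], [20.0, 10.0]]), "g")


# ---------------------------------------------------------------------------
# adjustments
# ---------------------------------------------------------------------------


def test_unit_design_effect_is_identity():
    row = ContinuousSummaryRow("x", 30, 5.0, 2.0, 30, 4.0, 2.0)
    base = t_test_from_summary(row)
    for convention in ("statistic_division", "effective_sample_size"):
        adj = adjust_continuous(base, 1.0, convention)
        assert adj.statistic_adjusted == base.statistic_unadjusted
        assert adj.p_adjusted == base.p_unadjusted
    cat = CategoricalSummaryRow("g", ["a", "b"], [10, 20], [20, 10])
    adj = adjust_categorical(cat, 1.0)
    assert adj.p_adjusted == adj.p_unadjusted


def test_statistic_division_literal_rule():
    row = ContinuousSummaryRow("x", 16, 10.0, 4.0, 16, 6.0, 4.0)
    base = t_test_from_summary(row)
    adj = adjust_continuous(base, 2.0, "statistic_division")
    assert adj.statistic_adjusted == pytest.approx(base.statistic_unadjusted / 2.0)
    assert adj.df == base.df  # df untouched in this convention
    adj197 = adjust_continuous(base, 1.97, "statistic_division")
    assert adj197.statistic_adjusted == pytest.approx(2.8284271247 / 1.97, rel=1e-9)
    assert adj197.p_adjusted == pytest.approx(
        2.0 * stats.t.sf(2.8284271247 / 1.97, 30), rel=1e-9
    )


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    counts=st.lists(st.integers(1, 200), min_size=4, max_size=4),
    deff=st.floats(1.0, 25.0),
)
def test_chi2_scaling_identity(counts, deff):
    row = CategoricalSummaryRow("g", ["a", "b"], counts[:2], counts[2:])
    adj = adjust_categorical(row, deff)
    assert adj.statistic_adjusted == pytest.approx(
        adj.statistic_unadjusted / deff, rel=1e-12
    )
    observed = np.array([counts[:2], counts[2:]], float) / deff
    if adj.statistic_unadjusted > 0:
        assert adj.statistic_adjusted == pytest.approx(pearson_by_hand(observed), rel=1e-10)
    assert adj.p_adjusted >= adj.p_unadjusted - 1e-15


@pytest.mark.parametrize("convention", ["statistic_division", "effective_sample_size"])
def test_p_adjusted_monotone_in_deff(convention):
    rng = np.random.default_rng(21)
    grid = [1.0, 1.5, 2.0, 5.0, 20.0]
    for _ in range(10):
        row = ContinuousSummaryRow(
            "x",
            int(rng.integers(30, 200)),
            float(rng.normal()),
            float(rng.uniform(0.5, 2)),
            int(rng.integers(30, 200)),
            float(rng.normal()),
            float(rng.uniform(0.5, 2)),
        )
        base = t_test_from_summary(row)
        ps = [adjust_continuous(base, d, convention).p_adjusted for d in grid]
        assert all(b >= a - 1e-12 for a, b in zip(ps, ps[1:]))
        cat = CategoricalSummaryRow(
            "g",
            ["a", "b"],
            [int(c) for c in rng.integers(5, 100, 2)],
            [int(c) for c in rng.integers(5, 100, 2)],
        )
        cps = [adjust_categorical(cat, d).p_adjusted for d in grid]
        assert all(b >= a - 1e-12 for a, b in zip(cps, cps[1:]))


def test_deff_below_one_rejected():
    base = t_test_from_summary(ContinuousSummaryRow("x", 30, 5.0, 2.0, 30, 4.0, 2.0))
    with pytest.raises(ValidationError):
        adjust_continuous(base, 0.9)
    with pytest.raises(ValidationError):
        adjust_categorical(CategoricalSummaryRow("g", ["a", "b"], [1, 2], [3, 4]), 0.5)


# ---------------------------------------------------------------------------
# whole-table driver
# ---------------------------------------------------------------------------


def test_run_table_without_design_is_unadjusted(small_table):
    results = run_aggregate_table(small_table)
    assert [r.covariate_name for r in results] == small_table.covariates
    assert all(r.adjustment_convention == "none" for r in results)
    assert all(r.p_adjusted == r.p_unadjusted for r in results)


def test_run_table_with_unit_deff_leaves_p_unchanged(small_table):
    small_table.design = ClusterDesign(icc=0.0, n_clusters=10, n_total=200)
    results = run_aggregate_table(small_table)
    assert all(r.p_adjusted == r.p_unadjusted for r in results)
    assert all(r.design_effect_used == 1.0 for r in results)


def test_run_table_batch_mode_flags_degenerate_rows(small_table):
    small_table.continuous_rows.append(
        ContinuousSummaryRow("flat", 10, 1.0, 0.0, 10, 1.0, 0.0, allow_degenerate=True)
    )
    small_table.covariate_order.append("flat")
    results = run_aggregate_table(small_table)
    by_name = {r.covariate_name: r for r in results}
    assert by_name["flat"].degenerate
    assert len(results) == len(small_table.covariates)
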