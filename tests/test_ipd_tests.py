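"""Random-intercept ML fit, Wald test, ANOVA ICC, and binary covariates.

statsmodels MixedLM (ML) serves as the independent oracle for the
profile-likelihood fit; it is never the implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clusterbias import (
    ConvergenceError,
    IPDDataset,
    ValidationError,
    estimate_icc_anova,
    fit_random_intercept,
    lmm_wald_test,
    read_ipd,
    to_aggregate_table,
    write_ipd,
)
from clusterbias import ipd_tests
from conftest import make_clustered_ipd


# ---------------------------------------------------------------------------
# container and I/O
# ---------------------------------------------------------------------------


def test_cluster_spanning_two_arms_rejected():
    frame = pd.DataFrame(
        {"cluster_id": ["a", "a", "b", "b", "c", "c", "d", "d"],
         "arm": [0, 1, 0, 0, 1, 1, 0, 0], "y": np.arange(8.0)}
    )
    with pytest.raises(ValidationError, match="more than one arm"):
        IPDDataset(frame, {"y": "continuous"})


def test_ipd_csv_round_trip(tmp_path):
    ds = make_clustered_ipd(seed=1)
    path = tmp_path / "ipd.csv"
    write_ipd(ds, path)
    back = read_ipd(path)
    assert back.covariate_kinds == {"y": "continuous"}
    np.testing.assert_allclose(back.data["y"], ds.data["y"])


def test_two_level_text_covariate_recoded_binary(tmp_path):
    ds = make_clustered_ipd(seed=2)
    ds.data["sex"] = np.where(np.arange(len(ds.data)) % 2 == 0, "f", "m")
    path = tmp_path / "ipd.csv"
    ds.data.to_csv(path, index=False)
    back = read_ipd(path)
    assert back.covariate_kinds["sex"] == "binary"
    assert set(back.data["sex"].unique()) == {0, 1}


# ---------------------------------------------------------------------------
# random-intercept fit
# ---------------------------------------------------------------------------


def test_fit_matches_statsmodels_ml():
    smf = pytest.importorskip("statsmodels.formula.api")
    for seed, beta, icc in [(3, 0.5, 0.1), (4, 0.0, 0.05), (5, -0.3, 0.15)]:
        ds = make_clustered_ipd(seed=seed, n_clusters=30, cluster_size=20, beta=beta, icc=icc)
        fit = fit_random_intercept(ds, "y")
        ref = smf.mixedlm(
            "y ~ arm", ds.data, groups=ds.data["cluster_id"]
        ).fit(reml=False)
        assert fit.beta_treatment == pytest.approx(ref.params["arm"], rel=1e-5, abs=1e-8)
        assert fit.se_beta == pytest.approx(ref.bse["arm"], rel=1e-3)
        assert fit.sigma2_residual == pytest.approx(ref.scale, rel=1e-3)
        assert fit.sigma2_cluster == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=2e-2, abs=1e-3
        )
        assert fit.converged


def test_loglik_never_below_ols_endpoint():
    for seed in range(6):
        ds = make_clustered_ipd(seed=seed, icc=0.0 if seed % 2 else 0.1)
        fit = fit_random_intercept(ds, "y")
        y = ds.data["y"].to_numpy()
        arm = ds.data["arm"].to_numpy()
        resid = y - np.where(arm == 1, y[arm == 1].mean(), y[arm == 0].mean())
        sigma2 = float(resid @ resid) / y.size
        ols_loglik = -0.5 * y.size * (math.log(2 * math.pi * sigma2) + 1.0)
        assert fit.loglik >= ols_loglik - 1e-8


def test_repeated_fits_are_bit_identical():
    ds = make_clustered_ipd(seed=8, icc=0.08)
    a = fit_random_intercept(ds, "y")
    b = fit_random_intercept(ds, "y")
    assert (a.beta_treatment, a.se_beta, a.sigma2_cluster, a.loglik) == (
        b.beta_treatment,
        b.se_beta,
        b.sigma2_cluster,
        b.loglik,
    )


def test_symmetric_cluster_means_give_beta_zero():
    # two clusters per arm with identical cluster means across arms
    frame = pd.DataFrame(
        {
            "cluster_id": np.repeat(["a", "b", "c", "d"], 4),
            "arm": np.repeat([0, 0, 1, 1], 4),
            "y": np.tile([1.0, 2.0, 3.0, 4.0], 4),
        }
    )
    fit = fit_random_intercept(IPDDataset(frame, {"y": "continuous"}), "y")
    assert fit.beta_treatment == pytest.approx(0.0, abs=1e-12)


def test_singleton_clusters_degenerate_to_t_test():
    rng = np.random.default_rng(9)
    n = 400
    frame = pd.DataFrame(
        {
            "cluster_id": [f"p{i}" for i in range(n)],
            "arm": np.repeat([0, 1], n // 2),
            "y": rng.standard_normal(n),
        }
    )
    ds = IPDDataset(frame, {"y": "continuous"})
    fit = fit_random_intercept(ds, "y")
    assert fit.boundary and fit.sigma2_cluster == 0.0
    res = lmm_wald_test(fit)
    ref = stats.ttest_ind(frame["y"][frame.arm == 1], frame["y"][frame.arm == 0])
    assert fit.beta_treatment == pytest.approx(
        frame["y"][frame.arm == 1].mean() - frame["y"][frame.arm == 0].mean(), rel=1e-12
    )
    # ML variance (1/n) vs pooled (1/(n-2)) and normal vs t reference: close at n=400
    assert res.statistic_unadjusted == pytest.approx(ref.statistic, rel=5e-3)
    assert res.p_adjusted == pytest.approx(ref.pvalue, rel=2e-2, abs=1e-3)


def test_vanishing_clustering_agrees_with_pooled_t():
    # sigma2_u = 0 truth: beta equals the raw mean difference exactly
    # (balanced clusters), icc_hat is near zero, and p agrees with the
    # pooled t-test up to sampling noise in the estimated variance ratio
    ds = make_clustered_ipd(seed=10, n_clusters=40, cluster_size=25, icc=0.0)
    fit = fit_random_intercept(ds, "y")
    assert fit.icc_hat < 0.02
    res = lmm_wald_test(fit)
    y, arm = ds.data["y"], ds.data["arm"]
    ref = stats.ttest_ind(y[arm == 1], y[arm == 0])
    assert fit.beta_treatment == pytest.approx(
        y[arm == 1].mean() - y[arm == 0].mean(), rel=1e-10
    )
    assert res.p_adjusted == pytest.approx(ref.pvalue, abs=0.1)


def test_beta_recovery_small_grid():
    reps, beta = 120, 0.5
    estimates = []
    for rep in range(reps):
        ds = make_clustered_ipd(seed=1000 + rep, n_clusters=30, cluster_size=20,
                                beta=beta, icc=0.1)
        estimates.append(fit_random_intercept(ds, "y").beta_treatment)
    est = np.asarray(estimates)
    mc_se = est.std(ddof=1) / math.sqrt(reps)
    assert abs(est.mean() - beta) < 3.0 * mc_se


def test_wald_antisymmetry_under_arm_swap():
    ds = make_clustered_ipd(seed=12, beta=0.4, icc=0.05)
    fit = fit_random_intercept(ds, "y")
    swapped = IPDDataset(
        ds.data.assign(arm=1 - ds.data["arm"]), dict(ds.covariate_kinds)
    )
    fit_sw = fit_random_intercept(swapped, "y")
    assert fit_sw.beta_treatment == pytest.approx(-fit.beta_treatment, rel=1e-9)
    assert lmm_wald_test(fit_sw).p_adjusted == pytest.approx(
        lmm_wald_test(fit).p_adjusted, rel=1e-9
    )


def test_unconverged_fit_refused_by_wald():
    ds = make_clustered_ipd(seed=13)
    fit = fit_random_intercept(ds, "y")
    fit.converged = False
    with pytest.raises(ConvergenceError, match="diagnostics"):
        lmm_wald_test(fit)


# ---------------------------------------------------------------------------
# ANOVA ICC
# ---------------------------------------------------------------------------


def test_icc_truncated_at_zero_for_iid_data():
    ds = make_clustered_ipd(seed=14, n_clusters=50, cluster_size=10, icc=0.0)
    assert 0.0 <= estimate_icc_anova(ds, "y") < 0.05


def test_icc_boundary_when_clusters_internally_constant():
    frame = pd.DataFrame(
        {
            "cluster_id": np.repeat(["a", "b", "c", "d"], 3),
            "arm": np.repeat([0, 0, 1, 1], 3),
            "y": np.repeat([1.0, 2.0, 3.0, 4.0], 3),
        }
    )
    ds = IPDDataset(frame, {"y": "continuous"})
    with pytest.warns(UserWarning, match="boundary"):
        est = estimate_icc_anova(ds, "y")
    assert est > 0.999


def test_icc_recovery():
    reps, icc = 150, 0.10
    ests = [
        estimate_icc_anova(
            make_clustered_ipd(seed=2000 + rep, n_clusters=50, cluster_size=20, icc=icc), "y"
        )
        for rep in range(reps)
    ]
    ests = np.asarray(ests)
    mc_se = ests.std(ddof=1) / math.sqrt(reps)
    assert abs(ests.mean() - icc) < 3.0 * mc_se


# ---------------------------------------------------------------------------
# binary covariates
# ---------------------------------------------------------------------------


def _binary_ds(seed: int, n_clusters=20, cluster_size=15, p0=0.4, p1=0.4):
    rng = np.random.default_rng(seed)
    arm_of_cluster = np.repeat([0, 1], n_clusters // 2)
    cl = np.repeat(np.arange(n_clusters), cluster_size)
    p = np.where(arm_of_cluster[cl] == 1, p1, p0)
    frame = pd.DataFrame(
        {
            "cluster_id": [f"c{j}" for j in cl],
            "arm": arm_of_cluster[cl],
            "b": (rng.random(cl.size) < p).astype(int),
        }
    )
    return IPDDataset(frame, {"b": "binary"})


def test_binary_test_reduces_to_chi2_when_icc_zero():
    ds = _binary_ds(seed=15, n_clusters=60, cluster_size=20)
    res = ipd_tests.test_binary_covariate(ds, "b")
    assert res.method == "adjusted_chi_squared_icc"
    # with icc_hat near zero the adjustment is weak
    assert res.design_effect_used < 1.5
    assert res.p_adjusted >= res.p_unadjusted - 1e-15


def test_binary_single_level_flagged():
    ds = _binary_ds(seed=16)
    ds.data["b"] = 0
    res = ipd_tests.test_binary_covariate(ds, "b")
    assert res.degenerate and res.p_adjusted == 1.0


def test_collapse_to_aggregate_matches_ipd():
    ds = make_clustered_ipd(seed=17, beta=0.3, icc=0.05)
    ds.data["b"] = (np.arange(len(ds.data)) % 3 == 0).astype(int)
    ds.covariate_kinds["b"] = "binary"
    table = to_aggregate_table(ds)
    cont = table.continuous_rows[0]
    arm0 = ds.data[ds.data.arm == 0]["y"]
    assert cont.arm1_n == len(arm0)
    assert cont.arm1_mean == pytest.approx(arm0.mean())
    assert cont.arm1_sd == pytest.approx(arm0.std(ddof=1))
    cat = table.categorical_rows[0]
    assert sum(cat.arm1_counts) + sum(cat.arm2_counts) == len(ds.data)
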