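"""Baseline tests from individual participant data (IPD).

The recommended analysis when IPD are available is, per continuous baseline
covariate, a random-intercept linear mixed model

    y_ij = mu + beta * arm_j + u_j + e_ij,
    u_j ~ N(0, sigma2_u),  e_ij ~ N(0, sigma2_e),

with treatment arm as the fixed effect and cluster as the random effect,
tested by a Wald z on beta. The fit is full maximum likelihood via a
one-dimensional profile likelihood over the variance ratio
lambda = sigma2_u / sigma2_e: for fixed lambda the GLS estimates of
(mu, beta) and the profiled sigma2_e are closed-form because both intercept
and arm are constant within cluster, so the whole fit reduces to a bounded
deterministic scalar optimisation (no random initialisation). ML rather than
REML is used, so variance components are slightly smaller than REML-based
package defaults; the Wald reference distribution is standard normal, which
is mildly anti-conservative with few clusters (a warning is attached below
20 clusters).

Binary covariates are not given a logistic GLMM; instead the ICC of the 0/1
values is estimated by the one-way ANOVA estimator, converted to a design
effect with this trial's cluster count and size, and the design-effect-
adjusted chi-squared test is applied (method ``adjusted_chi_squared_icc``).

Missing covariate values are dropped per covariate (complete case per test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .aggregate_io import (
    AggregateBaselineTable,
    CategoricalSummaryRow,
    ClusterDesign,
    ContinuousSummaryRow,
)
from .errors import ConvergenceError, SchemaError, ValidationError
from .summary_tests import (
    BaselineTestResult,
    adjust_categorical,
    compute_design_effect,
)

LAMBDA_UPPER = 1.0e4  # variance-ratio search bound
SMALL_CLUSTER_WARNING = 20


# ---------------------------------------------------------------------------
# Dataset container and CSV dialect
# ---------------------------------------------------------------------------


@dataclass
class IPDDataset:
    """Individual participant data: cluster id, arm (0/1), covariate columns.

    ``covariate_kinds`` maps each covariate column to ``"continuous"`` or
    ``"binary"``. Every cluster must belong to exactly one arm and each arm
    must contain at least two clusters.
    """

    data: pd.DataFrame
    covariate_kinds: dict[str, str]

    def __post_init__(self) -> None:
        for col in ("cluster_id", "arm"):
            if col not in self.data.columns:
                raise ValidationError(f"IPD data must contain a {col!r} column")
        arms = set(self.data["arm"].unique().tolist())
        if not arms <= {0, 1}:
            raise ValidationError(f"arm must be coded 0/1, found {sorted(arms)}")
        if self.data["arm"].isna().any():
            raise ValidationError("missing arm labels are not allowed")
        per_cluster = self.data.groupby("cluster_id", sort=False)["arm"].nunique()
        bad = per_cluster[per_cluster > 1]
        if len(bad):
            raise ValidationError(
                f"cluster(s) {list(bad.index)[:5]} map to more than one arm"
            )
        cluster_arm = self.data.groupby("cluster_id", sort=False)["arm"].first()
        for a in (0, 1):
            if (cluster_arm == a).sum() < 2:
                raise ValidationError(f"arm {a} has fewer than 2 clusters")
        for name, kind in self.covariate_kinds.items():
            if name not in self.data.columns:
                raise ValidationError(f"covariate {name!r} not found in IPD columns")
            if kind not in ("continuous", "binary"):
                raise ValidationError(f"{name}: unknown covariate kind {kind!r}")

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_kinds)

    @property
    def n_clusters(self) -> int:
        return self.data["cluster_id"].nunique()

    def column(self, covariate: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Complete-case (values, cluster codes, arm) arrays for one covariate."""
        if covariate not in self.covariate_kinds:
            raise ValidationError(f"unknown covariate {covariate!r}")
        sub = self.data[["cluster_id", "arm", covariate]].dropna(subset=[covariate])
        y = sub[covariate].to_numpy(dtype=float)
        codes, _ = pd.factorize(sub["cluster_id"], sort=False)
        arm = sub["arm"].to_numpy(dtype=int)
        return y, codes, arm


def infer_covariate_kinds(frame: pd.DataFrame) -> dict[str, str]:
    """Heuristic kinds for IPD columns: 0/1 or two text labels -> binary, numeric -> continuous."""
    kinds: dict[str, str] = {}
    for col in frame.columns:
        if col in ("cluster_id", "arm"):
            continue
        series = frame[col].dropna()
        uniq = series.unique()
        if pd.api.types.is_numeric_dtype(series):
            kinds[col] = "binary" if set(np.unique(uniq)).issubset({0, 1}) else "continuous"
        elif len(uniq) == 2:
            kinds[col] = "binary"
        else:
            raise ValidationError(
                f"{col}: text covariate with {len(uniq)} levels; only binary "
                "(two-level) categorical covariates are supported in IPD tests"
            )
    return kinds


def read_ipd(path: str | Path, covariate_kinds: dict[str, str] | None = None) -> IPDDataset:
    """Read the IPD CSV dialect: cluster_id, arm (0/1), one column per covariate.

    Two-level text covariates are recoded 0/1 by sorted label order.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path)
    for col in ("cluster_id", "arm"):
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing column {col!r}")
    kinds = covariate_kinds or infer_covariate_kinds(frame)
    for col, kind in kinds.items():
        if kind == "binary" and not pd.api.types.is_numeric_dtype(frame[col]):
            labels = sorted(frame[col].dropna().unique())
            frame[col] = frame[col].map({lab: i for i, lab in enumerate(labels)})
    return IPDDataset(data=frame, covariate_kinds=kinds)


def write_ipd(dataset: IPDDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Random-intercept ML fit
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """Maximum-likelihood random-intercept fit for one covariate."""

    covariate: str
    beta_treatment: float
    se_beta: float
    sigma2_cluster: float
    sigma2_residual: float
    icc_hat: float
    loglik: float
    converged: bool
    boundary: bool = False
    n_obs: int = 0
    n_clusters: int = 0
    message: str = ""


def _cluster_stats(y: np.ndarray, codes: np.ndarray, arm: np.ndarray):
    k = codes.max() + 1
    m = np.bincount(codes, minlength=k).astype(float)
    ysum = np.bincount(codes, weights=y, minlength=k)
    ybar = ysum / m
    ssw = float(np.sum((y - ybar[codes]) ** 2))
    arm_of_cluster = np.zeros(k, dtype=int)
    arm_of_cluster[codes] = arm
    return m, ybar, ssw, arm_of_cluster


def _profile_quantities(lam: float, m, ybar, ssw, arm_of_cluster):
    """GLS means, profiled residual SS and weights at a given variance ratio."""
    v = m / (1.0 + lam * m)  # cluster GLS weights
    mu = np.empty(2)
    V = np.empty(2)
    for a in (0, 1):
        sel = arm_of_cluster == a
        V[a] = v[sel].sum()
        mu[a] = float(np.dot(v[sel], ybar[sel])) / V[a]
    resid = ybar - mu[arm_of_cluster]
    q = ssw + float(np.dot(v, resid**2))
    return mu, V, q


def _profile_negloglik(lam: float, m, ybar, ssw, arm_of_cluster, n: int) -> float:
    _, _, q = _profile_quantities(lam, m, ybar, ssw, arm_of_cluster)
    if q <= 0.0:
        return -1.0e300  # degenerate perfect fit; likelihood unbounded
    return 0.5 * (n * math.log(2.0 * math.pi * q / n) + n) + 0.5 * float(
        np.sum(np.log1p(lam * m))
    )


def fit_random_intercept(data: IPDDataset, covariate: str) -> LMMFit:
    """ML fit of the per-covariate random-intercept model (deterministic).

    The profile likelihood over lambda = sigma2_u/sigma2_e is maximised on
    [0, 1e4] by bounded scalar optimisation on a log1p scale; the lambda = 0
    endpoint (the nested OLS fit) is always evaluated and wins ties, so the
    returned log-likelihood is never below the OLS log-likelihood.
    """
    if data.covariate_kinds.get(covariate) != "continuous":
        raise ValidationError(f"{covariate}: fit_random_intercept needs a continuous covariate")
    y, codes, arm = data.column(covariate)
    n = y.size
    k = int(codes.max()) + 1 if n else 0
    for a in (0, 1):
        if len(np.unique(codes[arm == a])) < 2:
            raise ValidationError(f"{covariate}: fewer than 2 clusters with data in arm {a}")
    m, ybar, ssw, arm_of_cluster = _cluster_stats(y, codes, arm)
    # all-singleton clusters are allowed: the profile likelihood is flat in
    # lambda and the lambda = 0 endpoint (the OLS fit) wins the tie below
    if n <= k + 1 and not np.all(m == 1):
        raise ValidationError(f"{covariate}: too few observations ({n}) for {k} clusters")
    args = (m, ybar, ssw, arm_of_cluster)

    def neg_on_log_scale(s: float) -> float:
        return _profile_negloglik(math.expm1(s), *args, n)

    res = optimize.minimize_scalar(
        neg_on_log_scale,
        bounds=(0.0, math.log1p(LAMBDA_UPPER)),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    lam_hat = math.expm1(float(res.x))
    converged = bool(res.success)
    message = str(getattr(res, "message", ""))

    nll_hat = _profile_negloglik(lam_hat, *args, n)
    nll_zero = _profile_negloglik(0.0, *args, n)
    if nll_zero <= nll_hat + 1e-10:  # endpoint wins ties: boundary at sigma2_u = 0
        lam_hat, nll_hat = 0.0, nll_zero

    boundary = lam_hat == 0.0 or lam_hat >= LAMBDA_UPPER * (1.0 - 1e-6)
    mu, V, q = _profile_quantities(lam_hat, *args)
    sigma2_e = q / n
    if sigma2_e <= 0.0 or not math.isfinite(nll_hat):
        return LMMFit(
            covariate=covariate,
            beta_treatment=float(mu[1] - mu[0]),
            se_beta=math.nan,
            sigma2_cluster=math.nan,
            sigma2_residual=0.0,
            icc_hat=math.nan,
            loglik=math.inf,
            converged=False,
            boundary=True,
            n_obs=n,
            n_clusters=k,
            message="residual variance collapsed to zero (covariate constant within clusters)",
        )
    sigma2_u = lam_hat * sigma2_e
    se_beta = math.sqrt(sigma2_e * (1.0 / V[0] + 1.0 / V[1]))
    note = message
    if lam_hat >= LAMBDA_UPPER * (1.0 - 1e-6):
        note = "variance ratio at the upper search bound"
    return LMMFit(
        covariate=covariate,
        beta_treatment=float(mu[1] - mu[0]),
        se_beta=se_beta,
        sigma2_cluster=sigma2_u,
        sigma2_residual=sigma2_e,
        icc_hat=sigma2_u / (sigma2_u + sigma2_e),
        loglik=-nll_hat,
        converged=converged,
        boundary=boundary,
        n_obs=n,
        n_clusters=k,
        message=note,
    )


def lmm_wald_test(fit: LMMFit) -> BaselineTestResult:
    """Wald z-test of the treatment fixed effect from a converged fit.

    The model itself accounts for clustering, so no design-effect adjustment
    is applied (convention ``none``). The reference distribution is standard
    normal; with fewer than 20 clusters a small-sample warning is attached.
    """
    if not fit.converged:
        raise ConvergenceError(
            f"{fit.covariate}: fit did not converge ({fit.message}); "
            "inspect the LMMFit diagnostics before testing"
        )
    z = fit.beta_treatment / fit.se_beta
    p = 2.0 * float(stats.norm.sf(abs(z)))
    notes = f"icc_hat={fit.icc_hat:.4f}"
    if fit.n_clusters < SMALL_CLUSTER_WARNING:
        notes += f"; only {fit.n_clusters} clusters: normal reference may be anti-conservative"
    if fit.boundary:
        notes += "; variance-ratio boundary fit"
    return BaselineTestResult(
        covariate_name=fit.covariate,
        method="lmm_wald",
        statistic_unadjusted=z,
        statistic_adjusted=z,
        df=math.inf,
        p_unadjusted=min(p, 1.0),
        p_adjusted=min(p, 1.0),
        adjustment_convention="none",
        notes=notes,
    )


# ---------------------------------------------------------------------------
# ANOVA ICC and binary covariates
# ---------------------------------------------------------------------------


def estimate_icc_anova(data: IPDDataset, covariate: str) -> float:
    """One-way ANOVA ICC estimator, truncated at 0 from below.

    icc = (MSB - MSW) / (MSB + (m0 - 1) * MSW) with
    m0 = (N - sum m_j^2 / N) / (k - 1), the standard unbalanced-design
    average cluster size. Works on any numeric covariate (0/1 included).
    """
    y, codes, _ = data.column(covariate)
    n = y.size
    k = int(codes.max()) + 1 if n else 0
    if k < 2:
        raise ValidationError(f"{covariate}: ICC estimation needs at least 2 clusters")
    m = np.bincount(codes, minlength=k).astype(float)
    ybar = np.bincount(codes, weights=y, minlength=k) / m
    grand = y.mean()
    msb = float(np.dot(m, (ybar - grand) ** 2)) / (k - 1)
    ssw = float(np.sum((y - ybar[codes]) ** 2))
    if n == k:
        raise ValidationError(f"{covariate}: one observation per cluster, ICC unidentifiable")
    msw = ssw / (n - k)
    m0 = (n - float(np.dot(m, m)) / n) / (k - 1)
    if msw == 0.0:
        warnings.warn(
            f"{covariate}: zero within-cluster variance; ICC at the upper boundary",
            stacklevel=2,
        )
        return 1.0 - 1e-12
    est = (msb - msw) / (msb + (m0 - 1.0) * msw)
    return max(0.0, float(est))


def test_binary_covariate(data: IPDDataset, covariate: str) -> BaselineTestResult:
    """ICC-adjusted chi-squared test for a binary covariate from IPD.

    The ICC of the 0/1 values is estimated by ANOVA, converted to a design
    effect with this trial's cluster count and total n, and the cell-division
    adjusted chi-squared applied.
    """
    if data.covariate_kinds.get(covariate) != "binary":
        raise ValidationError(f"{covariate}: test_binary_covariate needs a binary covariate")
    y, codes, arm = data.column(covariate)
    values = set(np.unique(y))
    if not values.issubset({0.0, 1.0}):
        raise ValidationError(f"{covariate}: binary covariate must be coded 0/1")
    if len(values) < 2:
        return BaselineTestResult(
            covariate_name=covariate,
            method="adjusted_chi_squared_icc",
            statistic_unadjusted=math.nan,
            statistic_adjusted=math.nan,
            df=math.nan,
            p_unadjusted=1.0,
            p_adjusted=1.0,
            degenerate=True,
            notes="only one observed level",
        )
    counts = np.zeros((2, 2), dtype=int)
    for a in (0, 1):
        counts[a, 0] = int(np.sum((arm == a) & (y == 0.0)))
        counts[a, 1] = int(np.sum((arm == a) & (y == 1.0)))
    icc = estimate_icc_anova(data, covariate)
    k = int(codes.max()) + 1
    deff = compute_design_effect(icc, k, y.size)
    row = CategoricalSummaryRow(
        covariate_name=covariate,
        levels=["0", "1"],
        arm1_counts=counts[0].tolist(),
        arm2_counts=counts[1].tolist(),
    )
    res = adjust_categorical(row, deff)
    res.method = "adjusted_chi_squared_icc"
    res.notes = f"icc_hat={icc:.4f} (ANOVA on 0/1 values)"
    return res


# ---------------------------------------------------------------------------
# Drivers and collapse to aggregate form
# ---------------------------------------------------------------------------


def run_ipd(data: IPDDataset) -> list[BaselineTestResult]:
    """Test every covariate in an IPD dataset: LMM Wald for continuous, ICC-adjusted chi-squared for binary."""
    results: list[BaselineTestResult] = []
    for name, kind in data.covariate_kinds.items():
        try:
            if kind == "continuous":
                results.append(lmm_wald_test(fit_random_intercept(data, name)))
            else:
                results.append(test_binary_covariate(data, name))
        except (ValidationError, ConvergenceError) as exc:
            results.append(
                BaselineTestResult(
                    covariate_name=name,
                    method="lmm_wald" if kind == "continuous" else "adjusted_chi_squared_icc",
                    statistic_unadjusted=math.nan,
                    statistic_adjusted=math.nan,
                    df=math.nan,
                    p_unadjusted=1.0,
                    p_adjusted=1.0,
                    degenerate=True,
                    notes=f"untestable: {exc}",
                )
            )
    return results


def to_aggregate_table(
    data: IPDDataset, design: ClusterDesign | None = None
) -> AggregateBaselineTable:
    """Collapse IPD to the aggregate per-arm summary form (n/mean/SD or counts)."""
    continuous: list[ContinuousSummaryRow] = []
    categorical: list[CategoricalSummaryRow] = []
    order: list[str] = []
    for name, kind in data.covariate_kinds.items():
        y, _, arm = data.column(name)
        y1, y2 = y[arm == 0], y[arm == 1]
        if kind == "continuous":
            continuous.append(
                ContinuousSummaryRow(
                    covariate_name=name,
                    arm1_n=int(y1.size),
                    arm1_mean=float(y1.mean()),
                    arm1_sd=float(y1.std(ddof=1)),
                    arm2_n=int(y2.size),
                    arm2_mean=float(y2.mean()),
                    arm2_sd=float(y2.std(ddof=1)),
                    allow_degenerate=True,
                )
            )
        else:
            categorical.append(
                CategoricalSummaryRow(
                    covariate_name=name,
                    levels=["0", "1"],
                    arm1_counts=[int(np.sum(y1 == 0.0)), int(np.sum(y1 == 1.0))],
                    arm2_counts=[int(np.sum(y2 == 0.0)), int(np.sum(y2 == 1.0))],
                )
            )
        order.append(name)
    return AggregateBaselineTable(
        continuous_rows=continuous,
        categorical_rows=categorical,
        design=design,
        covariate_order=order,
    )
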