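"""Synthetic two-arm cluster RCTs with selective post-randomisation recruitment.

The generator emulates the situation the detector targets: intact clusters
(schools, clinics) are randomised first, and individuals are recruited
afterwards, when the recruiting staff already know each cluster's arm. Each
eligible individual carries clustered covariates (cluster-random-intercept
normals; binary covariates via a latent-Gaussian threshold so "ICC" means
the same thing for both kinds) and is recruited with probability

    expit(gamma0_arm + gamma1_arm . x_std),

where x_std are the standardised covariate values. Identical recruitment
parameters in both arms is the null mechanism (recruitment may still depend
on covariates, but identically, so baseline balance is preserved);
arm-differential intercepts or slopes produce exactly the recruitment-bias
pattern the baseline tests are meant to expose — e.g. 50% of eligible
individuals recruited in control clusters versus 58% under intervention.

Cluster sizes are dispersed (negative-binomial-style, floored at 2) so the
design-effect formula's single mean cluster size is an approximation, as in
real trials. Everything is a pure function of the configuration, including
its seed; replicate r of a calibration run gets an independently
reproducible substream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .aggregate_io import ClusterDesign
from .bias_summary import BiasSummary, summarise
from .errors import ValidationError
from .ipd_tests import IPDDataset, estimate_icc_anova, run_ipd, to_aggregate_table
from .summary_tests import run_aggregate_table

_ETA_CAP = 36.5  # expit leaves (0, 1) in float64 near |eta| ~ 36.7
_CALIBRATION_DRAWS = 200_000
_CALIBRATION_SEED = 987_654_321  # internal stream for intercept calibration only


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution and clustering of one simulated covariate.

    Continuous covariates have marginal mean/sd and intraclass correlation
    ``icc``; binary covariates have marginal ``prevalence`` and a latent
    Gaussian with the same ``icc`` (the latent ICC, which exceeds the ICC of
    the observed 0/1 values).
    """

    name: str
    kind: Literal["continuous", "binary"]
    icc: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"{self.name}: unknown covariate kind {self.kind!r}")
        if not (0.0 <= self.icc < 1.0):
            raise ValidationError(f"{self.name}: icc must lie in [0, 1), got {self.icc}")
        if self.sd <= 0:
            raise ValidationError(f"{self.name}: sd must be positive")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError(f"{self.name}: prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated trial, seed included.

    ``n_clusters_per_arm`` may be a single integer (equal arms) or an
    ``(arm0, arm1)`` pair, e.g. ``(28, 29)`` for a 57-cluster trial.
    ``recruitment_intercepts`` and ``recruitment_slopes`` are per-arm
    (control first); slopes act on standardised covariate values.
    """

    n_clusters_per_arm: int | tuple[int, int]
    cluster_size_mean: float
    cluster_size_dispersion: float
    covariates: tuple[CovariateSpec, ...]
    recruitment_intercepts: tuple[float, float]
    recruitment_slopes: tuple[tuple[float, ...], tuple[float, ...]]
    seed: int

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValidationError("at least one covariate is required")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        k0, k1 = self.arm_cluster_counts
        if k0 < 2 or k1 < 2:
            raise ValidationError("each arm needs at least 2 clusters")
        if self.cluster_size_mean < 2:
            raise ValidationError("cluster_size_mean must be >= 2")
        if self.cluster_size_dispersion < 0:
            raise ValidationError("cluster_size_dispersion must be >= 0")
        slopes = tuple(tuple(float(s) for s in arm) for arm in self.recruitment_slopes)
        object.__setattr__(self, "recruitment_slopes", slopes)
        for arm_slopes in slopes:
            if len(arm_slopes) != len(self.covariates):
                raise ValidationError(
                    f"recruitment slopes must have one entry per covariate "
                    f"({len(self.covariates)}), got {len(arm_slopes)}"
                )
        for g0, g1 in zip(self.recruitment_intercepts, slopes):
            eta_max = abs(g0) + 4.0 * sum(abs(s) for s in g1)
            if eta_max > _ETA_CAP:
                raise ValidationError(
                    "recruitment parameters saturate the logistic within +/-4 SD "
                    f"(|eta| up to {eta_max:.1f} > {_ETA_CAP})"
                )

    @property
    def arm_cluster_counts(self) -> tuple[int, int]:
        if isinstance(self.n_clusters_per_arm, int):
            return (self.n_clusters_per_arm, self.n_clusters_per_arm)
        k0, k1 = self.n_clusters_per_arm
        return (int(k0), int(k1))

    @property
    def n_clusters_total(self) -> int:
        return sum(self.arm_cluster_counts)

    @property
    def is_null(self) -> bool:
        return (
            self.recruitment_intercepts[0] == self.recruitment_intercepts[1]
            and self.recruitment_slopes[0] == self.recruitment_slopes[1]
        )

    def to_json(self) -> str:
        obj = {
            "n_clusters_per_arm": list(self.arm_cluster_counts),
            "cluster_size_mean": self.cluster_size_mean,
            "cluster_size_dispersion": self.cluster_size_dispersion,
            "covariates": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "icc": c.icc,
                    "mean": c.mean,
                    "sd": c.sd,
                    "prevalence": c.prevalence,
                }
                for c in self.covariates
            ],
            "recruitment_intercepts": list(self.recruitment_intercepts),
            "recruitment_slopes": [list(s) for s in self.recruitment_slopes],
            "seed": self.seed,
        }
        return json.dumps(obj, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        obj = json.loads(text)
        ncpa = obj["n_clusters_per_arm"]
        return cls(
            n_clusters_per_arm=tuple(ncpa) if isinstance(ncpa, list) else int(ncpa),
            cluster_size_mean=float(obj["cluster_size_mean"]),
            cluster_size_dispersion=float(obj["cluster_size_dispersion"]),
            covariates=tuple(CovariateSpec(**c) for c in obj["covariates"]),
            recruitment_intercepts=tuple(obj["recruitment_intercepts"]),
            recruitment_slopes=tuple(tuple(s) for s in obj["recruitment_slopes"]),
            seed=int(obj["seed"]),
        )

    @classmethod
    def read(cls, path: str | Path) -> "SimConfig":
        return cls.from_json(Path(path).read_text())


@dataclass
class SimulatedTrial:
    """One realised trial: recruited IPD, the eligible superset, and the truth."""

    ipd: IPDDataset
    eligible_ipd: IPDDataset
    recruitment_fraction_by_arm: tuple[float, float]
    truth: SimConfig
    is_null: bool


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------


def _draw_cluster_sizes(rng: np.random.Generator, k: int, mean: float, disp: float) -> np.ndarray:
    if disp > 0:
        r = 1.0 / disp
        p = r / (r + mean)
        sizes = rng.negative_binomial(r, p, size=k)
    else:
        sizes = rng.poisson(mean, size=k)
    return np.maximum(sizes, 2)


def simulate_trial(config: SimConfig, max_retries: int = 10) -> SimulatedTrial:
    """Generate one trial; a pure function of ``config`` (seed included).

    Cluster labels are randomised to arms by simple randomisation (a random
    permutation with the configured arm sizes). If selective recruitment
    empties an arm — fewer than two recruited clusters or two participants —
    the whole draw is retried a bounded number of times.
    """
    rng = np.random.default_rng(config.seed)
    k0, k1 = config.arm_cluster_counts
    k = k0 + k1
    specs = config.covariates
    g0 = np.asarray(config.recruitment_intercepts, dtype=float)
    g1 = np.asarray(config.recruitment_slopes, dtype=float)  # (2, C)

    for _attempt in range(max_retries):
        sizes = _draw_cluster_sizes(rng, k, config.cluster_size_mean, config.cluster_size_dispersion)
        arm_of_cluster = np.zeros(k, dtype=int)
        arm_of_cluster[rng.permutation(k)[:k1]] = 1
        cluster_of_ind = np.repeat(np.arange(k), sizes)
        n_elig = cluster_of_ind.size
        arm_ind = arm_of_cluster[cluster_of_ind]

        observed = np.empty((n_elig, len(specs)))
        standardised = np.empty((n_elig, len(specs)))
        for c, spec in enumerate(specs):
            b = rng.standard_normal(k)
            e = rng.standard_normal(n_elig)
            x = math.sqrt(spec.icc) * b[cluster_of_ind] + math.sqrt(1.0 - spec.icc) * e
            if spec.kind == "continuous":
                observed[:, c] = spec.mean + spec.sd * x
                standardised[:, c] = x
            else:
                z = float(stats.norm.ppf(1.0 - spec.prevalence))
                obs = (x > z).astype(float)
                observed[:, c] = obs
                standardised[:, c] = (obs - spec.prevalence) / math.sqrt(
                    spec.prevalence * (1.0 - spec.prevalence)
                )

        eta = g0[arm_ind] + np.einsum("ic,ic->i", standardised, g1[arm_ind])
        recruited = rng.random(n_elig) < expit(eta)

        frac = tuple(
            float(recruited[arm_ind == a].mean()) if (arm_ind == a).any() else 0.0
            for a in (0, 1)
        )

        ok = True
        for a in (0, 1):
            sel = recruited & (arm_ind == a)
            if sel.sum() < 2 or len(np.unique(cluster_of_ind[sel])) < 2:
                ok = False
        if not ok:
            continue

        cluster_ids = np.array([f"c{j:03d}" for j in range(k)])
        frame = pd.DataFrame({"cluster_id": cluster_ids[cluster_of_ind], "arm": arm_ind})
        kinds: dict[str, str] = {}
        for c, spec in enumerate(specs):
            col = observed[:, c]
            frame[spec.name] = col.astype(int) if spec.kind == "binary" else col
            kinds[spec.name] = spec.kind
        eligible = IPDDataset(data=frame, covariate_kinds=kinds)
        ipd = IPDDataset(
            data=frame.loc[recruited].reset_index(drop=True), covariate_kinds=dict(kinds)
        )
        return SimulatedTrial(
            ipd=ipd,
            eligible_ipd=eligible,
            recruitment_fraction_by_arm=frac,
            truth=config,
            is_null=config.is_null,
        )
    raise ValidationError(
        f"recruitment emptied an arm in {max_retries} consecutive draws; "
        "the configuration is too extreme"
    )


def empirical_icc_check(trial: SimulatedTrial, covariate: str) -> float:
    """ANOVA ICC of a continuous covariate on the eligible (pre-recruitment) data."""
    kind = trial.eligible_ipd.covariate_kinds.get(covariate)
    if kind != "continuous":
        raise ValidationError(f"{covariate}: empirical ICC check needs a continuous covariate")
    return estimate_icc_anova(trial.eligible_ipd, covariate)


def calibrate_recruitment_intercept(
    target_fraction: float,
    slopes: Sequence[float],
    covariates: Sequence[CovariateSpec],
) -> float:
    """Solve for the logistic intercept giving a target marginal recruitment fraction.

    The marginal mean of expit(g0 + slopes . x_std) is evaluated by a large
    fixed Monte-Carlo draw of standardised covariate values (the clustering
    structure does not change their marginals), and g0 is found by bisection.
    Deterministic: the internal draw uses a fixed private seed.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValidationError("target recruitment fraction must lie in (0, 1)")
    rng = np.random.default_rng(_CALIBRATION_SEED)
    xs = np.empty((_CALIBRATION_DRAWS, len(covariates)))
    for c, spec in enumerate(covariates):
        z = rng.standard_normal(_CALIBRATION_DRAWS)
        if spec.kind == "continuous":
            xs[:, c] = z
        else:
            obs = (z > stats.norm.ppf(1.0 - spec.prevalence)).astype(float)
            xs[:, c] = (obs - spec.prevalence) / math.sqrt(
                spec.prevalence * (1.0 - spec.prevalence)
            )
    lin = xs @ np.asarray(slopes, dtype=float)

    def gap(g0: float) -> float:
        return float(expit(g0 + lin).mean()) - target_fraction

    return float(optimize.brentq(gap, -20.0, 20.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# Operating characteristics
# ---------------------------------------------------------------------------

Pipeline = Literal["aggregate_paper_rule", "aggregate_ess_rule", "ipd_lmm"]


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo rejection and verdict rates for one configuration and pipeline."""

    pipeline: str
    n_reps: int
    n_failed: int
    alpha: float
    rejection_rate_by_covariate: dict[str, float]
    overall_rejection_rate: float
    overall_rejection_se: float
    verdict_rates: dict[str, float]
    verdict_se: dict[str, float]
    mean_recruitment_fraction_by_arm: tuple[float, float]
    seed: int

    def to_json(self) -> str:
        obj = asdict_oc(self)
        return json.dumps(obj, indent=2)


def asdict_oc(oc: OperatingCharacteristics) -> dict:
    from dataclasses import asdict

    obj = asdict(oc)
    obj["mean_recruitment_fraction_by_arm"] = list(oc.mean_recruitment_fraction_by_arm)
    return obj


def replicate_seed(base_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2**31, reproducible in isolation."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline_on_trial(
    trial: SimulatedTrial,
    pipeline: Pipeline,
    design_icc: float | None = None,
    alpha: float = 0.05,
    high_threshold: float = 1e-4,
):
    """Run one detection pipeline on a recruited trial; returns (results, summary).

    Aggregate pipelines collapse the recruited IPD to per-arm summaries and
    form the design effect from the assumed ICC (``design_icc``, defaulting
    to the mean of the configured covariate ICCs — the "ICC assumed at
    design time") together with the realised cluster count and recruited n.
    """
    config = trial.truth
    if pipeline == "ipd_lmm":
        results = run_ipd(trial.ipd)
    elif pipeline in ("aggregate_paper_rule", "aggregate_ess_rule"):
        if design_icc is None:
            design_icc = float(np.mean([c.icc for c in config.covariates]))
        # clusters *randomised* (not just those with recruits) and consenting n
        design = ClusterDesign(
            icc=design_icc,
            n_clusters=config.n_clusters_total,
            n_total=len(trial.ipd.data),
        )
        convention = (
            "statistic_division" if pipeline == "aggregate_paper_rule" else "effective_sample_size"
        )
        table = to_aggregate_table(trial.ipd, design=design)
        results = run_aggregate_table(table, convention=convention)
    else:
        raise ValidationError(f"unknown pipeline {pipeline!r}")
    summary = summarise(results, alpha=alpha, high_threshold=high_threshold)
    return results, summary


def calibrate_detector(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    pipeline: Pipeline = "aggregate_ess_rule",
    design_icc: float | None = None,
    high_threshold: float = 1e-4,
    min_reps: int = 100,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics of a detection pipeline.

    Simulates ``n_reps`` independent trials from ``config`` (replicate r uses
    a substream derived from ``config.seed`` and r), runs the chosen pipeline
    on each recruited dataset, and returns per-covariate rejection rates at
    ``alpha``, verdict rates, and their Monte-Carlo standard errors.
    Per-replicate failures are counted and tolerated up to 5%.
    """
    if n_reps < min_reps:
        raise ValidationError(f"n_reps must be >= {min_reps}")
    names = [c.name for c in config.covariates]
    reject_counts = dict.fromkeys(names, 0)
    usable_counts = dict.fromkeys(names, 0)
    verdict_counts: dict[str, int] = {}
    frac_sum = np.zeros(2)
    n_failed = 0
    completed = 0

    for rep in range(n_reps):
        try:
            cfg_r = replace(config, seed=replicate_seed(config.seed, rep))
            trial = simulate_trial(cfg_r)
            results, summary = run_pipeline_on_trial(
                trial, pipeline, design_icc=design_icc, alpha=alpha, high_threshold=high_threshold
            )
        except Exception:
            n_failed += 1
            if n_failed > max(1, int(0.05 * n_reps)):
                raise
            continue
        completed += 1
        frac_sum += np.asarray(trial.recruitment_fraction_by_arm)
        for r in results:
            if not r.degenerate:
                usable_counts[r.covariate_name] += 1
                if r.p_adjusted < alpha:
                    reject_counts[r.covariate_name] += 1
        verdict_counts[summary.verdict] = verdict_counts.get(summary.verdict, 0) + 1

    if completed == 0:
        raise ValidationError("no replicate completed")
    rej_rates = {
        name: (reject_counts[name] / usable_counts[name] if usable_counts[name] else math.nan)
        for name in names
    }
    total_usable = sum(usable_counts.values())
    total_reject = sum(reject_counts.values())
    overall = total_reject / total_usable if total_usable else math.nan
    overall_se = (
        math.sqrt(overall * (1.0 - overall) / total_usable) if total_usable else math.nan
    )
    verdict_rates = {v: c / completed for v, c in sorted(verdict_counts.items())}
    verdict_se = {
        v: math.sqrt(r * (1.0 - r) / completed) for v, r in verdict_rates.items()
    }
    return OperatingCharacteristics(
        pipeline=pipeline,
        n_reps=completed,
        n_failed=n_failed,
        alpha=alpha,
        rejection_rate_by_covariate=rej_rates,
        overall_rejection_rate=overall,
        overall_rejection_se=overall_se,
        verdict_rates=verdict_rates,
        verdict_se=verdict_se,
        mean_recruitment_fraction_by_arm=tuple(frac_sum / completed),
        seed=config.seed,
    )
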