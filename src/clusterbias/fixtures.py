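"""Canonical worked examples: a biased cluster trial and a clean individual trial.

Both fixtures are synthetic. They emulate the two archetypal patterns a
reader of published baseline tables encounters — they are generated from
declarative specs and shipped seeds, and regenerate byte-identically; they
are not any real trial's data.

``biased_cluster_trial``
    A two-arm cluster trial with 57 clusters (28 control, 29 intervention)
    and 10 clustered covariates, in which recruitment happens after
    randomisation with arm-differential, covariate-dependent uptake
    (marginal recruitment calibrated to ~50% in control clusters versus
    ~58% under intervention). Run through the aggregate pipeline with the
    design-time ICC, several covariates land at vanishingly small p-values
    and the verdict is ``strong_evidence_of_bias`` for the shipped seed.

``clean_individual_trial``
    An individually randomised trial: 504 participants in 12 strata,
    block randomisation (block size 6) within stratum, ~20 independent
    baseline covariates, no selection mechanism. The unadjusted pipeline
    yields the familiar benign pattern (about one marginally significant
    test in twenty) and the verdict ``consistent_with_null`` for the
    shipped seed. Each participant is their own singleton "cluster" in the
    IPD export, which is exactly the structure of an individually
    randomised trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate_io import (
    AggregateBaselineTable,
    ClusterDesign,
    write_aggregate_table,
    write_design,
)
from .bias_summary import BiasSummary, summarise
from .errors import ValidationError
from .ipd_tests import IPDDataset, to_aggregate_table, write_ipd
from .simulator import (
    CovariateSpec,
    SimConfig,
    calibrate_recruitment_intercept,
    simulate_trial,
)
from .summary_tests import BaselineTestResult, run_aggregate_table

FIXTURE_NAMES = ("biased_cluster_trial", "clean_individual_trial")

BIASED_SEED = 1105
CLEAN_SEED = 2203

_BIASED_DESIGN_ICC = 0.10  # ICC assumed at design time for the emulated school trial

# Arm-differential recruitment slopes (standardised-covariate scale): five
# covariates with strong differential uptake, one mild, four neutral —
# recreating the published pattern of several highly significant imbalances.
_BIASED_SLOPES_CONTROL = (0.8, 0.8, 0.8, 0.8, 0.8, 0.3, 0.0, 0.0, 0.0, 0.0)
_BIASED_SLOPES_INTERVENTION = (-0.8, -0.8, -0.8, -0.8, -0.8, -0.3, 0.0, 0.0, 0.0, 0.0)

_CLEAN_N_STRATA = 12
_CLEAN_BLOCKS_PER_STRATUM = 7  # 7 blocks of 6 -> 42 per stratum, 504 total
_CLEAN_BLOCK = 6
_CLEAN_BINARY_PREVALENCES = (0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55)
_CLEAN_N_CONTINUOUS = 12


@dataclass
class FixtureBundle:
    """A generated fixture with everything downstream modules need."""

    name: str
    seed: int
    table: AggregateBaselineTable
    ipd: IPDDataset
    design: ClusterDesign | None
    results: list[BaselineTestResult]
    summary: BiasSummary


def null_cluster_trial_config(seed: int) -> SimConfig:
    """A 57-cluster null trial (no selective recruitment) for calibration runs.

    Same trial dimensions as the biased fixture — 10 covariates with ICC 0.05
    (a typical school/primary-care value), 57 clusters of mean size 20 with
    dispersed sizes — but identical covariate-independent recruitment (~54%,
    between the emulated 50%/58% arms) in both arms, so every baseline null
    is true and the detector's type-I behaviour can be measured.
    """
    covariates = tuple(
        [CovariateSpec(name=f"score{i}", kind="continuous", icc=0.05) for i in range(1, 6)]
        + [
            CovariateSpec(name=f"flag{i}", kind="binary", icc=0.05, prevalence=p)
            for i, p in enumerate((0.3, 0.35, 0.4, 0.45, 0.5), start=1)
        ]
    )
    g0 = calibrate_recruitment_intercept(0.54, (0.0,) * 10, covariates)
    return SimConfig(
        n_clusters_per_arm=(28, 29),
        cluster_size_mean=20.0,
        cluster_size_dispersion=0.15,
        covariates=covariates,
        recruitment_intercepts=(g0, g0),
        recruitment_slopes=((0.0,) * 10, (0.0,) * 10),
        seed=seed,
    )


def biased_trial_config(seed: int = BIASED_SEED, slope_scale: float = 1.0) -> SimConfig:
    """The declarative spec of the biased cluster-trial fixture.

    ``slope_scale`` multiplies the arm-differential recruitment slopes
    (intercepts are recalibrated so the marginal 50%/58% recruitment
    fractions are preserved); power studies scale it up or down.
    """
    slopes_control = tuple(s * slope_scale for s in _BIASED_SLOPES_CONTROL)
    slopes_interv = tuple(s * slope_scale for s in _BIASED_SLOPES_INTERVENTION)
    covariates = tuple(
        [
            CovariateSpec(name=f"score{i}", kind="continuous", icc=_BIASED_DESIGN_ICC)
            for i in range(1, 6)
        ]
        + [
            CovariateSpec(
                name=f"flag{i}", kind="binary", icc=_BIASED_DESIGN_ICC, prevalence=p
            )
            for i, p in enumerate((0.3, 0.35, 0.4, 0.45, 0.5), start=1)
        ]
    )
    g0_control = calibrate_recruitment_intercept(0.50, slopes_control, covariates)
    g0_interv = calibrate_recruitment_intercept(0.58, slopes_interv, covariates)
    return SimConfig(
        n_clusters_per_arm=(28, 29),
        cluster_size_mean=20.0,
        cluster_size_dispersion=0.15,
        covariates=covariates,
        recruitment_intercepts=(g0_control, g0_interv),
        recruitment_slopes=(slopes_control, slopes_interv),
        seed=seed,
    )


def _make_biased(seed: int) -> FixtureBundle:
    config = biased_trial_config(seed)
    trial = simulate_trial(config)
    design = ClusterDesign(
        icc=_BIASED_DESIGN_ICC,
        n_clusters=config.n_clusters_total,
        n_total=len(trial.ipd.data),
    )
    table = to_aggregate_table(trial.ipd, design=design)
    results = run_aggregate_table(table, convention="statistic_division")
    return FixtureBundle(
        name="biased_cluster_trial",
        seed=seed,
        table=table,
        ipd=trial.ipd,
        design=design,
        results=results,
        summary=summarise(results),
    )


def _make_clean(seed: int) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    n_per_stratum = _CLEAN_BLOCKS_PER_STRATUM * _CLEAN_BLOCK
    arms = []
    strata = []
    for s in range(_CLEAN_N_STRATA):
        for _b in range(_CLEAN_BLOCKS_PER_STRATUM):
            block = np.array([0, 0, 0, 1, 1, 1])
            arms.append(rng.permutation(block))
            strata.extend([s] * _CLEAN_BLOCK)
    arm = np.concatenate(arms)
    n = arm.size  # 504

    frame = pd.DataFrame(
        {
            "cluster_id": [f"p{i:03d}" for i in range(n)],  # singleton clusters
            "arm": arm,
            "stratum": strata,
        }
    )
    kinds: dict[str, str] = {}
    for i in range(1, _CLEAN_N_CONTINUOUS + 1):
        name = f"c{i:02d}"
        frame[name] = rng.standard_normal(n)
        kinds[name] = "continuous"
    for i, prev in enumerate(_CLEAN_BINARY_PREVALENCES, start=1):
        name = f"b{i:02d}"
        frame[name] = (rng.random(n) < prev).astype(int)
        kinds[name] = "binary"
    ipd = IPDDataset(data=frame, covariate_kinds=kinds)
    table = to_aggregate_table(ipd, design=None)
    results = run_aggregate_table(table)
    return FixtureBundle(
        name="clean_individual_trial",
        seed=seed,
        table=table,
        ipd=ipd,
        design=None,
        results=results,
        summary=summarise(results),
    )


def make_fixture(name: str, seed: int | None = None) -> FixtureBundle:
    """Generate a canonical fixture deterministically from (name, seed)."""
    if name == "biased_cluster_trial":
        return _make_biased(BIASED_SEED if seed is None else seed)
    if name == "clean_individual_trial":
        return _make_clean(CLEAN_SEED if seed is None else seed)
    raise ValidationError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> list[Path]:
    """Materialise a fixture as aggregate CSV + IPD CSV (+ design JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    agg = outdir / f"{bundle.name}_aggregate.csv"
    write_aggregate_table(bundle.table, agg)
    written.append(agg)
    ipd = outdir / f"{bundle.name}_ipd.csv"
    write_ipd(bundle.ipd, ipd)
    written.append(ipd)
    if bundle.design is not None:
        dj = outdir / f"{bundle.name}_design.json"
        write_design(bundle.design, dj)
        written.append(dj)
    return written
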