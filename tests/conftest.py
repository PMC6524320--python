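"""Shared fixtures: small deterministic datasets built in memory."""

import numpy as np
import pandas as pd
import pytest

from clusterbias import (
    AggregateBaselineTable,
    CategoricalSummaryRow,
    ContinuousSummaryRow,
    IPDDataset,
)
from clusterbias.simulator import CovariateSpec, SimConfig


def make_clustered_ipd(
    seed: int,
    n_clusters: int = 20,
    cluster_size: int = 15,
    beta: float = 0.0,
    icc: float = 0.05,
    covariate: str = "y",
) -> IPDDataset:
    """Balanced two-arm clustered data with known treatment effect and ICC."""
    rng = np.random.default_rng(seed)
    sigma2_u = icc / (1.0 - icc)  # residual variance fixed at 1
    u = rng.normal(0.0, np.sqrt(sigma2_u), n_clusters)
    arm_of_cluster = np.repeat([0, 1], n_clusters // 2)
    cl = np.repeat(np.arange(n_clusters), cluster_size)
    y = beta * arm_of_cluster[cl] + u[cl] + rng.standard_normal(cl.size)
    frame = pd.DataFrame(
        {"cluster_id": [f"c{j:02d}" for j in cl], "arm": arm_of_cluster[cl], covariate: y}
    )
    return IPDDataset(data=frame, covariate_kinds={covariate: "continuous"})


@pytest.fixture
def small_table() -> AggregateBaselineTable:
    rng = np.random.default_rng(42)
    continuous = [
        ContinuousSummaryRow(
            covariate_name=f"cont{i}",
            arm1_n=50,
            arm1_mean=float(rng.normal()),
            arm1_sd=float(rng.uniform(0.5, 2.0)),
            arm2_n=55,
            arm2_mean=float(rng.normal()),
            arm2_sd=float(rng.uniform(0.5, 2.0)),
        )
        for i in range(5)
    ]
    categorical = [
        CategoricalSummaryRow(
            covariate_name=f"cat{i}",
            levels=["low", "mid", "high"][: 2 + i % 2],
            arm1_counts=[int(c) for c in rng.integers(5, 40, size=2 + i % 2)],
            arm2_counts=[int(c) for c in rng.integers(5, 40, size=2 + i % 2)],
        )
        for i in range(5)
    ]
    return AggregateBaselineTable(continuous_rows=continuous, categorical_rows=categorical)


@pytest.fixture
def null_sim_config() -> SimConfig:
    covs = tuple(
        [CovariateSpec(f"x{i}", "continuous", icc=0.05) for i in range(3)]
        + [CovariateSpec(f"b{i}", "binary", icc=0.05, prevalence=0.4) for i in range(2)]
    )
    return SimConfig(
        n_clusters_per_arm=(28, 29),
        cluster_size_mean=20.0,
        cluster_size_dispersion=0.15,
        covariates=covs,
        recruitment_intercepts=(0.16, 0.16),
        recruitment_slopes=((0.0,) * 5, (0.0,) * 5),
        seed=314,
    )
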