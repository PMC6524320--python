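"""Reading, validating and writing aggregate baseline tables and design specs.

The aggregate CSV dialect mirrors how a published baseline table is
transcribed by hand: one file, a ``kind`` column separating continuous from
categorical covariates, and categorical covariates in long format (one line
per level). The reader accepts counts only — percentages must be converted to
integer counts by the user beforehand, so no silent rounding happens here.
Covariates reported only as median (IQR) cannot be used by the method and are
rejected with an explicit error.

Columns (unused cells left empty)::

    kind, covariate, level,
    arm1_n, arm1_mean, arm1_sd, arm1_count,
    arm2_n, arm2_mean, arm2_sd, arm2_count

The design specification is a small JSON object
``{"icc": float, "n_clusters": int, "n_total": int}`` holding the intraclass
correlation assumed in the sample-size calculation, the number of clusters
randomised (both arms combined) and the total number of participants who
consented. The design effect DEFF = 1 + (N/k - 1) * ICC is derived from it,
using one mean cluster size N/k for the whole trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

AGGREGATE_COLUMNS = [
    "kind",
    "covariate",
    "level",
    "arm1_n",
    "arm1_mean",
    "arm1_sd",
    "arm1_count",
    "arm2_n",
    "arm2_mean",
    "arm2_sd",
    "arm2_count",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ContinuousSummaryRow:
    """Per-arm n / mean / SD summary of one continuous baseline covariate."""

    covariate_name: str
    arm1_n: int
    arm1_mean: float
    arm1_sd: float
    arm2_n: int
    arm2_mean: float
    arm2_sd: float
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.covariate_name:
            raise ValidationError("continuous row with empty covariate name")
        for label, n in (("arm1_n", self.arm1_n), ("arm2_n", self.arm2_n)):
            if int(n) != n or n < 2:
                raise ValidationError(
                    f"{self.covariate_name}: {label} must be an integer >= 2, got {n}"
                )
        for label, sd in (("arm1_sd", self.arm1_sd), ("arm2_sd", self.arm2_sd)):
            if not math.isfinite(sd) or sd < 0:
                raise ValidationError(
                    f"{self.covariate_name}: {label} must be a non-negative real, got {sd}"
                )
            if sd == 0 and not self.allow_degenerate:
                raise ValidationError(
                    f"{self.covariate_name}: {label} is zero; pass allow_degenerate=True "
                    "to accept a constant covariate"
                )
        for label, m in (("arm1_mean", self.arm1_mean), ("arm2_mean", self.arm2_mean)):
            if not math.isfinite(m):
                raise ValidationError(f"{self.covariate_name}: {label} is not finite")


@dataclass
class CategoricalSummaryRow:
    """Per-arm level counts of one categorical baseline covariate."""

    covariate_name: str
    levels: list[str]
    arm1_counts: list[int]
    arm2_counts: list[int]

    def __post_init__(self) -> None:
        if not self.covariate_name:
            raise ValidationError("categorical row with empty covariate name")
        if len(self.levels) < 2:
            raise ValidationError(
                f"{self.covariate_name}: a categorical covariate needs >= 2 levels"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(f"{self.covariate_name}: duplicate level labels")
        if not (len(self.arm1_counts) == len(self.arm2_counts) == len(self.levels)):
            raise ValidationError(
                f"{self.covariate_name}: counts must align with levels "
                f"({len(self.levels)} levels, {len(self.arm1_counts)}/"
                f"{len(self.arm2_counts)} counts)"
            )
        for arm, counts in (("arm1", self.arm1_counts), ("arm2", self.arm2_counts)):
            for c in counts:
                if int(c) != c or c < 0:
                    raise ValidationError(
                        f"{self.covariate_name}: negative or non-integer {arm} count {c}"
                    )
            if sum(counts) == 0:
                raise ValidationError(
                    f"{self.covariate_name}: {arm} has no observations at any level"
                )


@dataclass(frozen=True)
class ClusterDesign:
    """Trial design quantities behind the design-effect adjustment.

    ``icc`` is the intraclass correlation assumed in the sample-size
    calculation, ``n_clusters`` the number of clusters randomised across both
    arms, and ``n_total`` the total number of participants who consented and
    participated. The design effect is 1 + (n_total/n_clusters - 1) * icc.
    """

    icc: float
    n_clusters: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.icc <= 1.0):
            raise ValidationError(f"icc must lie in [0, 1], got {self.icc}")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be a positive integer")
        if self.n_total < self.n_clusters:
            raise ValidationError(
                f"n_total ({self.n_total}) must be >= n_clusters ({self.n_clusters})"
            )

    @property
    def mean_cluster_size(self) -> float:
        return self.n_total / self.n_clusters

    @property
    def design_effect(self) -> float:
        from .summary_tests import compute_design_effect

        return compute_design_effect(self.icc, self.n_clusters, self.n_total)


@dataclass
class AggregateBaselineTable:
    """A transcribed published baseline table for a two-arm trial.

    ``design`` is the cluster design when the trial is cluster randomised;
    leaving it absent means an individually randomised (unadjusted) analysis.
    ``covariate_order`` preserves the input row order across both row kinds.
    """

    continuous_rows: list[ContinuousSummaryRow] = field(default_factory=list)
    categorical_rows: list[CategoricalSummaryRow] = field(default_factory=list)
    design: ClusterDesign | None = None
    covariate_order: list[str] | None = None

    def __post_init__(self) -> None:
        names = [r.covariate_name for r in self.continuous_rows] + [
            r.covariate_name for r in self.categorical_rows
        ]
        if not names:
            raise ValidationError("aggregate table has no covariates")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate covariate names: {sorted(dupes)}")
        if self.covariate_order is None:
            self.covariate_order = names
        elif sorted(self.covariate_order) != sorted(names):
            raise ValidationError("covariate_order does not match the table's covariates")

    @property
    def covariates(self) -> list[str]:
        return list(self.covariate_order or [])

    def row(self, name: str) -> ContinuousSummaryRow | CategoricalSummaryRow:
        for r in self.continuous_rows:
            if r.covariate_name == name:
                return r
        for r in self.categorical_rows:
            if r.covariate_name == name:
                return r
        raise KeyError(name)

    def iter_rows(self):
        for name in self.covariates:
            yield self.row(name)


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------


def _parse_number(cell: str, kind, where: str):
    try:
        return kind(cell)
    except (TypeError, ValueError):
        raise ValidationError(f"{where}: cannot parse {cell!r}") from None


def read_aggregate_table(
    path: str | Path, design: ClusterDesign | None = None
) -> AggregateBaselineTable:
    """Read an aggregate baseline table CSV in the documented dialect.

    Every row is validated against its type's invariants; row order in the
    file is preserved in ``covariate_order``. Categorical covariates appear
    as consecutive long-format lines, one per level.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in AGGREGATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")

    continuous: list[ContinuousSummaryRow] = []
    cat_acc: dict[str, dict[str, list]] = {}
    order: list[str] = []

    for i, rec in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after header
        where = f"{path.name} line {line}"
        kind = rec["kind"].strip().lower()
        name = rec["covariate"].strip()
        if kind == "continuous":
            if any(not rec[c].strip() for c in ("arm1_mean", "arm1_sd", "arm2_mean", "arm2_sd")):
                raise ValidationError(
                    f"{where} ({name}): continuous rows need per-arm mean and SD; "
                    "median/IQR summaries are not supported by this method"
                )
            continuous.append(
                ContinuousSummaryRow(
                    covariate_name=name,
                    arm1_n=_parse_number(rec["arm1_n"], int, where),
                    arm1_mean=_parse_number(rec["arm1_mean"], float, where),
                    arm1_sd=_parse_number(rec["arm1_sd"], float, where),
                    arm2_n=_parse_number(rec["arm2_n"], int, where),
                    arm2_mean=_parse_number(rec["arm2_mean"], float, where),
                    arm2_sd=_parse_number(rec["arm2_sd"], float, where),
                )
            )
            order.append(name)
        elif kind == "categorical":
            if name not in cat_acc:
                cat_acc[name] = {"levels": [], "arm1": [], "arm2": []}
                order.append(name)
            acc = cat_acc[name]
            acc["levels"].append(rec["level"].strip())
            acc["arm1"].append(_parse_number(rec["arm1_count"], int, where))
            acc["arm2"].append(_parse_number(rec["arm2_count"], int, where))
        else:
            raise ValidationError(
                f"{where}: kind must be 'continuous' or 'categorical', got {rec['kind']!r}"
            )

    categorical = [
        CategoricalSummaryRow(name, acc["levels"], acc["arm1"], acc["arm2"])
        for name, acc in cat_acc.items()
    ]
    return AggregateBaselineTable(
        continuous_rows=continuous,
        categorical_rows=categorical,
        design=design,
        covariate_order=order,
    )


def write_aggregate_table(table: AggregateBaselineTable, path: str | Path) -> None:
    """Write a table in the same CSV dialect that :func:`read_aggregate_table` reads.

    Numeric fields are written with ``repr`` so a write-then-read round trip
    is the identity to full float precision.
    """
    records: list[dict[str, str]] = []
    for row in table.iter_rows():
        if isinstance(row, ContinuousSummaryRow):
            records.append(
                {
                    "kind": "continuous",
                    "covariate": row.covariate_name,
                    "level": "",
                    "arm1_n": str(row.arm1_n),
                    "arm1_mean": repr(float(row.arm1_mean)),
                    "arm1_sd": repr(float(row.arm1_sd)),
                    "arm1_count": "",
                    "arm2_n": str(row.arm2_n),
                    "arm2_mean": repr(float(row.arm2_mean)),
                    "arm2_sd": repr(float(row.arm2_sd)),
                    "arm2_count": "",
                }
            )
        else:
            for level, c1, c2 in zip(row.levels, row.arm1_counts, row.arm2_counts):
                records.append(
                    {
                        "kind": "categorical",
                        "covariate": row.covariate_name,
                        "level": level,
                        "arm1_n": "",
                        "arm1_mean": "",
                        "arm1_sd": "",
                        "arm1_count": str(int(c1)),
                        "arm2_n": "",
                        "arm2_mean": "",
                        "arm2_sd": "",
                        "arm2_count": str(int(c2)),
                    }
                )
    pd.DataFrame(records, columns=AGGREGATE_COLUMNS).to_csv(path, index=False)


def read_design(path: str | Path) -> ClusterDesign:
    """Read a design-specification JSON and derive its design effect."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("icc", "n_clusters", "n_total"):
        if key not in obj:
            raise SchemaError(f"{path.name}: missing key {key!r}")
    return ClusterDesign(
        icc=float(obj["icc"]),
        n_clusters=int(obj["n_clusters"]),
        n_total=int(obj["n_total"]),
    )


def write_design(design: ClusterDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "icc": design.icc,
                "n_clusters": design.n_clusters,
                "n_total": design.n_total,
                "design_effect": design.design_effect,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def tables_equal(a: AggregateBaselineTable, b: AggregateBaselineTable) -> bool:
    """Field-level equality of two tables (numeric fields to full precision)."""
    if a.covariates != b.covariates:
        return False
    for name in a.covariates:
        ra, rb = a.row(name), b.row(name)
        if type(ra) is not type(rb):
            return False
        if isinstance(ra, ContinuousSummaryRow):
            if (
                ra.arm1_n != rb.arm1_n
                or ra.arm2_n != rb.arm2_n
                or ra.arm1_mean != rb.arm1_mean
                or ra.arm2_mean != rb.arm2_mean
                or ra.arm1_sd != rb.arm1_sd
                or ra.arm2_sd != rb.arm2_sd
            ):
                return False
        else:
            if (
                ra.levels != rb.levels
                or list(ra.arm1_counts) != list(rb.arm1_counts)
                or list(ra.arm2_counts) != list(rb.arm2_counts)
            ):
                return False
    return True
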