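"""Reduce a set of baseline test results to a selection-bias report.

In a sound two-arm trial every baseline null is true, so on average one in
twenty baseline tests is significant at alpha = 0.05. A table showing many
significant covariates — or any covariate at a vanishingly small p such as
p < 0.0001 — is therefore evidence that recruitment, not randomisation,
formed the groups. This module operationalises that informal argument as an
auditable rule: count the adjusted p-values below ``alpha`` and below the
stringent ``high_threshold``, compute the exact upper-tail probability of
seeing at least that many significant results under Binomial(K, alpha), and
map the pair (tail probability, stringent-flag count) onto a verdict.

The binomial null treats the K covariate tests as independent; baseline
covariates are typically positively correlated, so the tail probability is
approximate. The per-covariate p-values are always displayed raw alongside
the summary, and no further multiplicity correction is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Literal

from scipy import stats

from .errors import ValidationError
from .summary_tests import BaselineTestResult, results_to_frame

SCHEMA_VERSION = "1"

VERDICT_CONSISTENT = "consistent_with_null"
VERDICT_CAUTION = "caution"
VERDICT_STRONG = "strong_evidence_of_bias"

DECISION_RULE = (
    "strong_evidence_of_bias if binomial_tail_p < 0.01 or "
    "(n_tests >= 10 and n_highly_significant >= 2); "
    "caution if binomial_tail_p < 0.10 or n_highly_significant >= 1; "
    "otherwise consistent_with_null. "
    "binomial_tail_p = P(X >= n_significant) for X ~ Binomial(n_tests, alpha), "
    "computed on the adjusted p-values; degenerate tests are excluded from n_tests. "
    "The binomial null assumes independent covariates and is approximate when "
    "baseline covariates are correlated."
)


@dataclass
class BiasSummary:
    """Counts, flags and the binomial tail probability for one trial's baseline table."""

    n_tests: int
    alpha: float
    high_threshold: float
    n_significant: int
    n_highly_significant: int
    expected_significant: float
    binomial_tail_p: float
    verdict: str
    n_excluded: int = 0
    decision_rule: str = DECISION_RULE
    schema_version: str = SCHEMA_VERSION


def binomial_tail(n_significant: int, n_tests: int, alpha: float) -> float:
    """Exact P(X >= n_significant) for X ~ Binomial(n_tests, alpha)."""
    if n_significant <= 0:
        return 1.0
    return float(stats.binom.sf(n_significant - 1, n_tests, alpha))


def _verdict(tail_p: float, n_highly: int, n_tests: int) -> str:
    if tail_p < 0.01 or (n_tests >= 10 and n_highly >= 2):
        return VERDICT_STRONG
    if tail_p < 0.10 or n_highly >= 1:
        return VERDICT_CAUTION
    return VERDICT_CONSISTENT


def summarise(
    results: list[BaselineTestResult],
    alpha: float = 0.05,
    high_threshold: float = 1e-4,
) -> BiasSummary:
    """Summarise a list of baseline test results into a :class:`BiasSummary`.

    Degenerate/flagged results are excluded (with the exclusion count
    reported) and K reduced accordingly; the verdict follows the documented
    decision rule, which is reproduced verbatim on the summary itself.
    """
    if not results:
        raise ValidationError("cannot summarise an empty result list")
    if not (0.0 < high_threshold <= alpha < 1.0):
        raise ValidationError(
            f"thresholds must satisfy 0 < high_threshold <= alpha < 1, "
            f"got high_threshold={high_threshold}, alpha={alpha}"
        )
    usable = [r for r in results if not r.degenerate and math.isfinite(r.p_adjusted)]
    n_excluded = len(results) - len(usable)
    if not usable:
        raise ValidationError("all results are degenerate; nothing to summarise")
    k = len(usable)
    n_sig = sum(r.p_adjusted < alpha for r in usable)
    n_high = sum(r.p_adjusted < high_threshold for r in usable)
    tail = binomial_tail(n_sig, k, alpha)
    return BiasSummary(
        n_tests=k,
        alpha=alpha,
        high_threshold=high_threshold,
        n_significant=n_sig,
        n_highly_significant=n_high,
        expected_significant=k * alpha,
        binomial_tail_p=tail,
        verdict=_verdict(tail, n_high, k),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt_p(p: float) -> str:
    if not math.isfinite(p):
        return "-"
    return f"{p:.2e}" if p < 0.001 else f"{p:.4f}"


def render_report(
    summary: BiasSummary,
    results: list[BaselineTestResult],
    format: Literal["markdown", "json", "tsv"] = "markdown",
) -> str:
    """Render the per-covariate table plus the verdict as markdown, JSON or TSV.

    The JSON form round-trips: :func:`summary_from_json` recovers an equal
    :class:`BiasSummary` from it.
    """
    if format == "json":
        return json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "summary": asdict(summary),
                "results": [r.as_record() for r in results],
            },
            indent=2,
        )
    if format == "tsv":
        lines = [results_to_frame(results).to_csv(sep="\t", index=False).rstrip("\n")]
        lines.append("")
        for key, value in asdict(summary).items():
            if key == "decision_rule":
                continue
            lines.append(f"# {key}\t{value}")
        return "\n".join(lines) + "\n"
    if format != "markdown":
        raise ValidationError(f"unknown report format {format!r}")

    lines = [
        "# Baseline covariate balance report",
        "",
        f"Verdict: **{summary.verdict}**",
        "",
        f"- tests summarised: {summary.n_tests}"
        + (f" ({summary.n_excluded} degenerate, excluded)" if summary.n_excluded else ""),
        f"- significant at alpha = {summary.alpha:g}: {summary.n_significant} "
        f"(expected under the null: {summary.expected_significant:.2f})",
        f"- highly significant (p < {summary.high_threshold:g}): "
        f"{summary.n_highly_significant}",
        f"- exact binomial tail probability of >= {summary.n_significant} "
        f"significant tests: {_fmt_p(summary.binomial_tail_p)}",
        "",
        "| covariate | method | statistic (adj.) | p unadjusted | p adjusted | flags |",
        "|---|---|---|---|---|---|",
    ]
    for r in results:
        stat = "-" if not math.isfinite(r.statistic_adjusted) else f"{r.statistic_adjusted:.4f}"
        flags = []
        if not r.degenerate and r.p_adjusted < summary.high_threshold:
            flags.append("highly significant")
        elif not r.degenerate and r.p_adjusted < summary.alpha:
            flags.append("significant")
        if r.degenerate:
            flags.append("degenerate (excluded)")
        lines.append(
            f"| {r.covariate_name} | {r.method} | {stat} "
            f"| {_fmt_p(r.p_unadjusted)} | {_fmt_p(r.p_adjusted)} | {', '.join(flags)} |"
        )
    lines += [
        "",
        f"Decision rule: {summary.decision_rule}",
        "",
    ]
    return "\n".join(lines)


def summary_from_json(text: str) -> BiasSummary:
    """Parse the JSON report back into a :class:`BiasSummary`."""
    obj = json.loads(text)
    return BiasSummary(**obj["summary"])
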