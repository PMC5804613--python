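"""Report rendering: cohort characteristics, stage table, summary text.

Every number written here comes from a metrics/protocol operation; this
module only formats (2 decimals on the ng/mL scale, whole percent for
MDAPE, three decimals for correlations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (
    BiasSummary,
    ExceedanceResult,
    RegressionSummary,
    StageSummary,
    build_stage_table,
    correlation_regression,
    difference,
    difference_vs_time_regression,
    exceedance,
    fixed_bias,
)
from .protocol import ExclusionReport, PairedSample

__all__ = [
    "CohortSummaryRow",
    "AnalysisBundle",
    "summarize_characteristics",
    "summarize_pairs",
    "stage_table_to_frame",
    "pairs_to_frame",
    "render_reports",
]

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class CohortSummaryRow:
    """One characteristics row: formatted per-arm summaries.

    The format per arm follows the recorded normality decision: a
    Shapiro-Wilk test at alpha=0.05 selects ``mean +/- SD`` for plausibly
    normal variables and ``median (q1, q3) [min, max]`` otherwise.
    """

    variable: str
    summaries: dict[str, str]
    normal: dict[str, bool]


def _summarize_one(values: np.ndarray) -> tuple[str, bool]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise ValueError("normality-based summary needs n >= 3")
    if np.ptp(values) == 0:
        # degenerate: constant variable; SD is exactly zero
        return f"{values[0]:.1f} ± 0.0", True
    _, p = stats.shapiro(values)
    if p >= SHAPIRO_ALPHA:
        return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}", True
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return (
        f"{med:.1f} ({q1:.1f}, {q3:.1f}) [{values.min():.1f}, {values.max():.1f}]",
        False,
    )


def summarize_characteristics(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    arm_col: str = "procedure",
) -> list[CohortSummaryRow]:
    """Per-arm descriptive summaries of patient-level variables.

    ``table`` holds one row per patient with an arm column and numeric
    variables (covariates plus derived totals such as total fentanyl dose
    or sample counts).
    """
    if variables is None:
        variables = [
            c
            for c in table.columns
            if c != arm_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    arms = list(dict.fromkeys(table[arm_col]))
    for arm in arms:
        if (table[arm_col] == arm).sum() < 3:
            raise ValueError(f"arm {arm!r} has fewer than 3 patients")
    rows = []
    for var in variables:
        summaries, normal = {}, {}
        for arm in arms:
            s, is_norm = _summarize_one(table.loc[table[arm_col] == arm, var].values)
            summaries[arm] = s
            normal[arm] = is_norm
        rows.append(CohortSummaryRow(variable=var, summaries=summaries, normal=normal))
    return rows


@dataclass(frozen=True)
class AnalysisBundle:
    """Everything the text/CSV reports need, computed once from the pairs."""

    pairs: list[PairedSample]
    exclusions: ExclusionReport
    stage_table: list[StageSummary]
    overall_bias: BiasSummary
    overall_exceedance: ExceedanceResult
    measured_vs_predicted: RegressionSummary
    difference_vs_time: RegressionSummary
    difference_vs_time_by_arm: dict[str, RegressionSummary]


def summarize_pairs(
    pairs: Sequence[PairedSample], exclusions: ExclusionReport
) -> AnalysisBundle:
    """Compute the full set of reported statistics from usable pairs."""
    pairs = list(pairs)
    by_arm = {}
    for arm in sorted({p.procedure for p in pairs}):
        arm_pairs = [p for p in pairs if p.procedure == arm]
        if len(arm_pairs) >= 3:
            by_arm[arm] = difference_vs_time_regression(arm_pairs)
    return AnalysisBundle(
        pairs=pairs,
        exclusions=exclusions,
        stage_table=build_stage_table(pairs),
        overall_bias=fixed_bias(pairs),
        overall_exceedance=exceedance(pairs),
        measured_vs_predicted=correlation_regression(
            [p.predicted for p in pairs], [p.measured for p in pairs]
        ),
        difference_vs_time=difference_vs_time_regression(pairs),
        difference_vs_time_by_arm=by_arm,
    )


def pairs_to_frame(pairs: Sequence[PairedSample]) -> pd.DataFrame:
    from .metrics import performance_error

    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in pairs],
            "procedure": [p.procedure for p in pairs],
            "elapsed_min": [p.elapsed for p in pairs],
            "measured_ng_ml": [p.measured for p in pairs],
            "predicted_ng_ml": [p.predicted for p in pairs],
            "difference_ng_ml": [difference(p) for p in pairs],
            "performance_error_pct": [performance_error(p) for p in pairs],
            "stage": [p.stage for p in pairs],
        }
    )


def stage_table_to_frame(table: Sequence[StageSummary]) -> pd.DataFrame:
    rows = []
    for s in table:
        rows.append(
            {
                "procedure": s.procedure,
                "stage": s.stage,
                "n": s.n,
                "mean_measured": round(s.mean_measured, 2),
                "sd_measured": round(s.sd_measured, 2),
                "mean_predicted": round(s.mean_predicted, 2),
                "sd_predicted": round(s.sd_predicted, 2),
                "mean_difference": round(s.bias.mean_difference, 2),
                "sd_difference": round(s.bias.sd_difference, 2),
                "ci_low": round(s.bias.ci_low, 2),
                "ci_high": round(s.bias.ci_high, 2),
                "range_low": round(s.bias.range_low, 2),
                "range_high": round(s.bias.range_high, 2),
                "n_over_plus": s.n_over_plus,
                "n_under_minus": s.n_under_minus,
                "mdape_pct": round(s.mdape_pct),
            }
        )
    return pd.DataFrame(rows)


def _fmt_reg(reg: RegressionSummary) -> str:
    return (
        f"r = {reg.r:.3f}, y = {reg.slope:.3f}x + {reg.intercept:.3f} "
        f"(n = {reg.n}, P = {reg.p_value:.3g})"
    )


def render_reports(
    outdir: str | Path,
    bundle: AnalysisBundle,
    characteristics: Sequence[CohortSummaryRow] | None = None,
) -> dict[str, Path]:
    """Write table2.csv, summary.txt and exclusions.txt into ``outdir``.

    Deterministic: identical inputs give byte-identical files.  Returns
    the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    from .io import write_table

    table2 = outdir / "table2.csv"
    write_table(stage_table_to_frame(bundle.stage_table), table2)
    written["table2"] = table2

    b = bundle.overall_bias
    e = bundle.overall_exceedance
    lines = [
        "Measured vs simulation-predicted plasma concentration",
        "=====================================================",
        f"usable pairs: {b.n}",
        f"measured vs predicted: {_fmt_reg(bundle.measured_vs_predicted)}",
        (
            f"overall difference (measured - predicted): "
            f"{b.mean_difference:.2f} ± {b.sd_difference:.2f} ng/mL "
            f"[range {b.range_low:.2f}, {b.range_high:.2f}]"
        ),
        (
            f"samples beyond ±0.5 ng/mL: {e.n_over_plus} over, "
            f"{e.n_under_minus} under ({100 * e.fraction_abs:.1f}%)"
        ),
        f"difference vs elapsed time: {_fmt_reg(bundle.difference_vs_time)}",
    ]
    for arm, reg in bundle.difference_vs_time_by_arm.items():
        lines.append(f"  {arm}: {_fmt_reg(reg)}")
    if characteristics:
        lines.append("")
        lines.append("Patient characteristics")
        lines.append("-----------------------")
        arms = list(characteristics[0].summaries)
        for row in characteristics:
            per_arm = "; ".join(f"{a}: {row.summaries[a]}" for a in arms)
            lines.append(f"{row.variable}: {per_arm}")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written["summary"] = summary

    x = bundle.exclusions
    excl = outdir / "exclusions.txt"
    excl.write_text(
        "\n".join(
            [
                f"raw samples: {x.n_raw}",
                f"pre-dose controls excluded: {x.n_pre_dose_excluded}",
                f"within 10 min of a bolus excluded: {x.n_post_bolus_excluded}",
                f"below LLOQ excluded: {x.n_below_lloq}",
                f"usable samples: {x.n_usable}",
            ]
        )
        + "\n"
    )
    written["exclusions"] = excl
    return written
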