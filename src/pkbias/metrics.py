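"""Accuracy statistics for measured-vs-predicted concentration pairs.

Two complementary scales are used throughout:

* the *difference* scale, ``measured - predicted`` in ng/mL, on which the
  fixed bias (group mean difference with a 95% CI), its range, the
  +/-0.5 ng/mL exceedance counts and the difference-vs-time regression
  are computed; and
* the *performance error* (PE) scale,
  ``(measured - predicted) / predicted * 100%``, the standard relative
  accuracy measure for concentration prediction, summarised by the median
  absolute performance error (MDAPE).

The module also provides the Fisher-z sample-size calculation for
detecting a correlation, and the per-(procedure, stage) summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .protocol import PairedSample

__all__ = [
    "BiasSummary",
    "StageSummary",
    "RegressionSummary",
    "PowerSpec",
    "ExceedanceResult",
    "difference",
    "performance_error",
    "mdape",
    "fixed_bias",
    "ci_from_moments",
    "exceedance",
    "correlation_regression",
    "difference_vs_time_regression",
    "sample_size_for_correlation",
    "empirical_power_for_correlation",
    "build_stage_table",
    "EXCEEDANCE_THRESHOLD",
]

EXCEEDANCE_THRESHOLD = 0.5  # ng/mL


@dataclass(frozen=True)
class BiasSummary:
    """Fixed bias: mean difference, its CI, and the observed range (ng/mL)."""

    n: int
    mean_difference: float
    sd_difference: float
    ci_low: float
    ci_high: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("CI must bracket the mean difference")
        if self.range_low > self.range_high:
            raise ValueError("range_low must not exceed range_high")


@dataclass(frozen=True)
class StageSummary:
    """Accuracy statistics for one (procedure, stage) cell."""

    procedure: str
    stage: int
    n: int
    mean_measured: float
    sd_measured: float
    mean_predicted: float
    sd_predicted: float
    bias: BiasSummary
    n_over_plus: int
    n_under_minus: int
    mdape_pct: float

    def __post_init__(self) -> None:
        if self.n_over_plus + self.n_under_minus > self.n:
            raise ValueError("exceedance counts exceed cell size")
        if self.mdape_pct < 0:
            raise ValueError("MDAPE must be non-negative")


@dataclass(frozen=True)
class RegressionSummary:
    """Pearson correlation and OLS line for one scatter."""

    r: float
    slope: float
    intercept: float
    n: int
    p_value: float  # reported only, never an acceptance quantity

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation out of range")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


@dataclass(frozen=True)
class PowerSpec:
    """Design of a correlation-detection study."""

    r_target: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.r_target < 1:
            raise ValueError("r_target must lie strictly in (0, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


@dataclass(frozen=True)
class ExceedanceResult:
    n_over_plus: int
    n_under_minus: int
    fraction_abs: float


def _differences(group: Iterable[PairedSample | float]) -> np.ndarray:
    vals = [difference(g) if isinstance(g, PairedSample) else float(g) for g in group]
    return np.asarray(vals, dtype=float)


def difference(pair: PairedSample) -> float:
    """Measured minus predicted concentration, ng/mL."""
    return pair.measured - pair.predicted


def performance_error(pair: PairedSample) -> float:
    """Performance error (measured - predicted) / predicted * 100, percent."""
    if pair.predicted <= 0:
        raise ValueError("performance error undefined for non-positive prediction")
    return (pair.measured - pair.predicted) / pair.predicted * 100.0


def mdape(group: Sequence[PairedSample]) -> float:
    """Median absolute performance error over a group, percent."""
    if len(group) == 0:
        raise ValueError("MDAPE undefined for an empty group")
    return float(np.median([abs(performance_error(p)) for p in group]))


def ci_from_moments(
    mean: float, sd: float, n: int, level: float = 0.95, method: str = "t"
) -> tuple[float, float]:
    """Two-sided CI for a mean from summary moments.

    ``method='t'`` uses the Student-t quantile with n-1 df (the default);
    ``method='z'`` the normal quantile.
    """
    if n < 2:
        raise ValueError("CI undefined for n < 2")
    alpha = 1.0 - level
    if method == "t":
        q = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
    elif method == "z":
        q = stats.norm.ppf(1.0 - alpha / 2.0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = q * sd / math.sqrt(n)
    return mean - half, mean + half


def fixed_bias(
    group: Sequence[PairedSample | float],
    level: float = 0.95,
    method: str = "t",
) -> BiasSummary:
    """Fixed bias of a group: mean difference with a t-based two-sided CI.

    Accepts paired samples or raw differences.  The CI is
    ``mean +/- t_{1-alpha/2, n-1} * sd / sqrt(n)``; the range is the
    min/max of the differences.
    """
    d = _differences(group)
    n = d.size
    if n < 2:
        raise ValueError("fixed bias CI undefined for n < 2")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = ci_from_moments(mean, sd, n, level=level, method=method)
    return BiasSummary(
        n=n,
        mean_difference=mean,
        sd_difference=sd,
        ci_low=lo,
        ci_high=hi,
        range_low=float(d.min()),
        range_high=float(d.max()),
    )


def exceedance(
    group: Sequence[PairedSample | float],
    threshold: float = EXCEEDANCE_THRESHOLD,
) -> ExceedanceResult:
    """Counts of differences beyond +/-threshold and their pooled fraction."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d = _differences(group)
    if d.size == 0:
        raise ValueError("exceedance undefined for an empty group")
    over = int(np.sum(d > threshold))
    under = int(np.sum(d < -threshold))
    return ExceedanceResult(over, under, (over + under) / d.size)


def correlation_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionSummary:
    """Pearson r and the OLS line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return RegressionSummary(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
        p_value=float(res.pvalue),
    )


def difference_vs_time_regression(
    group: Sequence[PairedSample],
    time_unit: float = 1.0,
) -> RegressionSummary:
    """Regress the difference on elapsed time since the first dose.

    ``time_unit`` rescales the abscissa (minutes / time_unit); e.g. 10.0
    reports the slope per 10 minutes.  Constant differences are still a
    valid regression (slope 0) but constant *times* raise.
    """
    t = np.asarray([p.elapsed for p in group], dtype=float) / time_unit
    d = _differences(group)
    if np.ptp(d) == 0:
        # degenerate: flat response; r is undefined, report 0 with slope 0
        if t.size < 3 or np.ptp(t) == 0:
            raise ValueError("regression needs n >= 3 and non-constant time")
        return RegressionSummary(
            r=0.0, slope=0.0, intercept=float(d[0]), n=int(t.size), p_value=1.0
        )
    return correlation_regression(t, d)


def sample_size_for_correlation(spec: PowerSpec) -> int:
    """Minimum n to detect a correlation via the Fisher z-transform.

    ``n = ceil(((z_{1-alpha/2} + z_{power}) / atanh(r))^2 + 3)``.
    """
    z_a = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = stats.norm.ppf(spec.power)
    fz = math.atanh(spec.r_target)
    return int(math.ceil(((z_a + z_b) / fz) ** 2 + 3))


def empirical_power_for_correlation(
    n: int,
    rho: float,
    alpha: float = 0.05,
    n_reps: int = 5000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo rejection rate of H0: rho = 0 at sample size n.

    Draws ``n_reps`` bivariate-normal samples with correlation ``rho`` and
    applies the two-sided t-test on Pearson r; vectorised over replicates.
    """
    if rng is None:
        rng = np.random.default_rng()
    x = rng.standard_normal((n_reps, n))
    e = rng.standard_normal((n_reps, n))
    y = rho * x + math.sqrt(1.0 - rho**2) * e
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(np.mean(np.abs(tstat) > crit))


def build_stage_table(
    pairs: Sequence[PairedSample],
    threshold: float = EXCEEDANCE_THRESHOLD,
    level: float = 0.95,
) -> list[StageSummary]:
    """One StageSummary per non-empty (procedure, stage) cell.

    Cells are ordered by procedure name then stage; cells with a single
    pair report a zero-width CI at the observed difference (the t-CI needs
    n >= 2, so a singleton falls back to its point value).
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to summarise")
    cells: dict[tuple[str, int], list[PairedSample]] = {}
    for p in pairs:
        cells.setdefault((p.procedure, p.stage), []).append(p)
    out: list[StageSummary] = []
    for (proc, stage), cell in sorted(cells.items()):
        meas = np.array([p.measured for p in cell])
        pred = np.array([p.predicted for p in cell])
        n = len(cell)
        if n >= 2:
            bias = fixed_bias(cell, level=level)
        else:
            d = difference(cell[0])
            bias = BiasSummary(1, d, 0.0, d, d, d, d)
        exc = exceedance(cell, threshold=threshold)
        out.append(
            StageSummary(
                procedure=proc,
                stage=stage,
                n=n,
                mean_measured=float(meas.mean()),
                sd_measured=float(meas.std(ddof=1)) if n >= 2 else 0.0,
                mean_predicted=float(pred.mean()),
                sd_predicted=float(pred.std(ddof=1)) if n >= 2 else 0.0,
                bias=bias,
                n_over_plus=exc.n_over_plus,
                n_under_minus=exc.n_under_minus,
                mdape_pct=mdape(cell),
            )
        )
    return out
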