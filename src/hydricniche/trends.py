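"""Nonparametric trend statistics for annual climate series.

Implements the rank-based Mann-Kendall trend test (tie-corrected
variance, +-1 continuity correction, two-sided normal p-value), Sen's
slope (median of all pairwise slopes) with a rank-based 95% confidence
interval and decadal scaling, deviation-from-baseline anomalies
(1961-1990 climate-normal baseline by default), empirical percentile
ranks (mid-rank convention), and a lag-k autocorrelation utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import InsufficientDataError, InvalidInputError, MissingYearError

__all__ = [
    "AnnualSeries",
    "MannKendallResult",
    "SenSlopeResult",
    "mann_kendall",
    "sens_slope",
    "anomaly",
    "percentile_rank",
    "autocorrelation",
]


@dataclass(frozen=True)
class AnnualSeries:
    """An annual climate series (one variable, one value per year)."""

    variable: str
    years: tuple[int, ...]
    values: tuple[float, ...]
    baseline_window: tuple[int, int] = (1961, 1990)

    def __post_init__(self):
        if len(self.years) != len(self.values):
            raise InvalidInputError("years and values must have equal length")
        y = np.asarray(self.years)
        if len(y) and np.any(np.diff(y) <= 0):
            raise InvalidInputError("years must be strictly increasing (no duplicates)")
        object.__setattr__(self, "years", tuple(int(v) for v in self.years))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Closed year-range subset [start, end]."""
        pairs = [(y, v) for y, v in zip(self.years, self.values) if start <= y <= end]
        return AnnualSeries(
            self.variable,
            tuple(p[0] for p in pairs),
            tuple(p[1] for p in pairs),
            self.baseline_window,
        )

    def value(self, year: int) -> float:
        try:
            return self.values[self.years.index(year)]
        except ValueError:
            raise MissingYearError(f"year {year} absent from series {self.variable!r}")


@dataclass(frozen=True)
class MannKendallResult:
    S: int
    var_s: float
    z: float
    p_two_sided: float
    tau: float
    n: int


@dataclass(frozen=True)
class SenSlopeResult:
    slope_per_year: float
    slope_per_decade: float
    ci_95: tuple[float, float]
    n: int


def _mk_stats(values: np.ndarray) -> tuple[int, float]:
    """Mann-Kendall S and tie-corrected variance of S."""
    n = len(values)
    sgn = np.sign(values[None, :] - values[:, None])
    s = int(np.triu(sgn, k=1).sum())
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    return s, var_s


def mann_kendall(series: AnnualSeries, continuity: bool = True) -> MannKendallResult:
    """Mann-Kendall trend test over the observed years of a series.

    ``S`` sums ``sign(x_j - x_i)`` over all ordered pairs i < j; the
    variance carries the standard tie correction and, with
    ``continuity=True`` (the default convention), Z applies a +-1
    continuity correction before the two-sided normal p-value.
    Missing years are simply absent: pairs run over observed years.
    """
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    if n < 4:
        raise InsufficientDataError("Mann-Kendall needs n >= 4")
    s, var_s = _mk_stats(values)
    if var_s <= 0:  # all values tied
        z = 0.0
    elif s > 0:
        z = (s - 1 if continuity else s) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1 if continuity else s) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    tau = s / (0.5 * n * (n - 1))
    return MannKendallResult(S=s, var_s=var_s, z=z, p_two_sided=float(p), tau=float(tau), n=n)


def sens_slope(series: AnnualSeries, alpha: float = 0.05) -> SenSlopeResult:
    """Sen's slope: median of all pairwise slopes, with a rank-based CI.

    Slopes are ``(x_j - x_i) / (year_j - year_i)`` over all ordered
    pairs; the confidence interval takes the rank-based bounds
    ``(N -/+ z_{1-alpha/2} sqrt(var S)) / 2`` into the sorted slopes
    (lower index floored, upper index ceiled — a conservative
    convention).  ``slope_per_decade`` is 10x the annual slope.
    """
    years = np.asarray(series.years, dtype=float)
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    if n < 2:
        raise InsufficientDataError("Sen's slope needs n >= 2")
    dy = values[None, :] - values[:, None]
    dt = years[None, :] - years[:, None]
    iu = np.triu_indices(n, k=1)
    slopes = np.sort(dy[iu] / dt[iu])
    slope = float(np.median(slopes))
    big = len(slopes)
    if n >= 4:
        _, var_s = _mk_stats(values)
        c = norm.ppf(1.0 - alpha / 2.0) * math.sqrt(var_s)
        lo_idx = int(max(math.floor((big - c) / 2.0), 0))
        hi_idx = int(min(math.ceil((big + c) / 2.0), big) - 1)
        ci = (float(slopes[lo_idx]), float(slopes[hi_idx]))
    else:
        ci = (float(slopes[0]), float(slopes[-1]))
    return SenSlopeResult(
        slope_per_year=slope, slope_per_decade=10.0 * slope, ci_95=ci, n=n
    )


def anomaly(series: AnnualSeries, year: int, percent: bool = False) -> float:
    """Deviation of one year's value from the baseline-window mean.

    With ``percent=True`` the deviation is expressed as a percentage of
    the baseline mean.
    """
    start, end = series.baseline_window
    base = [v for y, v in zip(series.years, series.values) if start <= y <= end]
    if not base:
        raise InsufficientDataError(
            f"no observed years in baseline window {series.baseline_window}"
        )
    mean = float(np.mean(base))
    dev = series.value(year) - mean
    if percent:
        return 100.0 * dev / mean
    return dev


def percentile_rank(series: AnnualSeries, year: int) -> float:
    """Empirical percentile (0-100) of a year's value, mid-rank convention.

    The rank is the mean of the "proportion strictly below" and
    "proportion at or below" conventions, so full ties score 50.
    """
    target = series.value(year)
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    less = float(np.sum(values < target))
    equal = float(np.sum(values == target))
    return 100.0 * (less + 0.5 * equal) / n


@dataclass(frozen=True)
class AutocorrelationResult:
    lags: tuple[int, ...]
    acf: tuple[float, ...]
    bound: float  # +-1.96/sqrt(n) white-noise significance bound
    significant: tuple[bool, ...] = field(default=())


def autocorrelation(series: AnnualSeries, max_lag: int | None = None) -> AutocorrelationResult:
    """Lag-k sample autocorrelations with white-noise significance bounds."""
    values = np.asarray(series.values, dtype=float)
    n = len(values)
    if n < 3:
        raise InsufficientDataError("autocorrelation needs n >= 3")
    if max_lag is None:
        max_lag = min(n - 2, 20)
    x = values - values.mean()
    denom = float(np.dot(x, x))
    acf = [float(np.dot(x[:-k], x[k:]) / denom) for k in range(1, max_lag + 1)]
    bound = 1.96 / math.sqrt(n)
    sig = tuple(abs(a) > bound for a in acf)
    return AutocorrelationResult(
        lags=tuple(range(1, max_lag + 1)), acf=tuple(acf), bound=bound, significant=sig
    )
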