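"""Threshold-exceedance analytics on 30-minute soil sensor series.

Soil water potential / temperature loggers at frog sites are summarised
per site and July-June year window into counts and proportions of days
breaching the absorption threshold (AT, kPa), the thermal optimum
(T_opt, degC) and the critical thermal maximum (CT_max, degC), plus the
habitat maximum temperature and the resulting warming tolerance.

Day-counting rule
-----------------
By default a calendar day counts as exceeding AT if *any* non-missing
30-min water-potential reading that day is drier than AT (strictly
below), and as exceeding a temperature threshold if any reading is
strictly above it — breaching a physiological limit at any time of day
is the biologically conservative reading.  A ``daily-mean`` rule is
exposed as an option (``daily-extreme`` is equivalent to ``any`` and
accepted as an alias).  Days with no readings at all drop out of the
denominator; no imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyWindowError,
    InsufficientDataError,
    InvalidInputError,
    JoinError,
)

__all__ = [
    "SensorSeries",
    "SiteYearSummary",
    "PopulationEstimate",
    "SpearmanResult",
    "parse_year_window",
    "summarize_site_year",
    "exceedance_population_correlation",
    "mean_exceedance_days",
]

_DAY_RULES = ("any", "daily-mean", "daily-extreme")


@dataclass(frozen=True)
class SensorSeries:
    """A 30-min soil psi/temperature series for one site-habitat.

    ``data`` is a DataFrame indexed by timestamp with float columns
    ``psi`` (kPa, <= 0) and ``temp`` (degC); NaN marks missing readings.
    """

    site_id: str
    habitat: str  # "riparian" | "terrestrial"
    data: pd.DataFrame
    n_malformed: int = 0  # rows rejected by the reader, for provenance

    def __post_init__(self):
        df = self.data
        if not {"psi", "temp"} <= set(df.columns):
            raise InvalidInputError("sensor data needs 'psi' and 'temp' columns")
        if len(df) and not df.index.is_monotonic_increasing:
            raise InvalidInputError("timestamps must be increasing")
        if len(df) and df.index.has_duplicates:
            raise InvalidInputError("duplicate timestamps in sensor series")
        psi = df["psi"].to_numpy(dtype=float)
        if np.any(psi[np.isfinite(psi)] > 0):
            raise InvalidInputError("psi readings must be <= 0 kPa")

    @classmethod
    def from_arrays(cls, site_id, habitat, timestamps, psi, temp, n_malformed=0):
        df = pd.DataFrame(
            {"psi": np.asarray(psi, dtype=float), "temp": np.asarray(temp, dtype=float)},
            index=pd.DatetimeIndex(timestamps, name="timestamp"),
        )
        return cls(site_id=site_id, habitat=habitat, data=df, n_malformed=n_malformed)


@dataclass(frozen=True)
class SiteYearSummary:
    """Exceedance summary of one site over one July-June window."""

    site_id: str
    year_window: str  # e.g. "2019-20"
    days_exceeding_at: int
    days_exceeding_topt: int
    days_exceeding_ctmax: int
    prop_at: float
    prop_topt: float
    prop_ctmax: float
    t_hab_max: float | None
    wt: float | None
    n_days_observed: int


@dataclass(frozen=True)
class PopulationEstimate:
    """Population size inferred from calling males (50:50 sex ratio)."""

    site_id: str
    calling_males: int

    @property
    def estimated_size(self) -> int:
        return 2 * self.calling_males


@dataclass(frozen=True)
class SpearmanResult:
    rs: float
    p_value: float
    n: int


def parse_year_window(window):
    """Normalise a year window to (start, end) timestamps and a label.

    Accepts a label like ``"2019-20"`` (July 1 2019 to June 30 2020), a
    start year, or an explicit (start, end) pair of timestamps (end
    exclusive).
    """
    if isinstance(window, str) and "-" in window and ":" not in window:
        start_year = int(window.split("-")[0])
    elif isinstance(window, (int, np.integer)):
        start_year = int(window)
    else:
        start, end = window
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        label = f"{start.year}-{str(end.year)[-2:]}"
        return start, end, label
    start = pd.Timestamp(year=start_year, month=7, day=1)
    end = pd.Timestamp(year=start_year + 1, month=7, day=1)
    return start, end, f"{start_year}-{str(start_year + 1)[-2:]}"


def _exceed_days(frame, col, threshold, below, rule):
    """Number of days whose readings breach a threshold under a day rule."""
    series = frame[col].dropna()
    if series.empty:
        return 0
    if rule == "daily-mean":
        daily = series.groupby(series.index.normalize()).mean()
    elif below:  # 'any' / 'daily-extreme': driest reading of the day
        daily = series.groupby(series.index.normalize()).min()
    else:  # hottest reading of the day
        daily = series.groupby(series.index.normalize()).max()
    breached = daily < threshold if below else daily > threshold
    return int(breached.sum())


def summarize_site_year(
    series: SensorSeries,
    at: float,
    t_opt: float,
    ct_max: float,
    year_window,
    day_rule: str = "any",
) -> SiteYearSummary:
    """Summarise threshold exceedance for one site over one year window.

    A day exceeds AT when its water potential is drier (strictly below)
    than ``at``; it exceeds T_opt/CT_max when its temperature is
    strictly above the threshold.  ``t_hab_max`` is the maximum soil
    temperature in the window and the warming tolerance is
    ``ct_max - t_hab_max``.
    """
    if day_rule not in _DAY_RULES:
        raise InvalidInputError(f"day_rule must be one of {_DAY_RULES}")
    if at > 0:
        raise InvalidInputError("absorption threshold must be <= 0 kPa")
    start, end, label = parse_year_window(year_window)
    frame = series.data.loc[(series.data.index >= start) & (series.data.index < end)]
    frame = frame.dropna(how="all")
    if frame.empty:
        raise EmptyWindowError(
            f"site {series.site_id!r} has no readings in window {label}"
        )
    n_days = int(frame.index.normalize().nunique())
    days_at = _exceed_days(frame, "psi", at, below=True, rule=day_rule)
    days_topt = _exceed_days(frame, "temp", t_opt, below=False, rule=day_rule)
    days_ctmax = _exceed_days(frame, "temp", ct_max, below=False, rule=day_rule)
    temp = frame["temp"].dropna()
    t_hab_max = float(temp.max()) if len(temp) else None
    wt = ct_max - t_hab_max if t_hab_max is not None else None
    return SiteYearSummary(
        site_id=series.site_id,
        year_window=label,
        days_exceeding_at=days_at,
        days_exceeding_topt=days_topt,
        days_exceeding_ctmax=days_ctmax,
        prop_at=days_at / n_days,
        prop_topt=days_topt / n_days,
        prop_ctmax=days_ctmax / n_days,
        t_hab_max=t_hab_max,
        wt=wt,
        n_days_observed=n_days,
    )


def exceedance_population_correlation(
    summaries: Sequence[SiteYearSummary],
    populations: Sequence[PopulationEstimate],
    which: str = "at",
) -> SpearmanResult:
    """Spearman rank correlation of exceedance days against population size.

    Pairs summaries and population estimates by ``site_id`` (every site
    must appear in both), then computes the tie-corrected Spearman
    correlation (Pearson correlation of average ranks) with a two-sided
    t-approximation p-value.
    """
    counts = {s.site_id: getattr(s, f"days_exceeding_{which}") for s in summaries}
    sizes = {p.site_id: p.estimated_size for p in populations}
    unmatched = set(counts) ^ set(sizes)
    if unmatched:
        raise JoinError(
            f"site ids not present in both tables: {sorted(unmatched)}",
            unmatched=sorted(unmatched),
        )
    sites = sorted(counts)
    if len(sites) < 4:
        raise InsufficientDataError("need >= 4 paired sites")
    x = np.array([counts[s] for s in sites], dtype=float)
    y = np.array([sizes[s] for s in sites], dtype=float)
    rs, p = stats.spearmanr(x, y)
    return SpearmanResult(rs=float(rs), p_value=float(p), n=len(sites))


def mean_exceedance_days(
    summaries: Sequence[SiteYearSummary], which: str = "at"
) -> float:
    """Arithmetic mean across sites of an exceedance-day count."""
    if not summaries:
        raise InsufficientDataError("no site summaries supplied")
    return float(
        np.mean([getattr(s, f"days_exceeding_{which}") for s in summaries])
    )
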