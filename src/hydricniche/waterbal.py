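"""Water-balance arithmetic and absorption-threshold estimation.

An adult frog's net cutaneous water exchange on a wetted substrate is
expressed as an area-normalised flux (mg cm^-2 h^-1, positive = uptake).
Surface area follows the anuran allometry ``SA = 9.9 * mass^0.56`` (cm^2,
mass in g), evaluated at the frog's *standard mass* — the mass of the
fully hydrated animal with an empty bladder.

The absorption threshold (AT) is the substrate water potential at which
net flux is zero: on wetter substrates the frog gains water, on drier
ones it loses water.  It is estimated from per-treatment mean fluxes by
linear interpolation between the two adjacent treatments that bracket
zero (the default), or from a global isotonic (monotone) fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    IncompleteSeriesError,
    InvalidInputError,
    NoCrossingError,
)

__all__ = [
    "FrogRecord",
    "FluxMeasurement",
    "AbsorptionThreshold",
    "HydrationRate",
    "surface_area",
    "hydration_fraction",
    "flux_rate",
    "estimate_absorption_threshold",
    "dehydration_rate",
]


def surface_area(mass: float) -> float:
    """Ventral-plus-dorsal skin surface area (cm^2) from body mass (g).

    Uses the empirical anuran allometry ``9.9 * mass**0.56``.
    """
    if not (math.isfinite(mass) and mass >= 0):
        raise InvalidInputError(f"mass must be non-negative, got {mass}")
    return 9.9 * mass**0.56


def hydration_fraction(mass: float, standard_mass: float) -> float:
    """Current mass as a fraction of standard (fully hydrated) mass."""
    if not (math.isfinite(standard_mass) and standard_mass > 0):
        raise InvalidInputError("standard_mass must be positive")
    return mass / standard_mass


def flux_rate(
    mass_start: float, mass_end: float, duration: float, standard_mass: float
) -> float:
    """Area-normalised water flux, mg cm^-2 h^-1 (positive = uptake).

    The mass change over ``duration`` hours is normalised by the surface
    area of the frog at its standard mass.
    """
    if not (math.isfinite(duration) and duration > 0):
        raise InvalidInputError("duration must be a positive number of hours")
    return 1000.0 * (mass_end - mass_start) / surface_area(standard_mass) / duration


@dataclass(frozen=True)
class FrogRecord:
    """One frog with a timestamped mass series (times in hours)."""

    frog_id: str
    species_label: str
    standard_mass: float  # g
    times: tuple[float, ...]  # h, strictly increasing
    masses: tuple[float, ...]  # g

    def __post_init__(self):
        if not (self.standard_mass > 0):
            raise InvalidInputError("standard_mass must be positive")
        if len(self.times) != len(self.masses) or len(self.times) < 2:
            raise InvalidInputError("need >= 2 paired (time, mass) readings")
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(m <= 0):
            raise InvalidInputError("masses must be positive")


@dataclass(frozen=True)
class FluxMeasurement:
    """Area-normalised flux of one frog on one wetted substrate."""

    frog_id: str
    water_potential: float  # kPa, <= 0
    flux: float  # mg cm^-2 h^-1, positive = uptake
    mass_start: float | None = None
    mass_end: float | None = None
    duration: float | None = None
    excluded: bool = False  # frog urinated/defecated during the trial

    def __post_init__(self):
        if self.water_potential > 0:
            raise InvalidInputError("water_potential must be <= 0 kPa")
        if not math.isfinite(self.flux):
            raise InvalidInputError("flux must be finite")

    @classmethod
    def from_masses(
        cls,
        frog_id: str,
        water_potential: float,
        mass_start: float,
        mass_end: float,
        duration: float,
        standard_mass: float,
        excluded: bool = False,
    ) -> "FluxMeasurement":
        return cls(
            frog_id=frog_id,
            water_potential=water_potential,
            flux=flux_rate(mass_start, mass_end, duration, standard_mass),
            mass_start=mass_start,
            mass_end=mass_end,
            duration=duration,
            excluded=excluded,
        )


@dataclass(frozen=True)
class AbsorptionThreshold:
    """Estimated zero-flux water potential and how it was obtained."""

    threshold: float  # kPa, <= 0
    method: str
    n_frogs: int
    bracket: tuple[float, float]  # (wetter psi, drier psi)

    def __post_init__(self):
        if self.threshold > 0:
            raise InvalidInputError("threshold must be <= 0 kPa")
        lo, hi = min(self.bracket), max(self.bracket)
        if not (lo <= self.threshold <= hi):
            raise InvalidInputError("threshold must lie within the bracketing pair")


def _treatment_means(measurements):
    by_psi: dict[float, list[float]] = {}
    for m in measurements:
        by_psi.setdefault(float(m.water_potential), []).append(m.flux)
    psis = np.array(sorted(by_psi, reverse=True))  # wettest (0) first
    means = np.array([np.mean(by_psi[p]) for p in psis])
    return psis, means


def estimate_absorption_threshold(
    measurements: Sequence[FluxMeasurement],
    method: str = "bracket",
) -> AbsorptionThreshold:
    """Estimate the absorption threshold from flux measurements.

    Excluded measurements are dropped; per-treatment mean fluxes are
    computed and scanned from the wettest treatment downward for the
    first sign change.  ``method="bracket"`` interpolates linearly
    between the two adjacent treatment means that bracket zero;
    ``method="isotonic"`` first replaces the means by their best
    monotone (non-decreasing in water potential) fit and interpolates on
    the fitted values, which is robust to non-monotone noise.

    Raises
    ------
    EmptyInputError
        If no measurements remain after dropping excluded ones.
    NoCrossingError
        If the mean flux never changes sign across treatments.
    """
    kept = [m for m in measurements if not m.excluded]
    if not kept:
        raise EmptyInputError("all flux measurements excluded")
    if method not in ("bracket", "isotonic"):
        raise InvalidInputError("method must be 'bracket' or 'isotonic'")
    psis, means = _treatment_means(kept)
    if len(psis) < 2:
        raise NoCrossingError("need >= 2 water-potential treatments")
    if method == "isotonic":
        from sklearn.isotonic import IsotonicRegression

        # flux increases with water potential (wetter -> more uptake)
        iso = IsotonicRegression(increasing=True)
        means = iso.fit_transform(psis[::-1], means[::-1])[::-1]

    n_frogs = len({m.frog_id for m in kept})
    for i in range(len(psis) - 1):
        wet_psi, dry_psi = psis[i], psis[i + 1]
        wet_flux, dry_flux = means[i], means[i + 1]
        if wet_flux == 0.0:
            return AbsorptionThreshold(float(wet_psi), method, n_frogs, (float(wet_psi), float(dry_psi)))
        if wet_flux > 0.0 and dry_flux <= 0.0:
            if dry_flux == 0.0:
                thr = float(dry_psi)
            else:
                thr = float(
                    wet_psi + (dry_psi - wet_psi) * wet_flux / (wet_flux - dry_flux)
                )
            return AbsorptionThreshold(thr, method, n_frogs, (float(wet_psi), float(dry_psi)))
    raise NoCrossingError(
        "mean flux does not change sign across treatments; no threshold bracketed"
    )


@dataclass(frozen=True)
class HydrationRate:
    """Rate of mass change between two hydration fractions."""

    g_per_h: float  # magnitude of the mass-change rate
    pct_standard_per_h: float  # same, as % of standard mass per hour
    window: tuple[float, float]  # (from_fraction, to_fraction)


def _time_at_fraction(times, masses, target_mass, falling):
    """First time the series reaches target_mass, linearly interpolated."""
    for i in range(len(masses)):
        reached = masses[i] <= target_mass if falling else masses[i] >= target_mass
        if reached:
            if i == 0 or masses[i] == target_mass:
                return times[i], masses[i]
            t = times[i - 1] + (times[i] - times[i - 1]) * (
                (target_mass - masses[i - 1]) / (masses[i] - masses[i - 1])
            )
            return t, target_mass
    return None


def dehydration_rate(
    frog: FrogRecord,
    from_fraction: float = 1.0,
    to_fraction: float = 0.9,
) -> HydrationRate:
    """Mass-change rate between two hydration fractions of standard mass.

    The series is scanned for the first readings at/beyond each fraction
    bound, interpolating linearly at the bounds, and the slope of mass
    versus time between the two bound crossings is returned (as a
    magnitude, g h^-1 and % standard mass h^-1).  With
    ``from_fraction < to_fraction`` (e.g. 0.89 -> 1.0) the same machinery
    measures a rehydration rate on a rising series.
    """
    times = np.asarray(frog.times, dtype=float)
    masses = np.asarray(frog.masses, dtype=float)
    falling = to_fraction < from_fraction
    start = _time_at_fraction(times, masses, from_fraction * frog.standard_mass, falling)
    end = _time_at_fraction(times, masses, to_fraction * frog.standard_mass, falling)
    if start is None or end is None or end[0] <= start[0]:
        raise IncompleteSeriesError(
            f"mass series of {frog.frog_id!r} does not span fractions "
            f"{from_fraction}..{to_fraction}"
        )
    (t0, m0), (t1, m1) = start, end
    slope = abs((m1 - m0) / (t1 - t0))
    return HydrationRate(
        g_per_h=slope,
        pct_standard_per_h=100.0 * slope / frog.standard_mass,
        window=(from_fraction, to_fraction),
    )
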