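"""Seeded synthetic-data generators with known ground truth.

Each generator emulates one class of input the analysis pipeline
consumes — incubation durations, frog water fluxes, soil sensor series,
annual climate series and agar-model deployments — from explicit truth
parameters, so recovery tests can compare pipeline estimates against the
generating truth.  Defaults are the study conditions: the published
*G. alba* rate curve, an absorption threshold of -50 kPa, the seven
incubation regimes (constant 15/18/20/21/25 degC and sine-wave 21+-2.5,
25+-5 degC), Mediterranean-seasonal soils that are saturated in winter
and dry down in summer, and the published habitat-level water-loss
means.

Every generator is a pure function of its :class:`GeneratorConfig`:
identical config (including seed) gives bit-identical output.  Each
generator draws from an independent stream derived from the config seed,
so adding one generator call never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .devrate import (
    GEOCRINIA_ALBA,
    DevObservation,
    IncubationRegime,
    RateCurveParams,
    predict_duration,
)
from .errors import InvalidInputError, NonCompletionError
from .fieldloss import Deployment
from .microclim import PopulationEstimate, SensorSeries
from .trends import AnnualSeries
from .waterbal import FluxMeasurement, surface_area

__all__ = [
    "GeneratorConfig",
    "study_regimes",
    "gen_development_data",
    "gen_flux_data",
    "gen_microclimate",
    "microclimate_skeleton",
    "gen_climate_series",
    "gen_field_deployments",
]

# distinct sub-stream keys per generator (SeedSequence spawn keys)
_STREAMS = {
    "development": 1,
    "flux": 2,
    "microclimate": 3,
    "climate": 4,
    "deployments": 5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters and noise scales for every generator.

    The defaults are the study conditions; override individual fields
    (e.g. ``replace(config, seed=7)``) rather than re-tuning them.
    """

    seed: int = 0

    # --- incubation experiment ---
    rate_params: RateCurveParams = field(default_factory=lambda: GEOCRINIA_ALBA)
    constant_temps: tuple[float, ...] = (15.0, 18.0, 20.0, 21.0, 25.0)
    fluctuating: tuple[tuple[float, float], ...] = ((21.0, 2.5), (25.0, 5.0))
    duration_noise_sd: float = 1.0  # days
    clutches_per_regime: int = 4

    # --- water-flux experiment ---
    true_at: float = -50.0  # kPa
    flux_treatments: tuple[float, ...] = (
        0.0, -7.0, -15.0, -30.0, -40.0, -50.0, -70.0, -80.0, -100.0, -200.0
    )
    flux_slope_wet: float = 0.08  # mg cm^-2 h^-1 per kPa above AT
    flux_slope_dry: float = 0.05  # mg cm^-2 h^-1 per kPa below AT
    flux_noise_sd: float = 0.3  # mg cm^-2 h^-1
    n_frogs: int = 10
    frog_mass_mean: float = 1.35  # g (standard mass)
    frog_mass_sd: float = 0.27

    # --- microclimate sensors ---
    n_sites: int = 8
    series_start: str = "2019-07-01"
    series_days: int = 365
    psi_saturated: float = -5.0  # kPa, winter baseline
    psi_min_by_site: tuple[float, ...] = (
        -20.0, -30.0, -45.0, -55.0, -65.0, -90.0, -130.0, -200.0
    )
    temp_winter_mean: float = 12.0  # degC
    temp_summer_amp_by_site: tuple[float, ...] = (
        2.5, 3.0, 3.5, 4.0, 4.5, 5.5, 6.5, 7.3
    )
    temp_diel_amp: float = 2.5  # degC
    drydown_start_doy: int = 335  # Dec 1 (southern-hemisphere summer)
    drydown_days: int = 150
    psi_noise_sd_log10: float = 0.05  # on log10 |psi|
    temp_noise_sd: float = 0.3  # degC
    calling_males_by_site: tuple[int, ...] = (42, 35, 27, 18, 12, 8, 5, 3)

    # --- annual climate ---
    climate_years: tuple[int, int] = (1990, 2019)
    climate_base: float = 1000.0  # mm at the first year
    climate_slope: float = -10.9  # mm per year (-109 mm per decade)
    climate_noise_sd: float = 80.0  # mm

    # --- agar-model deployments ---
    habitat_loss_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "frog": 6.4, "adjacent_riparian": 13.5, "adjacent_terrestrial": 31.0
        }
    )  # % per 9 h, adult models at 25/50 m
    cover_loss_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "leaf_litter": 4.5, "moss": 5.0, "sedge": 6.5, "log": 5.5, "open": 26.0
        }
    )  # % per 9 h, adult models
    juvenile_loss_factor: float = 1.3
    loss_noise_sd: float = 2.0  # % per 9 h
    adult_mass: tuple[float, float] = (1.97, 0.16)  # g (mean, sd)
    juvenile_mass: tuple[float, float] = (0.46, 0.07)
    n_deploy_sites: int = 5

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


# ---------------------------------------------------------------------------
# incubation
# ---------------------------------------------------------------------------

def study_regimes(config: GeneratorConfig | None = None) -> list[IncubationRegime]:
    """The study's incubation regimes as regime objects.

    Fluctuating regimes follow one 24-h sine-wave cycle (recycled
    periodically by rate summation), mimicking diel fluctuation.
    """
    config = config or GeneratorConfig()
    regimes = [
        IncubationRegime(
            regime_id=f"const{t:g}", kind="constant", constant_temp=t,
            nominal_label=f"{t:g} degC",
        )
        for t in config.constant_temps
    ]
    hours = np.arange(24.0)
    for mean, amp in config.fluctuating:
        temps = mean + amp * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
        regimes.append(
            IncubationRegime(
                regime_id=f"fluct{mean:g}pm{amp:g}",
                kind="fluctuating",
                hourly_temps=tuple(temps),
                nominal_label=f"{mean:g} +- {amp:g} degC",
            )
        )
    return regimes


def gen_development_data(
    config: GeneratorConfig | None = None,
) -> tuple[list[IncubationRegime], list[DevObservation]]:
    """Split-clutch development durations from the truth rate curve.

    Durations are model predictions under each regime plus Gaussian
    noise (``duration_noise_sd`` days), ``clutches_per_regime`` split
    clutches per regime.  Refuses regimes under which development cannot
    complete.
    """
    config = config or GeneratorConfig()
    rng = config.rng("development")
    regimes = study_regimes(config)
    observations = []
    for regime in regimes:
        try:
            true_days = predict_duration(regime, config.rate_params)
        except NonCompletionError:
            raise InvalidInputError(
                f"truth curve cannot complete development under regime {regime.regime_id!r}"
            )
        mean_temp = (
            regime.constant_temp
            if regime.kind == "constant"
            else float(np.mean(regime.hourly_temps))
        )
        for k in range(config.clutches_per_regime):
            duration = true_days + rng.normal(0.0, config.duration_noise_sd)
            observations.append(
                DevObservation(
                    clutch_id=f"{regime.regime_id}-c{k + 1}",
                    regime_id=regime.regime_id,
                    duration_days=max(duration, 1.0),
                    mean_temp=mean_temp,
                )
            )
    return regimes, observations


# ---------------------------------------------------------------------------
# water flux
# ---------------------------------------------------------------------------

def true_flux(psi, config: GeneratorConfig):
    """Noise-free mean flux at water potential ``psi`` (piecewise linear).

    Positive above the true absorption threshold, zero at it, negative
    below; the wet and dry limbs have separate slopes.
    """
    p = np.asarray(psi, dtype=float)
    dev = p - config.true_at
    f = np.where(dev >= 0, config.flux_slope_wet * dev, config.flux_slope_dry * dev)
    return float(f) if np.ndim(psi) == 0 else f


def gen_flux_data(config: GeneratorConfig | None = None) -> list[FluxMeasurement]:
    """Per-frog flux measurements across water-potential treatments.

    Each of ``n_frogs`` frogs is measured on every treatment; fluxes are
    the piecewise-linear truth plus Gaussian noise, and start/end masses
    consistent with a 2-h trial are back-filled from the flux.
    """
    config = config or GeneratorConfig()
    if not (min(config.flux_treatments) < config.true_at < 0):
        raise InvalidInputError("true_at must lie inside the treatment range")
    rng = config.rng("flux")
    standard = np.clip(
        rng.normal(config.frog_mass_mean, config.frog_mass_sd, config.n_frogs),
        0.5, None,
    )
    out = []
    duration = 2.0  # h, as in the petri-dish trials
    for i in range(config.n_frogs):
        frog_id = f"frog{i + 1:02d}"
        sa = surface_area(standard[i])
        mass_start = 0.9 * standard[i]  # trial starts at ~90% hydration
        for psi in config.flux_treatments:
            flux = true_flux(psi, config) + rng.normal(0.0, config.flux_noise_sd)
            mass_end = mass_start + flux * sa * duration / 1000.0
            out.append(
                FluxMeasurement(
                    frog_id=frog_id,
                    water_potential=psi,
                    flux=float(flux),
                    mass_start=float(mass_start),
                    mass_end=float(mass_end),
                    duration=duration,
                )
            )
    return out


# ---------------------------------------------------------------------------
# microclimate
# ---------------------------------------------------------------------------

def microclimate_skeleton(config: GeneratorConfig, site_index: int):
    """Noise-free psi/temperature skeleton for one site.

    Returns (timestamps, psi, temp) at 30-min cadence.  Soil is
    saturated at ``psi_saturated`` outside the summer dry-down window;
    during the window, log10 |psi| rises and falls as a raised-cosine
    bump peaking at the site minimum.  Temperature is an annual sinusoid
    (coolest mid-winter) plus a diel sinusoid peaking mid-afternoon.
    """
    start = pd.Timestamp(config.series_start)
    periods = config.series_days * 48
    ts = pd.date_range(start, periods=periods, freq="30min")
    doy = ts.dayofyear.to_numpy(dtype=float)
    hour = ts.hour.to_numpy(dtype=float) + ts.minute.to_numpy(dtype=float) / 60.0

    # summer dry-down bump on log10 |psi|
    offset = (doy - config.drydown_start_doy) % 365.25
    in_window = offset < config.drydown_days
    w = np.where(in_window, np.sin(np.pi * offset / config.drydown_days) ** 2, 0.0)
    log_sat = np.log10(abs(config.psi_saturated))
    log_min = np.log10(abs(config.psi_min_by_site[site_index]))
    psi = -np.power(10.0, log_sat + (log_min - log_sat) * w)

    # annual cycle coolest at mid-winter (day ~196 = mid-July), warmest late Jan
    amp = config.temp_summer_amp_by_site[site_index]
    seasonal = config.temp_winter_mean + amp * (
        0.5 - 0.5 * np.cos(2.0 * np.pi * (doy - 26.0) / 365.25)
    ) * 2.0
    diel = config.temp_diel_amp * np.sin(2.0 * np.pi * (hour - 9.0) / 24.0)
    temp = seasonal + diel
    return ts, psi, temp


def gen_microclimate(
    config: GeneratorConfig | None = None, noise: bool = True
) -> list[SensorSeries]:
    """Seasonal 30-min soil sensor series for each site.

    Noise is Gaussian on log10 |psi| and additive on temperature; pass
    ``noise=False`` for the exact skeleton (known exceedance days).
    """
    config = config or GeneratorConfig()
    rng = config.rng("microclimate")
    out = []
    for i in range(config.n_sites):
        ts, psi, temp = microclimate_skeleton(config, i)
        if noise:
            log_abs = np.log10(np.abs(psi)) + rng.normal(
                0.0, config.psi_noise_sd_log10, len(psi)
            )
            psi = -np.power(10.0, log_abs)
            temp = temp + rng.normal(0.0, config.temp_noise_sd, len(temp))
        out.append(
            SensorSeries.from_arrays(
                site_id=f"site{i + 1}", habitat="riparian",
                timestamps=ts, psi=psi, temp=temp,
            )
        )
    return out


def population_estimates(config: GeneratorConfig | None = None) -> list[PopulationEstimate]:
    """Calling-male counts per site (largest populations at wettest sites)."""
    config = config or GeneratorConfig()
    return [
        PopulationEstimate(site_id=f"site{i + 1}", calling_males=males)
        for i, males in enumerate(config.calling_males_by_site[: config.n_sites])
    ]


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def gen_climate_series(
    config: GeneratorConfig | None = None, variable: str = "rainfall_mm"
) -> AnnualSeries:
    """Linear-trend-plus-noise annual series with known slope."""
    config = config or GeneratorConfig()
    rng = config.rng("climate")
    y0, y1 = config.climate_years
    years = np.arange(y0, y1 + 1)
    values = (
        config.climate_base
        + config.climate_slope * (years - y0)
        + rng.normal(0.0, config.climate_noise_sd, len(years))
    )
    return AnnualSeries(variable=variable, years=tuple(int(y) for y in years),
                        values=tuple(float(v) for v in values))


# ---------------------------------------------------------------------------
# deployments
# ---------------------------------------------------------------------------

def _make_deployment(rng, config, model_id, size_class, habitat, distance, site_id, mean_loss):
    mass_mean, mass_sd = (
        config.adult_mass if size_class == "adult" else config.juvenile_mass
    )
    mass_out = max(rng.normal(mass_mean, mass_sd), 0.1)
    loss9 = max(mean_loss + rng.normal(0.0, config.loss_noise_sd), 0.2)
    exposure = rng.uniform(9.0, 11.0)
    loss_frac = min(loss9 / 9.0 * exposure / 100.0, 0.95)
    time_out = pd.Timestamp("2020-02-03 06:30") + pd.Timedelta(minutes=int(rng.integers(0, 60)))
    return Deployment(
        model_id=model_id,
        size_class=size_class,
        habitat=habitat,
        distance_m=distance,
        mass_out=float(mass_out),
        mass_in=float(mass_out * (1.0 - loss_frac)),
        time_out=time_out,
        time_in=time_out + pd.Timedelta(hours=exposure),
        site_id=site_id,
    )


def gen_field_deployments(
    config: GeneratorConfig | None = None, experiment: str = "habitat"
) -> list[Deployment]:
    """Agar-model deployments with known per-group mean losses.

    ``experiment="habitat"``: adult and juvenile models in the three
    habitat types at 0/25/50 m across ``n_deploy_sites`` sites, group
    means from ``habitat_loss_means`` (juveniles scaled by
    ``juvenile_loss_factor``).  ``experiment="cover"``: models under the
    five cover types within frog habitat at three sites.
    """
    config = config or GeneratorConfig()
    rng = config.rng("deployments")
    out = []
    counter = 0
    if experiment == "habitat":
        for site in range(config.n_deploy_sites):
            for habitat, mean_loss in config.habitat_loss_means.items():
                for distance in (0.0, 25.0, 50.0):
                    for size_class in ("adult", "juvenile"):
                        counter += 1
                        mean = mean_loss * (
                            config.juvenile_loss_factor if size_class == "juvenile" else 1.0
                        )
                        out.append(
                            _make_deployment(
                                rng, config, f"m{counter:03d}", size_class,
                                habitat, distance, f"dsite{site + 1}", mean,
                            )
                        )
    elif experiment == "cover":
        for site in range(3):
            for cover, mean_loss in config.cover_loss_means.items():
                for size_class in ("adult", "juvenile"):
                    for _ in range(2):
                        counter += 1
                        mean = mean_loss * (
                            config.juvenile_loss_factor if size_class == "juvenile" else 1.0
                        )
                        out.append(
                            _make_deployment(
                                rng, config, f"c{counter:03d}", size_class,
                                cover, 0.0, f"csite{site + 1}", mean,
                            )
                        )
    else:
        raise InvalidInputError("experiment must be 'habitat' or 'cover'")
    return out
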