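"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular I/O is delimited text (comma/tab autodetected).  Sensor
exports from different logger families (iButton/HOBO/Em50 style) are
normalised through a configurable column map and timestamp format.
Fitted parameters and run configuration round-trip through YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import devrate, fieldloss, microclim, soilhydro, synth, trends, waterbal
from .errors import EmptyInputError, HydricNicheError, InvalidInputError

__all__ = [
    "RunConfig",
    "read_table",
    "read_sensor_export",
    "read_observations",
    "read_regimes",
    "read_flux_table",
    "read_annual_series",
    "read_population_table",
    "read_deployments",
    "read_rate_params",
    "write_rate_params",
    "run_pipeline",
]

log = logging.getLogger("hydricniche")

DEFAULT_SENSOR_COLUMNS = {"timestamp": "timestamp", "psi": "psi_kPa", "temp": "temp_C"}


def read_table(path) -> pd.DataFrame:
    """Read a delimited table, autodetecting comma/tab separators."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise EmptyInputError(f"empty file: {path}")
    return pd.read_csv(path, sep=None, engine="python")


# ---------------------------------------------------------------------------
# sensor exports
# ---------------------------------------------------------------------------

def read_sensor_export(
    path,
    column_map: Mapping[str, str] | None = None,
    timestamp_format: str | None = None,
    site_id: str | None = None,
    habitat: str = "riparian",
    malformed_tolerance: float = 0.2,
) -> microclim.SensorSeries:
    """Read a logger export into a validated :class:`SensorSeries`.

    ``column_map`` maps the canonical names ``timestamp``/``psi``/``temp``
    to the file's column headers; at least ``timestamp`` and one of
    ``psi``/``temp`` must be covered.  Rows with unparseable timestamps
    or entirely non-numeric readings are counted, logged and dropped;
    if their fraction exceeds ``malformed_tolerance`` a hard error
    listing the offending line numbers is raised.
    """
    cmap = dict(DEFAULT_SENSOR_COLUMNS)
    cmap.update(column_map or {})
    raw = read_table(path)
    if len(raw) == 0:
        raise EmptyInputError(f"no data rows in {path}")
    if cmap["timestamp"] not in raw.columns:
        raise InvalidInputError(f"missing timestamp column {cmap['timestamp']!r}")
    have = [k for k in ("psi", "temp") if cmap[k] in raw.columns]
    if not have:
        raise InvalidInputError("need at least one of the psi/temp columns")

    ts = pd.to_datetime(raw[cmap["timestamp"]], format=timestamp_format, errors="coerce")
    values = {}
    for key in ("psi", "temp"):
        if key in have:
            values[key] = pd.to_numeric(raw[cmap[key]], errors="coerce")
        else:
            values[key] = pd.Series(np.nan, index=raw.index)
    bad = ts.isna() | (values["psi"].isna() & values["temp"].isna())
    n_bad = int(bad.sum())
    if n_bad:
        lines = (raw.index[bad] + 2).tolist()  # 1-based, counting the header
        if n_bad / len(raw) > malformed_tolerance:
            raise InvalidInputError(
                f"{n_bad}/{len(raw)} malformed rows in {path} (lines {lines})"
            )
        log.warning("%s: dropped %d malformed rows (lines %s)", path, n_bad, lines)
    keep = ~bad
    frame = pd.DataFrame(
        {"psi": values["psi"][keep].to_numpy(), "temp": values["temp"][keep].to_numpy()},
        index=pd.DatetimeIndex(ts[keep], name="timestamp"),
    ).sort_index()
    if frame.empty:
        raise EmptyInputError(f"no valid readings in {path}")
    return microclim.SensorSeries(
        site_id=site_id or Path(path).stem,
        habitat=habitat,
        data=frame,
        n_malformed=n_bad,
    )


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

def read_observations(path) -> list[devrate.DevObservation]:
    """Columns: clutch_id, regime_id, duration_days [, mean_temp]."""
    df = read_table(path)
    return [
        devrate.DevObservation(
            clutch_id=str(r.clutch_id),
            regime_id=str(r.regime_id),
            duration_days=float(r.duration_days),
            mean_temp=float(r.mean_temp) if "mean_temp" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def read_regimes(directory) -> list[devrate.IncubationRegime]:
    """Read a regime table plus per-regime hourly series.

    ``directory`` must hold ``regimes.csv`` with columns regime_id,
    kind, constant_temp; each fluctuating regime additionally needs a
    two-column file ``<regime_id>.csv`` (timestamp, temp_C) at 1-h
    cadence.
    """
    directory = Path(directory)
    df = read_table(directory / "regimes.csv")
    out = []
    for r in df.itertuples():
        if str(r.kind) == "constant":
            out.append(
                devrate.IncubationRegime(
                    regime_id=str(r.regime_id), kind="constant",
                    constant_temp=float(r.constant_temp),
                )
            )
        else:
            series = read_table(directory / f"{r.regime_id}.csv")
            out.append(
                devrate.IncubationRegime(
                    regime_id=str(r.regime_id), kind="fluctuating",
                    hourly_temps=tuple(series["temp_C"].astype(float)),
                )
            )
    return out


def read_flux_table(path) -> list[waterbal.FluxMeasurement]:
    """Columns: frog_id, species, standard_mass_g, treatment_kPa,
    mass_start_g, mass_end_g, duration_h, excluded (0/1)."""
    df = read_table(path)
    return [
        waterbal.FluxMeasurement.from_masses(
            frog_id=str(r.frog_id),
            water_potential=float(r.treatment_kPa),
            mass_start=float(r.mass_start_g),
            mass_end=float(r.mass_end_g),
            duration=float(r.duration_h),
            standard_mass=float(r.standard_mass_g),
            excluded=bool(int(r.excluded)) if "excluded" in df.columns else False,
        )
        for r in df.itertuples()
    ]


def read_annual_series(path, variable=None, baseline=(1961, 1990)) -> trends.AnnualSeries:
    """Columns: year, value (one variable per file)."""
    df = read_table(path).sort_values("year")
    return trends.AnnualSeries(
        variable=variable or Path(path).stem,
        years=tuple(int(y) for y in df["year"]),
        values=tuple(float(v) for v in df["value"]),
        baseline_window=tuple(baseline),
    )


def read_population_table(path) -> list[microclim.PopulationEstimate]:
    """Columns: site_id, calling_males."""
    df = read_table(path)
    return [
        microclim.PopulationEstimate(site_id=str(r.site_id), calling_males=int(r.calling_males))
        for r in df.itertuples()
    ]


def read_deployments(path) -> list[fieldloss.Deployment]:
    """Columns: model_id, size_class, habitat, distance_m, mass_out_g,
    mass_in_g, time_out, time_in [, site_id]."""
    df = read_table(path)
    return [
        fieldloss.Deployment(
            model_id=str(r.model_id),
            size_class=str(r.size_class),
            habitat=str(r.habitat),
            distance_m=float(r.distance_m),
            mass_out=float(r.mass_out_g),
            mass_in=float(r.mass_in_g),
            time_out=pd.Timestamp(r.time_out),
            time_in=pd.Timestamp(r.time_in),
            site_id=str(getattr(r, "site_id", "")),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# fitted-parameter round trip
# ---------------------------------------------------------------------------

def write_rate_params(params: devrate.RateCurveParams, path) -> None:
    """Serialize fitted curve parameters (with SEs and RSS) to YAML."""
    doc = {
        "species_label": params.species_label,
        "parameters": {k: float(getattr(params, k)) for k in devrate.PARAM_NAMES},
        "se": {k: float(v) for k, v in (params.se or {}).items()},
        "rss": None if params.rss is None else float(params.rss),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_rate_params(path) -> devrate.RateCurveParams:
    doc = yaml.safe_load(Path(path).read_text())
    return devrate.RateCurveParams(
        **{k: float(v) for k, v in doc["parameters"].items()},
        se=doc.get("se") or None,
        rss=doc.get("rss"),
        species_label=doc.get("species_label", ""),
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    With all input paths left ``None`` the pipeline runs on the
    synthetic study conditions (seeded by ``seed``); any path that is
    set replaces the corresponding synthetic input.
    """

    output_dir: str = "hydricniche_run"
    seed: int = 0
    observations_path: str | None = None
    regimes_dir: str | None = None
    flux_path: str | None = None
    sensors_dir: str | None = None
    populations_path: str | None = None
    climate_path: str | None = None
    deployments_path: str | None = None
    at_kpa: float | None = None  # override estimated absorption threshold
    year_window: str = "2019-20"
    day_rule: str = "any"
    soil_class: str = "sand"
    trend_window: tuple[int, int] | None = None
    baseline_window: tuple[int, int] = (1961, 1990)
    fixed_params: Mapping[str, float] = field(default_factory=lambda: {"b5": 0.4})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if doc.get("trend_window") is not None:
            doc["trend_window"] = tuple(doc["trend_window"])
        if doc.get("baseline_window") is not None:
            doc["baseline_window"] = tuple(doc["baseline_window"])
        return cls(**doc)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write a report bundle.

    Stages: fit the development-rate curve -> extract T_opt/CT_max ->
    estimate the absorption threshold -> summarise per-site microclimate
    exceedance and warming tolerance -> trend statistics on the climate
    series -> agar-model group summary.  Outputs are written to
    ``config.output_dir`` as delimited tables plus a run manifest; the
    run is deterministic for a fixed configuration.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gen = synth.GeneratorConfig(seed=config.seed)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except HydricNicheError as exc:
            raise HydricNicheError(f"stage {name!r}: {exc}") from exc

    # --- development-rate curve ---
    if config.observations_path and config.regimes_dir:
        observations = stage("read-observations", read_observations, config.observations_path)
        regimes = stage("read-regimes", read_regimes, config.regimes_dir)
    else:
        regimes, observations = stage("synth-development", synth.gen_development_data, gen)
    params = stage(
        "fit-devrate", devrate.fit_rate_curve,
        observations, regimes, fixed=dict(config.fixed_params),
    )
    thresholds = stage("ctmax", devrate.estimate_ctmax, params)
    write_rate_params(params, out_dir / "rate_params.yaml")

    # --- absorption threshold ---
    if config.flux_path:
        flux = stage("read-flux", read_flux_table, config.flux_path)
    else:
        flux = stage("synth-flux", synth.gen_flux_data, gen)
    at = stage("absorption-threshold", waterbal.estimate_absorption_threshold, flux)
    at_value = config.at_kpa if config.at_kpa is not None else at.threshold
    curve = soilhydro.DEFAULT_CURVES[config.soil_class]
    at_vwc = soilhydro.psi_to_vwc(at_value, curve)
    pd.DataFrame(
        [{
            "t_opt_C": thresholds.t_opt,
            "ct_max_C": thresholds.ct_max,
            "at_kPa": at_value,
            "at_vwc_pct": at_vwc,
            "soil_class": config.soil_class,
            "n_frogs": at.n_frogs,
        }]
    ).to_csv(out_dir / "thresholds.csv", index=False)

    # --- microclimate exceedance ---
    if config.sensors_dir:
        sensor_dir = Path(config.sensors_dir)
        if not sensor_dir.is_dir():
            raise HydricNicheError(f"stage 'read-sensors': no such directory {sensor_dir}")
        sensor_files = sorted(sensor_dir.glob("*.csv"))
        if not sensor_files:
            raise HydricNicheError(f"stage 'read-sensors': no sensor files in {sensor_dir}")
        series = [stage("read-sensors", read_sensor_export, f) for f in sensor_files]
    else:
        series = stage("synth-microclimate", synth.gen_microclimate, gen)
    summaries = [
        stage(
            "exceedance", microclim.summarize_site_year,
            s, at_value, thresholds.t_opt, thresholds.ct_max,
            config.year_window, config.day_rule,
        )
        for s in series
    ]
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out_dir / "site_summaries.csv", index=False
    )
    if config.populations_path:
        populations = stage("read-populations", read_population_table, config.populations_path)
    else:
        populations = synth.population_estimates(gen)
    corr = stage(
        "population-correlation", microclim.exceedance_population_correlation,
        summaries, populations,
    )

    # --- climate trends ---
    if config.climate_path:
        climate = stage(
            "read-climate", read_annual_series,
            config.climate_path, baseline=config.baseline_window,
        )
    else:
        climate = stage("synth-climate", synth.gen_climate_series, gen)
    if config.trend_window:
        climate_win = climate.window(*config.trend_window)
    else:
        climate_win = climate
    mk = stage("mann-kendall", trends.mann_kendall, climate_win)
    sen = stage("sens-slope", trends.sens_slope, climate_win)
    pd.DataFrame(
        [{
            "variable": climate.variable,
            "n": mk.n,
            "mk_S": mk.S,
            "mk_z": mk.z,
            "mk_p": mk.p_two_sided,
            "sen_slope_per_year": sen.slope_per_year,
            "sen_slope_per_decade": sen.slope_per_decade,
            "sen_ci_lo": sen.ci_95[0],
            "sen_ci_hi": sen.ci_95[1],
        }]
    ).to_csv(out_dir / "trend.csv", index=False)

    # --- field water loss ---
    if config.deployments_path:
        deployments = stage("read-deployments", read_deployments, config.deployments_path)
    else:
        deployments = stage("synth-deployments", synth.gen_field_deployments, gen)
    loss = stage("fieldloss", fieldloss.group_summary, deployments)
    loss.to_csv(out_dir / "fieldloss.csv", index=False)

    from . import __version__

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "results": {
            "t_opt_C": thresholds.t_opt,
            "ct_max_C": thresholds.ct_max,
            "at_kPa": at_value,
            "mean_at_exceedance_days": microclim.mean_exceedance_days(summaries),
            "spearman_rs": corr.rs,
            "spearman_p": corr.p_value,
            "sen_slope_per_decade": sen.slope_per_decade,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
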