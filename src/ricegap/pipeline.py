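"""End-to-end pipeline: synth → simulate → gaps → project → scenarios.

All tables are UTF-8 CSV with header rows; unit suffixes in column names
(_mgha, _mha, _mt, _usd_b, _kg) guard against silent unit mixing.  A run is
reproducible from (config, seed) alone: every stage's outputs are written
with SHA-256 checksums into a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import crop, demand, scenarios, synthetic, upscaling
from .errors import RicegapError

__all__ = [
    "RunConfig",
    "StageError",
    "PipelineResult",
    "run_pipeline",
    "validate_tables",
    "write_weather_csv",
    "read_weather_csv",
    "buffers_to_frame",
    "frame_to_buffers",
    "profiles_to_frame",
    "frame_to_profiles",
]

log = logging.getLogger("ricegap")

_REGIMES = crop.REGIMES


class StageError(RicegapError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class RunConfig(BaseModel):
    """Fully serialisable run configuration."""

    seed: int = 0
    outdir: str = "ricegap_run"
    n_countries: int = Field(default=5, ge=1)
    weather_years: int = Field(default=10, ge=2)
    start_year: int = 2000
    closure_fractions: list[float] = [0.0, 0.25, 0.5, 0.75, 1.0]
    expansion_rates_mha_yr: list[float] = list(scenarios.EXPANSION_RATES_MHA_YR)
    horizon_years: float = 30.0
    price_usd_per_mg: float = 289.0
    demand_multiplier: float = 1.05
    yp_delta: float = 0.0
    area_delta: float = 0.0
    ssr_report_decimals: int = 2

    def scenario_spec(self) -> scenarios.ScenarioSpec:
        return scenarios.ScenarioSpec(
            horizon_years=self.horizon_years,
            price_usd_per_mg=self.price_usd_per_mg,
            demand_multiplier=self.demand_multiplier,
            yp_delta=self.yp_delta,
            area_delta=self.area_delta,
        )


@dataclass
class PipelineResult:
    study: synthetic.SyntheticStudy
    gap_table: pd.DataFrame
    regime_summary: pd.DataFrame
    stability: pd.DataFrame
    demand_records: pd.DataFrame
    scenario_grid: pd.DataFrame
    manifest: dict
    outdir: Path


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_weather_csv(weather: pd.DataFrame, path: Path | str) -> None:
    out = weather.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    # %.17g round-trips float64 exactly, keeping stage hand-offs lossless
    out.to_csv(path, index=False, float_format="%.17g")


def read_weather_csv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"], float_precision="round_trip")
    missing = [c for c in synthetic.WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise RicegapError(f"{path}: missing weather columns {missing}")
    return df[synthetic.WEATHER_COLUMNS]


def buffers_to_frame(buffers: list[synthetic.SiteBuffer]) -> pd.DataFrame:
    rows = []
    for b in buffers:
        rows.append({
            "id": b.id, "country": b.country, "climate_zone": b.climate_zone,
            "water_regime": b.water_regime, "area_ha": b.area_ha,
            "actual_yield_mgha": b.actual_yield_mgha,
            "sowing_doy": b.calendar.sowing_doy,
            "duration_days": b.calendar.duration_days,
            "establishment": b.calendar.establishment,
            "transplanting_offset_days": b.calendar.transplanting_offset_days,
            "overlaps": ";".join(f"{k}={v:.4f}" for k, v in sorted(b.overlaps.items())),
        })
    return pd.DataFrame(rows)


def frame_to_buffers(df: pd.DataFrame) -> list[synthetic.SiteBuffer]:
    out = []
    for _, r in df.iterrows():
        overlaps = {}
        if isinstance(r["overlaps"], str) and r["overlaps"]:
            for item in r["overlaps"].split(";"):
                k, v = item.split("=")
                overlaps[k] = float(v)
        cal = crop.CropCalendar(
            sowing_doy=int(r["sowing_doy"]), duration_days=int(r["duration_days"]),
            establishment=str(r["establishment"]),
            transplanting_offset_days=int(r["transplanting_offset_days"]),
        )
        out.append(synthetic.SiteBuffer(
            id=str(r["id"]), country=str(r["country"]),
            climate_zone=str(r["climate_zone"]), water_regime=str(r["water_regime"]),
            area_ha=float(r["area_ha"]), calendar=cal,
            actual_yield_mgha=float(r["actual_yield_mgha"]), overlaps=overlaps,
        ))
    return out


def profiles_to_frame(profiles: dict[str, synthetic.CountryProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles.values():
        row = {
            "name": p.name, "production_mt": p.production_mt,
            "imports_mt": p.imports_mt, "exports_mt": p.exports_mt,
            "stock_change_mt": p.stock_change_mt,
            "population_now": p.population_now, "population_2050": p.population_2050,
            "per_capita_now_kg": p.per_capita_now_kg,
            "per_capita_2050_kg": p.per_capita_2050_kg,
            "milling_rate": p.milling_rate,
            "yield_trend_kgha_yr": p.yield_trend_kgha_yr,
        }
        for regime in _REGIMES:
            row[f"area_{regime}_mha"] = p.area_mha_by_regime.get(regime, 0.0)
            row[f"ya_{regime}_mgha"] = p.actual_yield_mgha_by_regime.get(regime, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> dict[str, synthetic.CountryProfile]:
    out = {}
    for _, r in df.iterrows():
        areas = {}
        yas = {}
        for regime in _REGIMES:
            a = float(r[f"area_{regime}_mha"])
            if a > 0:
                areas[regime] = a
                yas[regime] = float(r[f"ya_{regime}_mgha"])
        out[str(r["name"])] = synthetic.CountryProfile(
            name=str(r["name"]), production_mt=float(r["production_mt"]),
            imports_mt=float(r["imports_mt"]), exports_mt=float(r["exports_mt"]),
            stock_change_mt=float(r["stock_change_mt"]),
            population_now=float(r["population_now"]),
            population_2050=float(r["population_2050"]),
            per_capita_now_kg=float(r["per_capita_now_kg"]),
            per_capita_2050_kg=float(r["per_capita_2050_kg"]),
            milling_rate=float(r["milling_rate"]),
            yield_trend_kgha_yr=float(r["yield_trend_kgha_yr"]),
            area_mha_by_regime=areas, actual_yield_mgha_by_regime=yas,
        )
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_tables(paths: dict[str, Path | str]) -> pd.DataFrame:
    """Schema/unit/invariant checks with row-level diagnostics.

    ``paths`` maps table kinds (``weather``, ``buffers``, ``profiles``) to CSV
    paths (``weather`` may map to a list of paths).  Returns a DataFrame of
    violations (table, row, column, message); empty means all checks passed.
    """
    violations: list[dict] = []

    def flag(table: str, row: int, column: str, message: str) -> None:
        violations.append({"table": str(table), "row": int(row),
                           "column": column, "message": message})

    weather_paths = paths.get("weather", [])
    if isinstance(weather_paths, (str, Path)):
        weather_paths = [weather_paths]
    for wp in weather_paths:
        df = pd.read_csv(wp, parse_dates=["date"])
        for i in df.index[df["tmax"] < df["tmin"]]:
            flag(wp, i, "tmax", "tmax < tmin")
        for i in df.index[df["srad"] < 0]:
            flag(wp, i, "srad", "negative solar radiation")
        for i in df.index[df["precip"] < 0]:
            flag(wp, i, "precip", "negative precipitation")
        day_steps = np.diff(pd.DatetimeIndex(df["date"]).values).astype(
            "timedelta64[D]").astype(int)
        for i in np.flatnonzero(day_steps != 1):
            flag(wp, i + 1, "date", "non-contiguous daily series")

    if "buffers" in paths:
        df = pd.read_csv(paths["buffers"])
        for i in df.index[df["area_ha"] <= 0]:
            flag(paths["buffers"], i, "area_ha", "non-positive area")
        bad = ~df["water_regime"].isin(_REGIMES)
        for i in df.index[bad]:
            flag(paths["buffers"], i, "water_regime",
                 f"unknown regime {df.loc[i, 'water_regime']!r}")

    if "profiles" in paths:
        df = pd.read_csv(paths["profiles"])
        for col in ("production_mt", "imports_mt", "exports_mt"):
            for i in df.index[df[col] < 0]:
                flag(paths["profiles"], i, col, "negative mass")
        lo, hi = synthetic.MILLING_RATE_RANGE
        outside = (df["milling_rate"] < lo) | (df["milling_rate"] > hi)
        for i in df.index[outside]:
            flag(paths["profiles"], i, "milling_rate",
                 f"milling rate outside [{lo}, {hi}]")

    return pd.DataFrame(violations,
                        columns=["table", "row", "column", "message"])


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage, writing per-stage CSVs and a provenance manifest.

    The simulate stage reads weather back from the CSVs the synth stage
    wrote, so the published tables — not in-memory state — are the contract
    between stages.  Reruns with the same config are byte-identical.
    """
    outdir = Path(config.outdir)
    (outdir / "weather").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # -- synth ------------------------------------------------------------
    log.info("stage synth: %d countries, %d weather years, seed %d",
             config.n_countries, config.weather_years, config.seed)
    try:
        study = synthetic.gen_site_network(
            config.n_countries, seed=config.seed, years=config.weather_years,
            start_year=config.start_year)
        for bid, wx in study.weather.items():
            p = outdir / "weather" / f"{bid}.csv"
            write_weather_csv(wx, p)
            written.append(p)
        buffers_csv = outdir / "buffers.csv"
        buffers_to_frame(study.buffers).to_csv(buffers_csv, index=False)
        profiles_csv = outdir / "profiles.csv"
        profiles_to_frame(study.profiles).to_csv(profiles_csv, index=False)
        written += [buffers_csv, profiles_csv]
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("synth", str(e)) from e

    # -- simulate ---------------------------------------------------------
    log.info("stage simulate: %d buffers", len(study.buffers))
    try:
        season_rows = []
        for buf in study.buffers:
            wpath = outdir / "weather" / f"{buf.id}.csv"
            if not wpath.exists():
                raise FileNotFoundError(f"missing weather file {wpath}")
            wx = synthetic.qc_fill(read_weather_csv(wpath))
            phen = crop.calibrate_development_rates(wx, buf.calendar)
            series = crop.simulate_multi_year(wx, buf.calendar, buf.water_regime,
                                              phenology=phen)
            study.yp_series[buf.id] = series
            study.phenology[buf.id] = phen
            for scen, results in series.results.items():
                yrs = series.years
                for y, res in zip(yrs, results):
                    season_rows.append({
                        "buffer_id": buf.id, "regime": buf.water_regime,
                        "year": int(y), "scenario": scen,
                        "groundwater_cm": (int(scen[2:]) if scen.startswith("gw")
                                           else (1000 if buf.water_regime == "rainfed_upland" else 0)),
                        "yield_mgha": res.yield_mgha,
                        "biomass_mgha": res.biomass_mgha,
                        "sterility": res.sterility, "died": res.died,
                    })
        seasons_csv = outdir / "seasons.csv"
        pd.DataFrame(season_rows).to_csv(seasons_csv, index=False)
        written.append(seasons_csv)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    # -- gaps -------------------------------------------------------------
    try:
        gap_table = upscaling.yield_gap_table(study)
        summary = upscaling.regime_summary(gap_table)
        stability = upscaling.stability_table(study)
        for name, df in (("yield_gaps", gap_table), ("gap_summary", summary),
                         ("stability", stability)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    except Exception as e:  # noqa: BLE001
        raise StageError("gaps", str(e)) from e

    # -- project ----------------------------------------------------------
    try:
        att_by_country = _attainable_by_country(gap_table)
        records = [demand.demand_record(p, att_by_country.get(name, {}),
                                        config.horizon_years)
                   for name, p in study.profiles.items()]
        demand_df = pd.DataFrame([r.__dict__ for r in records])
        p = outdir / "demand.csv"
        demand_df.to_csv(p, index=False)
        written.append(p)
    except Exception as e:  # noqa: BLE001
        raise StageError("project", str(e)) from e

    # -- scenarios --------------------------------------------------------
    try:
        inputs = scenario_inputs(study, gap_table, demand_df)
        grid = scenarios.run_scenario_grid(
            inputs, config.closure_fractions, config.expansion_rates_mha_yr,
            config.scenario_spec())
        p = outdir / "scenarios.csv"
        grid.to_csv(p, index=False)
        written.append(p)
    except Exception as e:  # noqa: BLE001
        raise StageError("scenarios", str(e)) from e

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)},
        "n_buffers": len(study.buffers),
        "n_countries": len(study.profiles),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(study=study, gap_table=gap_table, regime_summary=summary,
                          stability=stability, demand_records=demand_df,
                          scenario_grid=grid, manifest=manifest, outdir=outdir)


def _attainable_by_country(gap_table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Area-weighted attainable yield per country × regime."""
    out: dict[str, dict[str, float]] = {}
    for (country, regime), g in gap_table.groupby(["country", "regime"]):
        out.setdefault(country, {})[regime] = upscaling.area_weighted_mean(
            g["attainable_mgha"], g["area_ha"])
    return out


def scenario_inputs(study: synthetic.SyntheticStudy, gap_table: pd.DataFrame,
                    demand_df: pd.DataFrame) -> list[scenarios.CountryScenarioInput]:
    """Assemble the per-country scenario inputs from pipeline tables."""
    att = _attainable_by_country(gap_table)
    demand_2050 = dict(zip(demand_df["country"], demand_df["demand_2050_mt"]))
    out = []
    for name, p in study.profiles.items():
        out.append(scenarios.CountryScenarioInput(
            name=name,
            area_mha=dict(p.area_mha_by_regime),
            ya_mgha=dict(p.actual_yield_mgha_by_regime),
            attainable_mgha={r: att[name][r] for r in p.area_mha_by_regime},
            demand_2050_mt=demand_2050[name],
        ))
    return out
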