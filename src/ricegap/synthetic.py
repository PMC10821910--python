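"""Synthetic study inputs: weather, site networks, and country profiles.

The real analysis draws on station weather records, rice-area statistics,
crop calendars, and national supply/demand accounts.  This module generates
stand-ins with the statistical structure the downstream stages assume, so
the whole pipeline runs and is testable offline.

Weather model: sinusoidal annual cycles for mean temperature and clear-sky
radiation; rainfall as a two-state (wet/dry) Bernoulli occurrence process
with higher wet-day probability inside a monsoon window and gamma-distributed
wet-day depths; radiation multiplicatively attenuated on wet days.  Leap days
are generated like any other day.

Site networks emulate a reference-weather-station layout: each country gets
1–3 buffers (100 km circles in the real protocol) per water regime present,
with harvested areas, climate-zone labels, pairwise overlap fractions, and a
crop calendar.  Actual farmer yields are drawn strictly below the attainable
yield implied by simulating the buffer's weather, so every stratum carries a
positive exploitable gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import crop
from .errors import ParameterError

__all__ = [
    "WeatherGeneratorParams",
    "SiteBuffer",
    "CountryProfile",
    "SyntheticStudy",
    "gen_weather",
    "qc_fill",
    "gen_site_network",
    "WEATHER_COLUMNS",
]

WEATHER_COLUMNS = ["date", "srad", "tmax", "tmin", "precip"]


class WeatherGeneratorParams(BaseModel):
    """Parameters of the daily weather generator.

    Temperatures in °C, radiation in MJ m⁻² d⁻¹, precipitation in mm.
    The monsoon window is [onset, onset + length) in day-of-year terms.
    """

    t_mean_c: float = 27.0
    t_seasonal_amplitude_c: float = Field(default=2.5, ge=0)
    diurnal_range_c: float = Field(default=9.0, gt=0)
    monsoon_onset_doy: int = Field(default=150, ge=1, le=366)
    monsoon_length_days: int = Field(default=120, ge=0, le=366)
    p_wet_monsoon: float = Field(default=0.55, ge=0, le=1)
    p_wet_dry_season: float = Field(default=0.06, ge=0, le=1)
    wet_day_depth_mm: float = Field(default=10.0, gt=0)
    gamma_shape: float = Field(default=1.2, gt=0)
    monsoon_strength_sd: float = Field(default=0.30, ge=0)
    onset_jitter_days: float = Field(default=10.0, ge=0)
    srad_clear_mj: float = Field(default=21.0, gt=0)
    srad_amplitude_mj: float = Field(default=3.0, ge=0)
    rain_attenuation: float = Field(default=0.25, ge=0, le=1)
    t_noise_c: float = Field(default=1.2, ge=0)
    srad_noise_mj: float = Field(default=1.5, ge=0)
    start_year: int = 2000
    seed: int = 0

    @model_validator(mode="after")
    def _amplitude_sane(self) -> "WeatherGeneratorParams":
        if self.srad_amplitude_mj >= self.srad_clear_mj:
            raise ParameterError("radiation amplitude must be below the clear-sky mean")
        return self


def gen_weather(params: WeatherGeneratorParams, years: int) -> pd.DataFrame:
    """Generate ``years`` calendar years of daily weather.

    Deterministic in ``params`` (including its seed).  Output columns:
    ``date, srad, tmax, tmin, precip`` with tmax ≥ tmin, srad ≥ 0, precip ≥ 0
    and a contiguous daily index (leap days included).
    """
    if years < 1:
        raise ParameterError("years must be >= 1")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(f"{params.start_year}-01-01",
                          f"{params.start_year + years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)

    # annual cycle peaking shortly before monsoon onset
    phase = 2.0 * np.pi * (doy - (params.monsoon_onset_doy - 45)) / 365.25
    t_day = (params.t_mean_c + params.t_seasonal_amplitude_c * np.cos(phase)
             + rng.normal(0.0, params.t_noise_c, n))
    half_range = 0.5 * np.clip(
        params.diurnal_range_c + rng.normal(0.0, 0.25 * params.t_noise_c, n),
        0.5, None)
    tmax = t_day + half_range
    tmin = t_day - half_range

    # year-to-year monsoon variability: strength multiplier and onset shift
    year_idx = dates.year.to_numpy() - params.start_year
    strength = np.clip(
        rng.lognormal(0.0, params.monsoon_strength_sd, years), 0.0, None)[year_idx]
    onset_shift = rng.normal(0.0, params.onset_jitter_days, years)[year_idx]
    onset = params.monsoon_onset_doy + onset_shift
    in_monsoon = ((doy - onset) % 365 < params.monsoon_length_days)
    p_wet = np.where(in_monsoon,
                     np.clip(params.p_wet_monsoon * strength, 0.0, 0.95),
                     params.p_wet_dry_season)
    wet = rng.random(n) < p_wet
    scale = params.wet_day_depth_mm / params.gamma_shape
    depth = rng.gamma(params.gamma_shape, scale, n)
    precip = np.where(wet, depth, 0.0)

    srad = (params.srad_clear_mj + params.srad_amplitude_mj * np.cos(phase)
            + rng.normal(0.0, params.srad_noise_mj, n))
    srad = np.where(wet, srad * (1.0 - params.rain_attenuation), srad)
    srad = np.clip(srad, 0.1, None)

    return pd.DataFrame({"date": dates, "srad": srad, "tmax": tmax,
                         "tmin": tmin, "precip": precip})


def qc_fill(weather: pd.DataFrame) -> pd.DataFrame:
    """Fill missing weather values by linear interpolation between neighbours.

    Observed values are never altered and the operation is idempotent.  Gaps
    touching a series boundary cannot be interpolated two-sidedly and are
    filled with the nearest observed value; this is reported as a warning.
    """
    out = weather.copy()
    value_cols = [c for c in WEATHER_COLUMNS if c != "date" and c in out.columns]
    for col in value_cols:
        s = out[col].astype(float)
        if not s.isna().any():
            continue
        filled = s.interpolate(method="linear", limit_direction="forward",
                               limit_area="inside")
        if filled.isna().any():
            warnings.warn(
                f"{col}: gap at series boundary filled with nearest observed value",
                stacklevel=2)
            filled = filled.ffill().bfill()
        out[col] = filled
    return out


# ---------------------------------------------------------------------------
# site network and country profiles
# ---------------------------------------------------------------------------

@dataclass
class SiteBuffer:
    """One reference-station buffer: a site representing surrounding rice area."""

    id: str
    country: str
    climate_zone: str
    water_regime: str
    area_ha: float
    calendar: crop.CropCalendar
    actual_yield_mgha: float
    overlaps: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ParameterError("buffer area must be > 0")
        if self.water_regime not in crop.REGIMES:
            raise ParameterError(f"unknown regime: {self.water_regime}")
        for other, f in self.overlaps.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"overlap fraction with {other} outside [0,1]")


MILLING_RATE_RANGE = (0.63, 0.69)


@dataclass
class CountryProfile:
    """National supply/demand inputs, paddy basis unless noted.

    ``per_capita_*`` are kg paddy person⁻¹ yr⁻¹; ``yield_trend_kgha_yr`` is
    the historical farmer-yield trend used for 2050 extrapolation.
    """

    name: str
    production_mt: float
    imports_mt: float
    exports_mt: float
    stock_change_mt: float
    population_now: float
    population_2050: float
    per_capita_now_kg: float
    per_capita_2050_kg: float
    milling_rate: float
    yield_trend_kgha_yr: float
    area_mha_by_regime: dict[str, float]
    actual_yield_mgha_by_regime: dict[str, float]

    def __post_init__(self) -> None:
        for name in ("production_mt", "imports_mt", "exports_mt"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        lo, hi = MILLING_RATE_RANGE
        if not lo <= self.milling_rate <= hi:
            warnings.warn(f"milling rate {self.milling_rate:.3f} outside the "
                          f"typical [{lo}, {hi}] range", stacklevel=2)

    @property
    def total_area_mha(self) -> float:
        return sum(self.area_mha_by_regime.values())


@dataclass
class SyntheticStudy:
    """Bundle of generated study inputs plus the simulations run to build them."""

    buffers: list[SiteBuffer]
    profiles: dict[str, CountryProfile]
    weather: dict[str, pd.DataFrame]              # buffer id → daily weather
    phenology: dict[str, crop.PhenologyParams]    # buffer id → calibrated rates
    yp_series: dict[str, crop.YieldSeries]        # buffer id → simulated Yp/Yw

    def buffers_for(self, country: str, regime: str | None = None) -> list[SiteBuffer]:
        return [b for b in self.buffers
                if b.country == country and (regime is None or b.water_regime == regime)]


_ATTAINABLE_FRACTION = {"irrigated": 0.8, "rainfed_lowland": 0.7, "rainfed_upland": 0.7}

# regime mixes a country may declare (weights chosen to keep all three common)
_REGIME_PATTERNS = [
    ("irrigated", "rainfed_lowland", "rainfed_upland"),
    ("irrigated",),
    ("rainfed_lowland", "rainfed_upland"),
    ("irrigated", "rainfed_lowland"),
]
_REGIME_PATTERN_P = [0.4, 0.2, 0.2, 0.2]


def _country_weather_params(rng: np.random.Generator, seed: int,
                            years_start: int) -> WeatherGeneratorParams:
    return WeatherGeneratorParams(
        t_mean_c=float(rng.uniform(24.0, 29.0)),
        t_seasonal_amplitude_c=float(rng.uniform(1.5, 4.0)),
        diurnal_range_c=float(rng.uniform(7.0, 11.0)),
        monsoon_onset_doy=int(rng.integers(120, 181)),
        monsoon_length_days=int(rng.integers(100, 141)),
        p_wet_monsoon=float(rng.uniform(0.45, 0.65)),
        p_wet_dry_season=float(rng.uniform(0.02, 0.10)),
        wet_day_depth_mm=float(rng.uniform(8.0, 13.0)),
        srad_clear_mj=float(rng.uniform(19.0, 23.0)),
        start_year=years_start,
        seed=seed,
    )


def gen_site_network(
    n_countries: int,
    seed: int = 0,
    years: int = 6,
    start_year: int = 2000,
) -> SyntheticStudy:
    """Generate a multi-country study: buffers, weather, calendars, profiles.

    Each country declares a water-regime mix and gets 1–3 buffers per regime,
    each with its own weather realisation, a monsoon-aligned crop calendar,
    calibrated phenology, and a multi-year yield-potential simulation.  The
    actual farmer yield of every buffer is drawn uniformly between 35% and
    75% of its attainable yield, so exploitable gap fractions land in the
    25–65% band the gap analysis expects.  Deterministic in (args, seed).
    """
    if n_countries < 1:
        raise ParameterError("n_countries must be >= 1")
    root = np.random.SeedSequence(seed)
    country_seeds = root.spawn(n_countries)

    buffers: list[SiteBuffer] = []
    profiles: dict[str, CountryProfile] = {}
    weather: dict[str, pd.DataFrame] = {}
    phenology: dict[str, crop.PhenologyParams] = {}
    yp_series: dict[str, crop.YieldSeries] = {}

    for ci, cs in enumerate(country_seeds):
        rng = np.random.default_rng(cs)
        cname = f"C{ci:02d}"
        pattern = _REGIME_PATTERNS[rng.choice(len(_REGIME_PATTERNS), p=_REGIME_PATTERN_P)]

        country_buffers: list[SiteBuffer] = []
        for regime in pattern:
            n_buf = int(rng.integers(1, 4))
            for bi in range(n_buf):
                bid = f"{cname}-{regime[:3]}{bi}"
                wparams = _country_weather_params(
                    rng, seed=int(rng.integers(0, 2**31 - 1)), years_start=start_year)
                wx = gen_weather(wparams, years)

                sow = int((wparams.monsoon_onset_doy + rng.integers(5, 25)) % 360) or 1
                duration = int(rng.integers(110, 136))
                establishment = "transplanted" if rng.random() < 0.5 else "direct_seeded"
                cal = crop.CropCalendar(
                    sowing_doy=sow, duration_days=duration,
                    establishment=establishment,
                    transplanting_offset_days=(int(rng.integers(15, 26))
                                               if establishment == "transplanted" else 0),
                )
                phen = crop.calibrate_development_rates(wx, cal)
                series = crop.simulate_multi_year(wx, cal, regime, phenology=phen)
                yp_mean = float(series.yields.mean())
                attainable = _ATTAINABLE_FRACTION[regime] * yp_mean
                ya = attainable * float(rng.uniform(0.35, 0.75))

                buf = SiteBuffer(
                    id=bid, country=cname,
                    climate_zone=f"CZ{int(rng.integers(1, 4))}",
                    water_regime=regime,
                    area_ha=float(rng.lognormal(np.log(2.0e5), 0.6)),
                    calendar=cal, actual_yield_mgha=ya,
                )
                country_buffers.append(buf)
                weather[bid] = wx
                phenology[bid] = phen
                yp_series[bid] = series

        # symmetric overlaps between some same-regime buffer pairs
        for i in range(len(country_buffers)):
            for j in range(i + 1, len(country_buffers)):
                a, b = country_buffers[i], country_buffers[j]
                if a.water_regime == b.water_regime and rng.random() < 0.3:
                    f = float(rng.uniform(0.05, 0.35))
                    a.overlaps[b.id] = f
                    b.overlaps[a.id] = f

        profiles[cname] = _build_profile(cname, country_buffers, rng)
        buffers.extend(country_buffers)

    return SyntheticStudy(buffers=buffers, profiles=profiles, weather=weather,
                          phenology=phenology, yp_series=yp_series)


def _build_profile(cname: str, bufs: list[SiteBuffer],
                   rng: np.random.Generator) -> CountryProfile:
    """Roll buffers up to a national profile with a plausible trade balance."""
    coverage = rng.uniform(0.55, 0.85)  # buffers cover this share of national area
    area_by_regime: dict[str, float] = {}
    ya_by_regime: dict[str, float] = {}
    for regime in {b.water_regime for b in bufs}:
        rb = [b for b in bufs if b.water_regime == regime]
        tot = sum(b.area_ha for b in rb)
        area_by_regime[regime] = tot / coverage / 1e6  # ha → M ha
        ya_by_regime[regime] = sum(b.actual_yield_mgha * b.area_ha for b in rb) / tot

    production = sum(area_by_regime[r] * ya_by_regime[r] for r in area_by_regime)
    ssr = rng.uniform(0.35, 0.90)
    demand = production / ssr
    per_capita = rng.uniform(35.0, 65.0)
    population = demand * 1e9 / per_capita
    return CountryProfile(
        name=cname,
        production_mt=production,
        imports_mt=demand - production,
        exports_mt=0.0,
        stock_change_mt=0.0,
        population_now=population,
        population_2050=population * rng.uniform(1.7, 2.1),
        per_capita_now_kg=per_capita,
        per_capita_2050_kg=per_capita * rng.uniform(1.15, 1.35),
        milling_rate=float(rng.uniform(*MILLING_RATE_RANGE)),
        yield_trend_kgha_yr=float(rng.uniform(5.0, 35.0)),
        area_mha_by_regime=area_by_regime,
        actual_yield_mgha_by_regime=ya_by_regime,
    )
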