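"""Simplified daily rice season simulator.

Simulates yield potential (irrigated) and water-limited yield potential
(rainfed lowland / upland) one crop cycle at a time.  The model is a daily
radiation-use-efficiency (RUE) canopy model coupled to thermal-time phenology
in the ORYZA convention (development stage DVS: 0 emergence, 1 flowering,
2 maturity) and, for rainfed crops, a single-layer soil water bucket with a
bund, percolation capped at Ksat, and a groundwater capillary-rise term.

Fixed physiological settings follow standard rice-modelling practice:
base temperature for development 14 °C, lethal cold threshold 12 °C sustained
for 3 consecutive days, critical spikelet-sterility temperature 35.6 °C,
photosynthetically active fraction of sunlight 0.5, and a stem-reserve
fraction of 0.2 remobilised to grain.  All yields are paddy rice at 14%
grain moisture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationInfeasibleError, CycleIncompleteError, ParameterError

__all__ = [
    "CropCalendar",
    "PhenologyParams",
    "StressParams",
    "CanopyParams",
    "SoilProfile",
    "SoilWaterState",
    "WaterFluxes",
    "SeasonResult",
    "YieldSeries",
    "effective_temperature",
    "simulate_phenology",
    "calibrate_development_rates",
    "capillary_rise",
    "reference_et",
    "soil_water_step",
    "heat_sterility",
    "simulate_season",
    "simulate_multi_year",
    "REGIMES",
]

REGIMES = ("irrigated", "rainfed_lowland", "rainfed_upland")

#: dry-matter fraction of paddy grain at the 14% (140 g kg^-1) moisture standard
_DRY_MATTER_FRACTION = 0.86


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropCalendar:
    """Crop calendar for one cycle, expressed as day-of-year anchors.

    50% flowering is fixed at 30 days before maturity, so the calendar is
    fully determined by sowing day and total sowing→maturity duration.
    """

    sowing_doy: int
    duration_days: int
    establishment: str = "direct_seeded"  # or "transplanted"
    transplanting_offset_days: int = 0    # sowing → transplanting, transplanted only

    def __post_init__(self) -> None:
        if not 1 <= self.sowing_doy <= 366:
            raise ParameterError(f"sowing_doy out of range: {self.sowing_doy}")
        if self.duration_days <= 30:
            raise ParameterError("duration must exceed the 30-day grain-fill phase")
        if self.establishment not in ("direct_seeded", "transplanted"):
            raise ParameterError(f"unknown establishment: {self.establishment}")
        if self.establishment == "direct_seeded" and self.transplanting_offset_days:
            raise ParameterError("transplanting offset given for direct-seeded crop")

    @property
    def flowering_offset_days(self) -> int:
        """Days from sowing to 50% flowering (maturity − 30 d)."""
        return self.duration_days - 30


@dataclass(frozen=True)
class PhenologyParams:
    """Development rates ((°Cd)⁻¹) and the cardinal temperatures driving them.

    Stage structure (ORYZA convention): juvenile DVS 0→0.40 at rate ``dvrj``,
    photoperiod-sensitive DVS 0.40→0.65 at ``dvri``, panicle development
    DVS 0.65→1.0 at ``dvrp``, reproductive DVS 1→2 at ``dvrr``.  Photoperiod
    sensitivity is off: day length never modulates ``dvri``.
    """

    dvrj: float = 0.000773
    dvri: float = 0.000749
    dvrp: float = 0.000564
    dvrr: float = 0.001900
    t_base_c: float = 14.0
    t_opt_c: float = 30.0
    t_max_c: float = 42.0
    photoperiod_optimum_h: float = 10.0
    photoperiod_sensitive: bool = False

    def __post_init__(self) -> None:
        for name in ("dvrj", "dvri", "dvrp", "dvrr"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"development rate {name} must be > 0")
        if not self.t_base_c < self.t_opt_c < self.t_max_c:
            raise ParameterError("cardinal temperatures must be ordered base < opt < max")


@dataclass(frozen=True)
class StressParams:
    """Temperature-stress thresholds and fixed partitioning fractions."""

    t_lethal_c: float = 12.0
    lethal_run_days: int = 3
    t_sterility_c: float = 35.6
    sterility_slope_per_c: float = 0.10
    par_fraction: float = 0.5
    stem_reserve_fraction: float = 0.2


@dataclass(frozen=True)
class CanopyParams:
    """RUE canopy model settings.

    ``rue_g_mj`` is grams of above-ground dry matter per MJ of intercepted
    PAR; the prescribed leaf-area curve peaks at ``lai_max`` at flowering.
    """

    rue_g_mj: float = 2.2
    k_extinction: float = 0.5
    lai_max: float = 6.0
    harvest_index: float = 0.45
    stem_fraction: float = 0.4

    @property
    def harvest_index_ceiling(self) -> float:
        """Upper bound of grain:biomass including stem-reserve remobilisation."""
        return self.harvest_index + self.stem_fraction  # reserves ≤ stem biomass


@dataclass(frozen=True)
class SoilProfile:
    """Single-bucket soil description for the water balance.

    Volumetric water contents are m³ m⁻³; ``ksat_cm_d`` caps daily
    percolation.  Lowland profiles carry a 25 cm bund; upland has none and a
    groundwater table far below the root zone (1000 cm).
    """

    environment: str                 # "lowland" | "upland"
    bund_height_cm: float
    groundwater_depth_cm: float
    theta_init: float
    theta_sat: float
    theta_fc: float
    theta_wp: float
    ksat_cm_d: float
    rooting_depth_cm: float
    puddled: bool = False

    def __post_init__(self) -> None:
        if self.environment not in ("lowland", "upland"):
            raise ParameterError(f"unknown environment: {self.environment}")
        if self.theta_init > self.theta_sat + 0.02:
            raise ParameterError("theta_init exceeds theta_sat beyond tolerance")
        if not 0 < self.theta_wp < self.theta_fc < self.theta_sat < 1:
            raise ParameterError("require 0 < wp < fc < sat < 1")

    @classmethod
    def rainfed_lowland(cls, groundwater_depth_cm: float = 40.0) -> "SoilProfile":
        """Non-puddled clayey loam, 25 cm bund; shallow (40) or deep (100 cm) water table."""
        return cls(
            environment="lowland", bund_height_cm=25.0,
            groundwater_depth_cm=groundwater_depth_cm,
            theta_init=0.57, theta_sat=0.56, theta_fc=0.49, theta_wp=0.25,
            ksat_cm_d=10.79, rooting_depth_cm=50.0,
        )

    @classmethod
    def rainfed_upland(cls) -> "SoilProfile":
        """Non-puddled sandy loam, no bund, groundwater at 1000 cm."""
        return cls(
            environment="upland", bund_height_cm=0.0, groundwater_depth_cm=1000.0,
            theta_init=0.39, theta_sat=0.38, theta_fc=0.31, theta_wp=0.10,
            ksat_cm_d=99.77, rooting_depth_cm=30.0,
        )

    @property
    def saturation_mm(self) -> float:
        return self.theta_sat * self.rooting_depth_cm * 10.0

    @property
    def field_capacity_mm(self) -> float:
        return self.theta_fc * self.rooting_depth_cm * 10.0

    @property
    def wilting_mm(self) -> float:
        return self.theta_wp * self.rooting_depth_cm * 10.0

    def initial_state(self) -> "SoilWaterState":
        storage = min(self.theta_init, self.theta_sat) * self.rooting_depth_cm * 10.0
        return SoilWaterState(storage_mm=storage, pond_mm=0.0)


@dataclass
class SoilWaterState:
    storage_mm: float
    pond_mm: float

    @property
    def total_mm(self) -> float:
        return self.storage_mm + self.pond_mm


@dataclass(frozen=True)
class WaterFluxes:
    """Daily water-balance ledger (all mm d⁻¹)."""

    rain: float
    irrigation: float
    capillary: float
    transpiration: float
    evaporation: float
    percolation: float
    runoff: float

    @property
    def net_in(self) -> float:
        return (self.rain + self.irrigation + self.capillary
                - self.transpiration - self.evaporation
                - self.percolation - self.runoff)


@dataclass(frozen=True)
class SeasonResult:
    """Outcome of one simulated crop cycle.

    ``yield_mgha`` is paddy at 14% moisture; ``biomass_mgha`` is above-ground
    dry matter.  ``water_stress`` is 1 − (season transpiration / demand).
    """

    yield_mgha: float
    biomass_mgha: float
    sterility: float
    water_stress: float
    sowing_date: pd.Timestamp
    flowering_date: pd.Timestamp | None
    maturity_date: pd.Timestamp | None
    died: bool


@dataclass
class YieldSeries:
    """Per-year simulated yields for one site × regime.

    For rainfed lowland, ``components`` holds the shallow (40 cm) and deep
    (100 cm) groundwater scenarios and ``yields`` their 50:50 blend.
    """

    regime: str
    years: np.ndarray
    yields: np.ndarray
    components: dict[str, np.ndarray] = field(default_factory=dict)
    results: dict[str, list[SeasonResult]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"year": self.years, "yield_mgha": self.yields})
        for name, vals in self.components.items():
            out[f"yield_{name}_mgha"] = vals
        out.insert(0, "regime", self.regime)
        return out


# ---------------------------------------------------------------------------
# thermal time and phenology
# ---------------------------------------------------------------------------

def effective_temperature(tmin, tmax, params: PhenologyParams | None = None):
    """Daily thermal-time increment (°Cd) from min/max air temperature.

    Piecewise-linear response of the daily mean: zero at or below the 14 °C
    base, rising 1 °Cd per °C up to the 30 °C optimum, then falling linearly
    to zero at 42 °C.
    """
    p = params or PhenologyParams()
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ParameterError("tmax < tmin")
    tm = 0.5 * (tmin + tmax)
    span = p.t_opt_c - p.t_base_c
    rising = np.clip(tm - p.t_base_c, 0.0, None)
    falling = span * np.clip(p.t_max_c - tm, 0.0, None) / (p.t_max_c - p.t_opt_c)
    teff = np.where(tm <= p.t_opt_c, rising, falling)
    return teff if teff.ndim else float(teff)


def _stage_targets(p: PhenologyParams) -> tuple[float, float, float, float]:
    """Cumulative °Cd needed to finish each stage boundary (DVS .4, .65, 1, 2)."""
    s1 = 0.40 / p.dvrj
    s2 = s1 + 0.25 / p.dvri
    s3 = s2 + 0.35 / p.dvrp
    s4 = s3 + 1.00 / p.dvrr
    return s1, s2, s3, s4


def _dvs_from_cumteff(cum: np.ndarray, p: PhenologyParams) -> np.ndarray:
    s1, s2, s3, s4 = _stage_targets(p)
    return np.select(
        [cum <= s1, cum <= s2, cum <= s3, cum <= s4],
        [cum * p.dvrj,
         0.40 + (cum - s1) * p.dvri,
         0.65 + (cum - s2) * p.dvrp,
         1.00 + (cum - s3) * p.dvrr],
        default=2.0,
    )


def simulate_phenology(
    weather: pd.DataFrame,
    start_idx: int,
    params: PhenologyParams | None = None,
) -> tuple[int, int, np.ndarray]:
    """Integrate DVS from sowing; return (days to flowering, days to maturity, daily DVS).

    Day counts are 1-based (the sowing day is day 1).  Raises
    :class:`CycleIncompleteError` if the weather series ends before DVS
    reaches 2, including the degenerate case of temperatures pinned at the
    base where DVS never advances.
    """
    p = params or PhenologyParams()
    tmin = weather["tmin"].to_numpy()[start_idx:]
    tmax = weather["tmax"].to_numpy()[start_idx:]
    if tmin.size == 0:
        raise CycleIncompleteError("no weather after sowing date")
    teff = effective_temperature(tmin, tmax, p)
    cum = np.cumsum(teff)
    _, _, s3, s4 = _stage_targets(p)
    i_fl = int(np.searchsorted(cum, s3))
    i_mat = int(np.searchsorted(cum, s4))
    if i_mat >= cum.size:
        raise CycleIncompleteError(
            "weather series exhausted before maturity (DVS < 2)")
    dvs = _dvs_from_cumteff(cum[: i_mat + 1], p)
    return i_fl + 1, i_mat + 1, dvs


def _mean_duration(cum_by_year: list[np.ndarray], target_cd: float) -> float:
    """Mean days (1-based) to accumulate ``target_cd`` °Cd; inf if any year cannot."""
    days = []
    for cum in cum_by_year:
        i = int(np.searchsorted(cum, target_cd))
        if i >= cum.size:
            return math.inf
        days.append(i + 1)
    return float(np.mean(days))


def calibrate_development_rates(
    weather: pd.DataFrame,
    calendar: CropCalendar,
    base: PhenologyParams | None = None,
    tol_days: float = 1.0,
    max_multiplier: float = 200.0,
    max_iter: int = 80,
) -> PhenologyParams:
    """Calibrate development rates so simulated phenology matches the calendar.

    Mirrors the DRATE approach: a scalar multiplier on the pre-flowering
    rates (DVRJ, DVRI, DVRP — relative proportions preserved) is solved by
    bisection so the mean simulated sowing→flowering duration across all
    years matches the calendar within ``tol_days``; DVRR is then solved the
    same way for the flowering→maturity (30 d) phase.  DVRI is calibrated but
    never photoperiod-modulated (sensitivity off).
    """
    p = base or PhenologyParams()
    dates = pd.DatetimeIndex(weather["date"])
    tmin = weather["tmin"].to_numpy()
    tmax = weather["tmax"].to_numpy()
    teff_all = effective_temperature(tmin, tmax, p)

    doy = dates.dayofyear.to_numpy()
    years = dates.year.to_numpy()
    starts = np.flatnonzero((doy == calendar.sowing_doy))
    # keep sowings with enough trailing weather for a generous cycle
    starts = [s for s in starts if len(dates) - s >= calendar.duration_days + 60]
    if not starts:
        raise ParameterError("calendar sowing dates not covered by weather series")

    cum_by_year = [np.cumsum(teff_all[s:]) for s in starts]
    target_fl = float(calendar.flowering_offset_days)
    target_mat = float(calendar.duration_days)

    s1, s2, s3, _ = _stage_targets(p)   # °Cd to flowering at multiplier 1

    def solve(target_days: float, duration_at: callable) -> float:
        lo, hi = 1.0 / max_multiplier, max_multiplier
        d_lo, d_hi = duration_at(lo), duration_at(hi)
        if d_hi > target_days:
            raise CalibrationInfeasibleError(
                f"target {target_days:.0f} d unreachable even at max rate")
        if d_lo < target_days:
            raise CalibrationInfeasibleError(
                f"target {target_days:.0f} d shorter than slowest achievable")
        for _ in range(max_iter):
            mid = math.sqrt(lo * hi)
            d = duration_at(mid)
            if abs(d - target_days) <= tol_days:
                return mid
            if d > target_days:
                lo = mid
            else:
                hi = mid
        return math.sqrt(lo * hi)

    m_pre = solve(target_fl, lambda m: _mean_duration(cum_by_year, s3 / m))

    # flowering day per year is now fixed; solve DVRR for the last 30 days
    fl_idx = [int(np.searchsorted(cum, s3 / m_pre)) for cum in cum_by_year]

    def mat_duration(mr: float) -> float:
        need = 1.0 / (p.dvrr * mr)
        days = []
        for cum, i_fl in zip(cum_by_year, fl_idx):
            i = int(np.searchsorted(cum, cum[i_fl] + need))
            if i >= cum.size:
                return math.inf
            days.append(i + 1)
        return float(np.mean(days))

    m_rep = solve(target_mat, mat_duration)

    return replace(p, dvrj=p.dvrj * m_pre, dvri=p.dvri * m_pre,
                   dvrp=p.dvrp * m_pre, dvrr=p.dvrr * m_rep)


# ---------------------------------------------------------------------------
# soil water balance
# ---------------------------------------------------------------------------

def capillary_rise(groundwater_depth_cm: float) -> float:
    """Capillary-rise supply (mm d⁻¹), linear in water-table depth.

    5 mm d⁻¹ at 40 cm, 1 mm d⁻¹ at 100 cm, zero at or below 200 cm; clamped
    to 5 mm d⁻¹ for tables shallower than 40 cm.
    """
    return float(np.interp(groundwater_depth_cm, [40.0, 100.0, 200.0],
                           [5.0, 1.0, 0.0]))


def reference_et(srad, tmin, tmax):
    """Reference evapotranspiration (mm d⁻¹), Hargreaves-type radiation form.

    ET0 = 0.0135 · (Tmean + 17.8) · Rs/λ with Rs the measured solar radiation
    (MJ m⁻² d⁻¹) and λ = 2.45 MJ kg⁻¹; used because the weather series carries
    no humidity or wind.
    """
    tm = 0.5 * (np.asarray(tmin, float) + np.asarray(tmax, float))
    et0 = 0.0135 * (tm + 17.8) * np.asarray(srad, float) / 2.45
    return np.clip(et0, 0.0, None)


def soil_water_step(
    state: SoilWaterState,
    rain_mm: float,
    irrigation_mm: float,
    et_demand_mm: float,
    capillary_mm: float,
    soil: SoilProfile,
    evaporation_mm: float = 0.0,
) -> tuple[SoilWaterState, float, WaterFluxes]:
    """Advance the bucket one day; return (new state, transpiration ratio, fluxes).

    Order of operations: inflows infiltrate to saturation, excess ponds up to
    the bund (surplus runs off); the crop then transpires
    ``ratio = min(1, available / demand)`` of its demand, pond water first;
    potential soil evaporation ``evaporation_mm`` is then taken from pond and
    soil down to wilting; finally free water (pond + storage above field
    capacity) percolates at up to Ksat.  The daily mass balance closes
    exactly by construction.
    """
    for name, v in (("rain", rain_mm), ("irrigation", irrigation_mm),
                    ("et_demand", et_demand_mm), ("capillary", capillary_mm),
                    ("evaporation", evaporation_mm)):
        if v < 0:
            raise ParameterError(f"negative flux: {name}={v}")

    storage, pond = state.storage_mm, state.pond_mm
    sat, fc, wp = soil.saturation_mm, soil.field_capacity_mm, soil.wilting_mm
    bund = soil.bund_height_cm * 10.0

    water = pond + rain_mm + irrigation_mm + capillary_mm
    infil = min(water, max(0.0, sat - storage))
    storage += infil
    water -= infil
    pond = min(water, bund)
    runoff = water - pond

    available = pond + max(0.0, storage - wp)
    if et_demand_mm <= 0.0:
        ratio = 1.0
    else:
        ratio = min(1.0, available / et_demand_mm)
    transp = ratio * et_demand_mm
    from_pond = min(pond, transp)
    pond -= from_pond
    storage -= transp - from_pond

    evap = min(evaporation_mm, pond + max(0.0, storage - wp))
    e_pond = min(pond, evap)
    pond -= e_pond
    storage -= evap - e_pond

    free = pond + max(0.0, storage - fc)
    perc = min(soil.ksat_cm_d * 10.0, free)
    p_pond = min(pond, perc)
    pond -= p_pond
    storage -= perc - p_pond

    new = SoilWaterState(storage_mm=storage, pond_mm=pond)
    fluxes = WaterFluxes(rain=rain_mm, irrigation=irrigation_mm,
                         capillary=capillary_mm, transpiration=transp,
                         evaporation=evap, percolation=perc, runoff=runoff)
    return new, ratio, fluxes


# ---------------------------------------------------------------------------
# stress and season integration
# ---------------------------------------------------------------------------

def heat_sterility(tmax_window, stress: StressParams | None = None) -> float:
    """Spikelet sterility fraction from daily maxima around flowering.

    Each day contributes ``slope × (tmax − 35.6)`` clamped to [0, 1]; the
    window (days with DVS in [0.96, 1.2]) average is returned, clamped again.
    An empty window (e.g. crop died earlier) yields 0.
    """
    s = stress or StressParams()
    t = np.asarray(tmax_window, dtype=float)
    if t.size == 0:
        return 0.0
    per_day = np.clip(s.sterility_slope_per_c * (t - s.t_sterility_c), 0.0, 1.0)
    return float(np.clip(per_day.mean(), 0.0, 1.0))


def _lai_curve(dvs: np.ndarray, lai_max: float) -> np.ndarray:
    """Prescribed leaf-area index: sin² rise to ``lai_max`` at flowering, then
    linear senescence to 60% of the peak at maturity."""
    rising = lai_max * np.sin(0.5 * np.pi * np.clip(dvs, 0.0, 1.0)) ** 2
    falling = lai_max * (1.0 - 0.4 * np.clip(dvs - 1.0, 0.0, 1.0))
    return np.where(dvs <= 1.0, rising, falling)


_STERILITY_DVS_WINDOW = (0.96, 1.20)


def _season_start_index(weather: pd.DataFrame, year: int, calendar: CropCalendar) -> int:
    dates = pd.DatetimeIndex(weather["date"])
    mask = (dates.year == year) & (dates.dayofyear == calendar.sowing_doy)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise CycleIncompleteError(f"sowing day {calendar.sowing_doy} of {year} "
                                   "not present in weather series")
    return int(idx[0])


def simulate_season(
    weather: pd.DataFrame,
    year: int,
    calendar: CropCalendar,
    regime: str,
    phenology: PhenologyParams | None = None,
    soil: SoilProfile | None = None,
    stress: StressParams | None = None,
    canopy: CanopyParams | None = None,
) -> SeasonResult:
    """Simulate one crop cycle starting at the calendar's sowing day of ``year``.

    Irrigated crops are never water-limited (transpiration ratio pinned at 1);
    rainfed crops run the soil bucket, lowland with the profile's groundwater
    capillary supply.  Growth stops with zero yield if the daily mean
    temperature stays below 12 °C for 3 consecutive days.
    """
    if regime not in REGIMES:
        raise ParameterError(f"unknown water regime: {regime}")
    p = phenology or PhenologyParams()
    s = stress or StressParams()
    c = canopy or CanopyParams()
    if regime != "irrigated":
        if soil is None:
            soil = (SoilProfile.rainfed_lowland() if regime == "rainfed_lowland"
                    else SoilProfile.rainfed_upland())

    start = _season_start_index(weather, year, calendar)
    i_fl, i_mat, dvs = simulate_phenology(weather, start, p)

    sl = slice(start, start + i_mat)
    srad = weather["srad"].to_numpy()[sl]
    tmin = weather["tmin"].to_numpy()[sl]
    tmax = weather["tmax"].to_numpy()[sl]
    precip = weather["precip"].to_numpy()[sl]
    dates = pd.DatetimeIndex(weather["date"])[sl]
    tmean = 0.5 * (tmin + tmax)

    lai = _lai_curve(dvs, c.lai_max)
    fint = 1.0 - np.exp(-c.k_extinction * lai)
    et0 = reference_et(srad, tmin, tmax)
    demand = et0 * np.clip(1.35 * fint, 0.05, 1.25)  # transpiration demand, Kc≈1.25 at full canopy
    evap_pot = 0.85 * et0 * (1.0 - fint)             # bare-soil evaporation

    bio_start = (calendar.transplanting_offset_days
                 if calendar.establishment == "transplanted" else 0)

    state = soil.initial_state() if soil is not None else None
    cap = capillary_rise(soil.groundwater_depth_cm) if soil is not None else 0.0

    biomass_g = 0.0
    supply_sum = 0.0
    demand_sum = 0.0
    cold_run = 0
    died = False
    n_days = i_mat
    for i in range(i_mat):
        if tmean[i] < s.t_lethal_c:
            cold_run += 1
            if cold_run >= s.lethal_run_days:
                died = True
                n_days = i + 1
                break
        else:
            cold_run = 0
        if regime == "irrigated":
            ratio = 1.0
        else:
            state, ratio, _ = soil_water_step(
                state, float(precip[i]), 0.0, float(demand[i]), cap, soil,
                evaporation_mm=float(evap_pot[i]))
        supply_sum += ratio * demand[i]
        demand_sum += demand[i]
        if i >= bio_start:
            biomass_g += c.rue_g_mj * s.par_fraction * srad[i] * fint[i] * ratio

    water_stress = 0.0 if demand_sum <= 0 else 1.0 - supply_sum / demand_sum

    if died:
        sterility = 0.0
        grain_g = 0.0
        fl_date = dates[i_fl - 1] if i_fl <= n_days else None
        mat_date = None
    else:
        lo, hi = _STERILITY_DVS_WINDOW
        window = tmax[(dvs >= lo) & (dvs <= hi)]
        sterility = heat_sterility(window, s)
        grain_g = (c.harvest_index * biomass_g * (1.0 - sterility)
                   + s.stem_reserve_fraction * c.stem_fraction * biomass_g)
        fl_date = dates[i_fl - 1]
        mat_date = dates[i_mat - 1]

    # g DM m^-2 → Mg ha^-1 (×0.01); grain to paddy at 14% moisture
    yield_mgha = 0.0 if died else grain_g * 0.01 / _DRY_MATTER_FRACTION
    return SeasonResult(
        yield_mgha=yield_mgha,
        biomass_mgha=biomass_g * 0.01,
        sterility=sterility,
        water_stress=float(np.clip(water_stress, 0.0, 1.0)),
        sowing_date=dates[0],
        flowering_date=fl_date,
        maturity_date=mat_date,
        died=died,
    )


_LOWLAND_GW_SCENARIOS = (40.0, 100.0)


def simulate_multi_year(
    weather: pd.DataFrame,
    calendar: CropCalendar,
    regime: str,
    phenology: PhenologyParams | None = None,
    soil: SoilProfile | None = None,
    stress: StressParams | None = None,
    canopy: CanopyParams | None = None,
) -> YieldSeries:
    """One season per covered year; rainfed lowland blends groundwater scenarios.

    Rainfed lowland runs both the shallow (40 cm) and deep (100 cm) water
    table and reports their 50:50 blend as ``yields`` with the individual
    scenarios kept in ``components`` — the lowland area is assumed split
    evenly between the two environments.
    """
    years_all = sorted(pd.DatetimeIndex(weather["date"]).year.unique())
    kwargs = dict(phenology=phenology, stress=stress, canopy=canopy)

    def run(soil_: SoilProfile | None) -> tuple[list[int], list[SeasonResult]]:
        yrs, out = [], []
        for y in years_all:
            try:
                out.append(simulate_season(weather, y, calendar, regime,
                                           soil=soil_, **kwargs))
                yrs.append(y)
            except CycleIncompleteError:
                continue
        if len(yrs) < 2:
            raise CycleIncompleteError("fewer than 2 complete seasons in weather series")
        return yrs, out

    if regime == "rainfed_lowland" and soil is None:
        comp: dict[str, np.ndarray] = {}
        results: dict[str, list[SeasonResult]] = {}
        for gw in _LOWLAND_GW_SCENARIOS:
            yrs, res = run(SoilProfile.rainfed_lowland(groundwater_depth_cm=gw))
            key = f"gw{int(gw)}"
            comp[key] = np.array([r.yield_mgha for r in res])
            results[key] = res
        blend = 0.5 * (comp["gw40"] + comp["gw100"])
        return YieldSeries(regime=regime, years=np.array(yrs), yields=blend,
                           components=comp, results=results)

    yrs, res = run(soil)
    vals = np.array([r.yield_mgha for r in res])
    return YieldSeries(regime=regime, years=np.array(yrs), yields=vals,
                       components={}, results={"default": res})
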