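"""Country-level rice demand accounting and 2050 projection.

All quantities are paddy rice at 14% moisture.  Baseline demand follows the
supply identity demand = production + imports − exports − stock change;
future demand is population × per-capita demand; yields are extrapolated
along the historical trend, capped at the attainable yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import AccountingError, ParameterError
from .synthetic import MILLING_RATE_RANGE, CountryProfile

__all__ = [
    "DemandRecord",
    "baseline_demand",
    "milled_to_paddy",
    "project_demand",
    "extrapolate_yield",
    "self_sufficiency_ratio",
    "rice_deficit",
    "demand_record",
]


@dataclass(frozen=True)
class DemandRecord:
    """Baseline and 2050 demand, SSR, and deficit for one country (Mt paddy yr⁻¹)."""

    country: str
    demand_now_mt: float
    demand_2050_mt: float
    ssr_now: float
    ssr_2050: float
    deficit_2050_mt: float


def baseline_demand(production_mt: float, imports_mt: float, exports_mt: float,
                    stock_change_mt: float = 0.0, stock_sign: float = -1.0) -> float:
    """Domestic demand from the national supply identity (Mt paddy).

    demand = production + imports − exports + stock_sign·stock_change.
    The default sign treats positive stock change as stock build-up (grain
    withheld from consumption, hence subtracted); pass ``stock_sign=1`` for
    the draw-down convention.
    """
    for name, v in (("production", production_mt), ("imports", imports_mt),
                    ("exports", exports_mt)):
        if v < 0:
            raise ParameterError(f"{name} must be >= 0")
    demand = production_mt + imports_mt - exports_mt + stock_sign * stock_change_mt
    if demand < 0:
        raise AccountingError(f"negative demand ({demand:.3f} Mt) from supply identity")
    return demand


def milled_to_paddy(milled_kg_per_capita: float, milling_rate: float) -> float:
    """Convert per-capita milled rice to paddy basis by dividing by the milling rate."""
    if milling_rate <= 0 or milling_rate > 1:
        raise ParameterError("milling rate must be in (0, 1]")
    lo, hi = MILLING_RATE_RANGE
    if not lo <= milling_rate <= hi:
        warnings.warn(f"milling rate {milling_rate:.3f} outside the typical "
                      f"[{lo}, {hi}] range", stacklevel=2)
    return milled_kg_per_capita / milling_rate


def project_demand(population: float, per_capita_kg: float) -> float:
    """Total demand (Mt paddy) = population × per-capita demand (kg, paddy basis)."""
    if population < 0 or per_capita_kg < 0:
        raise ParameterError("population and per-capita demand must be >= 0")
    return population * per_capita_kg / 1e9


def extrapolate_yield(y0_mgha: float, trend_kgha_yr: float, years: float,
                      cap_mgha: float) -> float:
    """Continue the historical yield trend, capped at the attainable yield.

    If the cap already sits below the current yield (gap closed), the current
    yield is returned with a warning.
    """
    if years < 0:
        raise ParameterError("years must be >= 0")
    if cap_mgha < y0_mgha:
        warnings.warn("attainable yield below current yield (gap already closed); "
                      "holding yield constant", stacklevel=2)
        return y0_mgha
    return min(y0_mgha + trend_kgha_yr * years / 1000.0, cap_mgha)


def self_sufficiency_ratio(production_mt: float, demand_mt: float) -> float:
    """SSR = production / demand."""
    if demand_mt <= 0:
        raise ParameterError("demand must be > 0")
    return production_mt / demand_mt


def rice_deficit(demand_mt: float, production_mt: float) -> float:
    """Deficit = demand − production (negative ⇒ exportable surplus)."""
    return demand_mt - production_mt


def demand_record(profile: CountryProfile,
                  attainable_mgha_by_regime: dict[str, float],
                  horizon_years: float = 30.0) -> DemandRecord:
    """Full per-country accounting: baseline and 2050 demand, SSR, deficit.

    2050 production assumes current harvested area with the farmer yield of
    each regime extrapolated along the historical trend, capped at that
    regime's attainable yield.
    """
    demand_now = baseline_demand(profile.production_mt, profile.imports_mt,
                                 profile.exports_mt, profile.stock_change_mt)
    demand_2050 = project_demand(profile.population_2050, profile.per_capita_2050_kg)
    production_2050 = 0.0
    for regime, area in profile.area_mha_by_regime.items():
        y0 = profile.actual_yield_mgha_by_regime[regime]
        cap = attainable_mgha_by_regime.get(regime, float("inf"))
        y = extrapolate_yield(y0, profile.yield_trend_kgha_yr, horizon_years, cap)
        production_2050 += area * y
    return DemandRecord(
        country=profile.name,
        demand_now_mt=demand_now,
        demand_2050_mt=demand_2050,
        ssr_now=self_sufficiency_ratio(profile.production_mt, demand_now),
        ssr_2050=self_sufficiency_ratio(production_2050, demand_2050),
        deficit_2050_mt=rice_deficit(demand_2050, production_2050),
    )
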