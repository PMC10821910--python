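"""2050 intensification × area-expansion scenario grid for continental rice supply.

Each scenario cell combines a closure fraction f of the current exploitable
yield gap with an annual harvested-area expansion rate over a 30-year
horizon.  Countries are pooled continentally (regional trade offsets
country-level deficits), continental demand carries a 1.05 multiplier for
minor consumers outside the study set, and net imports are costed at the
US$289 Mg⁻¹ paddy market price.  A climate-sensitivity mode scales
attainable yields and the expansion rate down by 5–10%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd
from scipy.optimize import brentq

from .errors import ParameterError

__all__ = [
    "ScenarioSpec",
    "CountryScenarioInput",
    "RestOfContinent",
    "ScenarioResult",
    "intensified_yield",
    "required_gain_rate",
    "expanded_area",
    "country_production",
    "continental_rollup",
    "net_import_and_cost",
    "land_equivalent",
    "run_scenario_grid",
    "climate_sensitivity",
    "solve_closure_fraction",
    "EXPANSION_RATES_MHA_YR",
]

#: slower / historical / faster expansion rates (M ha yr⁻¹): 0.4 ± 50%
EXPANSION_RATES_MHA_YR = (0.2, 0.4, 0.6)


@dataclass(frozen=True)
class ScenarioSpec:
    """Fixed scenario settings shared across grid cells."""

    horizon_years: float = 30.0
    price_usd_per_mg: float = 289.0
    demand_multiplier: float = 1.05
    yp_delta: float = 0.0      # relative change in attainable yield (≤ 0)
    area_delta: float = 0.0    # relative change in expansion rate (≤ 0)

    def __post_init__(self) -> None:
        if self.price_usd_per_mg <= 0:
            raise ParameterError("price must be > 0")
        if not -0.10 - 1e-9 <= self.yp_delta <= 0 or not -0.10 - 1e-9 <= self.area_delta <= 0:
            raise ParameterError("climate deltas must lie in [-0.10, 0]")


@dataclass(frozen=True)
class CountryScenarioInput:
    """Per-country state feeding the scenario grid.

    Areas in M ha, yields in Mg ha⁻¹, demand in Mt paddy yr⁻¹.  Expansion is
    allocated pro-rata to current regime shares (the irrigated fraction and
    cropping intensity are held fixed).
    """

    name: str
    area_mha: dict[str, float]
    ya_mgha: dict[str, float]
    attainable_mgha: dict[str, float]
    demand_2050_mt: float

    def __post_init__(self) -> None:
        if set(self.area_mha) != set(self.ya_mgha) or set(self.area_mha) != set(self.attainable_mgha):
            raise ParameterError(f"{self.name}: regime sets do not match across fields")

    @property
    def total_area_mha(self) -> float:
        return sum(self.area_mha.values())

    @property
    def baseline_production_mt(self) -> float:
        return sum(self.area_mha[r] * self.ya_mgha[r] for r in self.area_mha)


@dataclass(frozen=True)
class RestOfContinent:
    """Producing countries outside the study set.

    Their baseline production is scaled by the study-average relative yield
    increase implied by gap closure (the study-average yield gap is assumed
    to apply to them); their demand is covered by the continental demand
    multiplier.
    """

    baseline_production_mt: float


@dataclass(frozen=True)
class ScenarioResult:
    """Continental outcome of one (closure fraction, expansion rate) cell."""

    closure_fraction: float
    expansion_rate_mha_yr: float
    production_mt: float
    demand_mt: float
    ssr: float
    net_import_mt: float
    net_export_mt: float
    import_cost_usd_b: float
    added_area_mha: float


def intensified_yield(ya_mgha: float, attainable_mgha: float, f: float) -> float:
    """Yield after closing fraction ``f`` of the exploitable gap.

    Headroom is floored at zero: where farmers already exceed the attainable
    yield, intensification neither adds nor removes production.
    """
    if not 0.0 <= f <= 1.0:
        raise ParameterError("closure fraction must lie in [0, 1]")
    return ya_mgha + f * max(0.0, attainable_mgha - ya_mgha)


def required_gain_rate(ya_mgha: float, attainable_mgha: float, f: float,
                       horizon_years: float) -> float:
    """Annual yield-gain rate (kg ha⁻¹ yr⁻¹) needed to close fraction ``f``
    of the gap over the horizon."""
    if horizon_years <= 0:
        raise ParameterError("horizon must be > 0")
    return 1000.0 * f * max(0.0, attainable_mgha - ya_mgha) / horizon_years


def expanded_area(area0_mha: float, rate_mha_yr: float, years: float) -> float:
    """Harvested area after linear expansion: area0 + rate × years (M ha)."""
    if rate_mha_yr < 0 or years < 0:
        raise ParameterError("rate and years must be >= 0")
    return area0_mha + rate_mha_yr * years


def country_production(areas_mha: dict[str, float],
                       yields_mgha: dict[str, float]) -> float:
    """Production (Mt) = Σ regime area × regime yield."""
    if set(areas_mha) != set(yields_mgha):
        raise ParameterError("regime sets of areas and yields do not match")
    return sum(areas_mha[r] * yields_mgha[r] for r in areas_mha)


def net_import_and_cost(demand_mt: float, production_mt: float,
                        price_usd_per_mg: float = 289.0) -> tuple[float, float]:
    """Net import (Mt) after continental pooling and its cost (US$ billion)."""
    if price_usd_per_mg <= 0:
        raise ParameterError("price must be > 0")
    net_import = max(0.0, demand_mt - production_mt)
    return net_import, net_import * price_usd_per_mg / 1000.0


def land_equivalent(deficit_mt: float, yield_mgha: float) -> float:
    """Area (M ha) needed to grow ``deficit_mt`` at the given yield."""
    if yield_mgha <= 0:
        raise ParameterError("yield must be > 0")
    return deficit_mt / yield_mgha


def continental_rollup(
    countries: list[CountryScenarioInput],
    f: float,
    rate_mha_yr: float,
    spec: ScenarioSpec | None = None,
    rest: RestOfContinent | None = None,
) -> ScenarioResult:
    """Pool one scenario cell continentally.

    Total expansion (rate × horizon, scaled by any area delta) is allocated
    across countries proportionally to current rice area and within countries
    pro-rata across regimes; every regime's yield moves to
    ``intensified_yield`` with attainable yields scaled by any climate delta.
    Continental demand is the summed country demand times the demand
    multiplier.  Rest-of-continent production scales with the study-average
    relative yield increase.
    """
    spec = spec or ScenarioSpec()
    if not countries:
        raise ParameterError("no study countries supplied")
    eff_rate = rate_mha_yr * (1.0 + spec.area_delta)
    added_total = eff_rate * spec.horizon_years
    study_area = sum(c.total_area_mha for c in countries)
    if study_area <= 0:
        raise ParameterError("total study area must be > 0")

    production = 0.0
    for c in countries:
        growth = 1.0 + (added_total / study_area if study_area else 0.0)
        areas = {r: a * growth for r, a in c.area_mha.items()}
        yields = {r: intensified_yield(c.ya_mgha[r],
                                       c.attainable_mgha[r] * (1.0 + spec.yp_delta), f)
                  for r in c.area_mha}
        production += country_production(areas, yields)

    if rest is not None:
        base = sum(c.baseline_production_mt for c in countries)
        intens = sum(country_production(
            c.area_mha,
            {r: intensified_yield(c.ya_mgha[r],
                                  c.attainable_mgha[r] * (1.0 + spec.yp_delta), f)
             for r in c.area_mha}) for c in countries)
        factor = intens / base if base > 0 else 1.0
        production += rest.baseline_production_mt * factor

    demand = sum(c.demand_2050_mt for c in countries) * spec.demand_multiplier
    net_import, cost = net_import_and_cost(demand, production, spec.price_usd_per_mg)
    net_export = max(0.0, production - demand)
    return ScenarioResult(
        closure_fraction=f,
        expansion_rate_mha_yr=rate_mha_yr,
        production_mt=production,
        demand_mt=demand,
        ssr=production / demand,
        net_import_mt=net_import,
        net_export_mt=net_export,
        import_cost_usd_b=cost,
        added_area_mha=added_total,
    )


def run_scenario_grid(
    countries: list[CountryScenarioInput],
    f_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    rates_mha_yr=EXPANSION_RATES_MHA_YR,
    spec: ScenarioSpec | None = None,
    rest: RestOfContinent | None = None,
) -> pd.DataFrame:
    """One :class:`ScenarioResult` per (closure fraction, expansion rate) cell."""
    spec = spec or ScenarioSpec()
    rows = [continental_rollup(countries, f, rate, spec, rest).__dict__
            for f in f_values for rate in rates_mha_yr]
    return pd.DataFrame(rows)


def climate_sensitivity(
    countries: list[CountryScenarioInput],
    yp_delta: float,
    area_delta: float,
    f_values=(0.0, 0.25, 0.5, 0.75, 1.0),
    rates_mha_yr=EXPANSION_RATES_MHA_YR,
    spec: ScenarioSpec | None = None,
    rest: RestOfContinent | None = None,
) -> pd.DataFrame:
    """Recompute the grid with attainable yields and expansion rate scaled down.

    ``yp_delta`` and ``area_delta`` are relative reductions in [−0.10, 0]
    applied before gap closure and to the expansion rate respectively.
    """
    spec = replace(spec or ScenarioSpec(), yp_delta=yp_delta, area_delta=area_delta)
    out = run_scenario_grid(countries, f_values, rates_mha_yr, spec, rest)
    out["yp_delta"] = yp_delta
    out["area_delta"] = area_delta
    return out


def solve_closure_fraction(
    countries: list[CountryScenarioInput],
    rate_mha_yr: float,
    spec: ScenarioSpec | None = None,
    rest: RestOfContinent | None = None,
) -> float | None:
    """Smallest closure fraction achieving self-sufficiency at the given
    expansion rate, or None if even full closure leaves a deficit.

    Production is monotone (piecewise-linear) in f, so the root of
    production(f) − demand is found by bracketing + Brent's method.
    """
    spec = spec or ScenarioSpec()

    def surplus(f: float) -> float:
        r = continental_rollup(countries, f, rate_mha_yr, spec, rest)
        return r.production_mt - r.demand_mt

    hi = surplus(1.0)
    if hi < 0:
        return None
    if surplus(0.0) >= 0:
        return 0.0
    return float(brentq(surplus, 0.0, 1.0, xtol=1e-6))
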