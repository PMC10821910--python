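"""Site selection, yield-gap accounting, area-weighted aggregation, stability.

Follows the yield-gap-atlas style of upscaling: reference buffers are picked
greedily by harvested area under overlap and coverage constraints; attainable
yield is 80% of yield potential for irrigated rice and 70% of water-limited
yield potential for rainfed rice; the exploitable gap is attainable minus
actual farmer yield, aggregated with harvested-area weights.  Inter-annual
stability is summarised by the coefficient of variation and the downside
semi-deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError
from .synthetic import SiteBuffer, SyntheticStudy

__all__ = [
    "ATTAINABLE_FRACTION",
    "YieldGapRecord",
    "StabilityMetrics",
    "select_reference_buffers",
    "attainable_yield",
    "exploitable_gap",
    "area_weighted_mean",
    "stability_metrics",
    "yield_gap_table",
    "regime_summary",
    "stability_table",
]

ATTAINABLE_FRACTION = {"irrigated": 0.8, "rainfed_lowland": 0.7, "rainfed_upland": 0.7}


@dataclass(frozen=True)
class YieldGapRecord:
    """Yield-gap accounting for one country × regime × buffer stratum (Mg ha⁻¹)."""

    country: str
    regime: str
    buffer_id: str
    yp_mgha: float
    ya_mgha: float
    attainable_mgha: float
    gap_mgha: float
    gap_fraction: float
    area_ha: float

    @property
    def gap_closed(self) -> bool:
        """True where farmers already meet or exceed the attainable yield."""
        return self.gap_mgha <= 0.0


@dataclass(frozen=True)
class StabilityMetrics:
    """Inter-annual variability summaries: CV in %, semi-deviation in Mg ha⁻¹."""

    cv_pct: float
    semideviation_mgha: float


def select_reference_buffers(
    candidates: list[SiteBuffer],
    national_area_ha: float,
    max_overlap: float = 0.20,
    target_coverage: float = 0.50,
    min_cz_share: float = 0.05,
    cz_area_share: dict[str, float] | None = None,
) -> list[SiteBuffer]:
    """Greedy buffer selection by descending harvested area.

    Candidates in climate zones holding less than ``min_cz_share`` of the
    regime's area are dropped first (when zone shares are supplied).  Buffers
    are then accepted largest-first, skipping any that overlap an accepted
    buffer by more than ``max_overlap``, until cumulative coverage of the
    national area reaches ``target_coverage`` or candidates run out — a
    shortfall is a warning, not an error.
    """
    if not candidates:
        raise SelectionError("no candidate buffers")
    if national_area_ha <= 0:
        raise ParameterError("national area must be > 0")
    pool = list(candidates)
    if cz_area_share is not None:
        pool = [b for b in pool if cz_area_share.get(b.climate_zone, 0.0) > min_cz_share]
        if not pool:
            raise SelectionError("no candidates left after climate-zone threshold")
    pool.sort(key=lambda b: (-b.area_ha, b.id))

    selected: list[SiteBuffer] = []
    coverage = 0.0
    for cand in pool:
        if any(cand.overlaps.get(s.id, 0.0) > max_overlap for s in selected):
            continue
        selected.append(cand)
        coverage += cand.area_ha / national_area_ha
        if coverage >= target_coverage:
            break
    if coverage < target_coverage:
        warnings.warn(f"coverage shortfall: selected buffers cover "
                      f"{100 * coverage:.0f}% < {100 * target_coverage:.0f}% "
                      "of national area", stacklevel=2)
    return selected


def attainable_yield(y_mgha: float, regime: str) -> float:
    """Attainable yield: 0.8·Yp (irrigated) or 0.7·Yw (rainfed)."""
    if y_mgha < 0:
        raise ParameterError("yield must be >= 0")
    try:
        return ATTAINABLE_FRACTION[regime] * y_mgha
    except KeyError:
        raise ParameterError(f"unknown regime: {regime}") from None


def exploitable_gap(attainable_mgha: float, ya_mgha: float) -> tuple[float, float]:
    """Exploitable gap (Mg ha⁻¹) and gap fraction of attainable yield.

    Negative gaps (farmers at or above attainable — the nearly-closed-gap
    case) are retained as-is for reporting.
    """
    if attainable_mgha <= 0:
        raise ParameterError("attainable yield must be > 0")
    gap = attainable_mgha - ya_mgha
    return gap, gap / attainable_mgha


def area_weighted_mean(values, weights) -> float:
    """Σ(v·w)/Σw with harvested-area weights."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ParameterError("values and weights must have the same length")
    if np.any(w < 0):
        raise ParameterError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ParameterError("sum of weights must be > 0")
    return float((v * w).sum() / total)


def stability_metrics(series) -> StabilityMetrics:
    """CV (100·sd/mean, sample sd) and downside semi-deviation of a yield series.

    Semi-deviation uses the series mean as benchmark:
    sqrt(mean(min(0, xᵢ − x̄)²)) — below-benchmark deviations only, averaged
    over all n years.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least 2 years")
    mean = x.mean()
    if mean == 0:
        raise ParameterError("CV undefined for zero-mean series")
    cv = 100.0 * x.std(ddof=1) / mean
    downside = np.minimum(0.0, x - mean)
    semidev = float(np.sqrt(np.mean(downside**2)))
    return StabilityMetrics(cv_pct=float(cv), semideviation_mgha=semidev)


# ---------------------------------------------------------------------------
# study-level aggregation
# ---------------------------------------------------------------------------

def series_stability(series) -> StabilityMetrics:
    """Stability of a simulated :class:`~ricegap.crop.YieldSeries`.

    Where the series carries groundwater-scenario components (rainfed
    lowland), the metrics are the 50:50 area-weighted mean of the
    per-scenario metrics: half the area experiences each environment, so the
    instability farmers face is the average of the two environments'
    instability — pooling the series first would let opposite anomalies in
    areas that share no water cancel.
    """
    if series.components:
        parts = [stability_metrics(v) for v in series.components.values()]
        return StabilityMetrics(
            cv_pct=float(np.mean([p.cv_pct for p in parts])),
            semideviation_mgha=float(np.mean([p.semideviation_mgha for p in parts])),
        )
    return stability_metrics(series.yields)


def yield_gap_table(study: SyntheticStudy) -> pd.DataFrame:
    """Per-buffer yield-gap records for a study, as a tidy DataFrame."""
    rows = []
    for buf in study.buffers:
        yp = float(study.yp_series[buf.id].yields.mean())
        att = attainable_yield(yp, buf.water_regime)
        gap, frac = exploitable_gap(att, buf.actual_yield_mgha)
        rows.append(YieldGapRecord(
            country=buf.country, regime=buf.water_regime, buffer_id=buf.id,
            yp_mgha=yp, ya_mgha=buf.actual_yield_mgha, attainable_mgha=att,
            gap_mgha=gap, gap_fraction=frac, area_ha=buf.area_ha,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


def regime_summary(table: pd.DataFrame,
                   by: tuple[str, ...] = ("regime",)) -> pd.DataFrame:
    """Area-weighted Yp, Ya, attainable, gap, and gap fraction per group."""
    def agg(g: pd.DataFrame) -> pd.Series:
        w = g["area_ha"]
        out = {c: area_weighted_mean(g[c], w)
               for c in ("yp_mgha", "ya_mgha", "attainable_mgha", "gap_mgha")}
        out["gap_fraction"] = out["gap_mgha"] / out["attainable_mgha"]
        out["area_ha"] = float(w.sum())
        return pd.Series(out)

    return (table.groupby(list(by)).apply(agg, include_groups=False)
            .reset_index())


def stability_table(study: SyntheticStudy) -> pd.DataFrame:
    """CV and semi-deviation of each buffer's simulated yield series.

    Rainfed-lowland metrics are the 50:50 area-weighted mean over the two
    groundwater scenarios (see :func:`series_stability`).
    """
    rows = []
    for buf in study.buffers:
        m = series_stability(study.yp_series[buf.id])
        rows.append({"buffer_id": buf.id, "country": buf.country,
                     "regime": buf.water_regime, "area_ha": buf.area_ha,
                     "cv_pct": m.cv_pct, "semideviation_mgha": m.semideviation_mgha})
    return pd.DataFrame(rows)
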