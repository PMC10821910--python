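# Methods

This note documents the models behind `ricegap`: what each stage assumes,
which parameters matter, what the synthetic data does and does not emulate,
and where genuinely open design choices were made.

## Crop season simulator

The simulator is deliberately simple: a daily radiation-use-efficiency (RUE)
canopy model with prescribed leaf area, coupled to thermal-time phenology
and a one-bucket soil water balance. It is not a full process model — no
organ-level carbon partitioning, no nitrogen, no pests or diseases
(simulations assume non-limiting nutrients and no biotic stress, which is
what "yield potential" means). Its purpose is to honour every stated
physiological parameter and reproduce the *relative* structure yield-gap
analysis relies on: irrigated ≥ rainfed lowland ≥ rainfed upland, shallow ≥
deep water tables, and realistic 4–11 Mg ha⁻¹ paddy yields across monsoonal
climates.

### Phenology

Development stage DVS advances daily by `DVR(stage) × T_eff`, with stages in
the ORYZA convention: juvenile (DVS 0→0.40, rate DVRJ), photoperiod-sensitive
(0.40→0.65, DVRI), panicle development (0.65→1.0, DVRP), reproductive
(1→2, DVRR). Thermal time `T_eff` is piecewise linear in the daily mean
temperature: zero at or below the 14 °C base, rising 1 °Cd per °C to the
30 °C optimum, falling to zero at 42 °C. Only the base temperature is a
stated constant; the optimum and maximum follow the common rice-model
convention and are configurable. Photoperiod sensitivity is off: DVRI is
calibrated like the other rates but day length never modulates it.

Calibration mirrors the DRATE approach: bisection on a single multiplier of
the three pre-flowering rates until the mean simulated sowing→flowering
duration across all weather years matches the calendar within ±1 day, then
the same for DVRR against the flowering→maturity phase. Flowering is fixed
30 days before maturity, so a calendar is fully described by sowing day and
total duration. Because cumulative thermal time is monotone, each simulated
duration is a step function of the multiplier and bisection (geometric
midpoint, bounds ×/÷200) converges in a few dozen iterations; a target
shorter than achievable at the rate bound raises a calibration-infeasible
error rather than silently clipping.

### Canopy and growth

Daily above-ground growth is
`ΔW = RUE × f_PAR × R_s × (1 − e^{−k·LAI}) × ratio` with RUE = 2.2 g MJ⁻¹
(PAR basis), PAR fraction f_PAR = 0.5, extinction k = 0.5, and a prescribed
LAI curve: a sin² rise to LAI 6 at flowering, then linear senescence to 60%
of the peak at maturity. Grain yield is
`HI·W·(1 − sterility) + 0.2 × (stem biomass)` with base harvest index 0.45,
a stem fraction of 0.4, and the 0.2 stem-reserve fraction remobilised to
grain; dry grain is converted to paddy at the standard 14% (140 g kg⁻¹)
moisture by dividing by 0.86. These canopy defaults were chosen once to give
realistic absolute yields; absolute levels are a calibration outcome of this
simplified model, not independently validated values — the quantities the
package stands behind are the orderings and the gap/scenario accounting
built on top.

### Temperature stress

Two rules, both pure functions of the temperature series: (i) three
consecutive days with mean temperature below 12 °C kill the crop (yield 0);
(ii) spikelet sterility accumulates around flowering (days with DVS in
[0.96, 1.20]) as 0.10 per °C of daily maximum above 35.6 °C, averaged over
the window and clamped to [0, 1]. The thresholds (12 °C, 3 days, 35.6 °C)
are stated constants; the 0.10 °C⁻¹ slope and the DVS window are design
choices, configurable via `StressParams`. Cold sterility is omitted — only
the lethal-cold rule comes with stated numbers.

### Soil water balance

One bucket per site: root-zone storage plus a surface pond. Daily order of
operations — inflows (rain, irrigation, capillary rise) infiltrate to
saturation; excess ponds up to the bund (25 cm lowland, none upland) and the
surplus runs off; the crop transpires `ratio = min(1, available/demand)` of
its demand (pond first, soil down to wilting); bare-soil evaporation
(0.85·ET₀ uncovered fraction) dries pond and soil likewise; free water
(pond + storage above field capacity) percolates at up to K_sat. The daily
ledger closes exactly by construction and tests assert it to machine
precision.

Stated soil constants: θ_init/θ_sat/K_sat = 0.57/0.56 m³ m⁻³/10.79 cm d⁻¹
(lowland clayey loam) and 0.39/0.38/99.77 (upland sandy loam); groundwater
at 40 or 100 cm for lowland (area split 50:50 between the two scenarios,
yields reported as the blend) and 1000 cm for upland. Field capacity and
wilting point are not stated and were set once on texture grounds:
θ_fc = θ_sat − 0.07 both profiles; θ_wp = 0.25 (clay) and 0.10 (sand);
rooting depth 50 cm lowland, 30 cm upland. Capillary rise is linear in
water-table depth — 5 mm d⁻¹ at 40 cm, 1 mm d⁻¹ at 100 cm, zero at 200 cm —
a minimal profile that preserves the shallow ≥ deep ordering the analysis
relies on, since the real effect is highly site-dependent.

Transpiration demand is `ET₀ × min(1.35·f_int, 1.25)` — a paddy crop
coefficient around 1.25 at full canopy — with reference ET from the
Hargreaves radiation form `0.0135 (T_mean + 17.8) R_s / 2.45`, chosen
because the weather generator provides no humidity or wind. Irrigated crops
bypass the bucket entirely (ratio = 1).

Transplanting is modelled minimally: development integrates from sowing, and
biomass accumulation starts at the transplanting date. Transplanting shock
is ignored.

## Synthetic weather and study generator

The generator emulates a monsoonal station record: sinusoidal annual cycles
in temperature (default mean 27 °C, amplitude 2.5 °C, diurnal range 9 °C)
and clear-sky radiation (21 ± 3 MJ m⁻² d⁻¹); rainfall as Bernoulli wet-day
occurrence (probability 0.55 inside a 120-day monsoon window starting day
150, 0.06 outside) with gamma wet-day depths (mean 10 mm, shape 1.2);
radiation reduced 25% on wet days. Year-to-year monsoon variability — a
lognormal strength multiplier (σ = 0.30) on the wet-day odds and a ±10-day
onset jitter — reproduces the 20–30% interannual rainfall CV typical of
semi-arid monsoon climates. These defaults define the study conditions:
crop calendars sown just after monsoon onset with 110–135-day durations put
grain fill into the tapering rains, which is what makes rainfed upland rice
both lower-yielding and less stable than lowland and irrigated rice. Leap
days are generated like any other day; the simulator treats all days
identically.

What the generator does *not* emulate: spatial correlation between sites,
humidity/wind, multi-day synoptic persistence, trends, or any real station's
record. Tests passing on synthetic data therefore demonstrate the internal
consistency and qualitative behaviour of the pipeline, not agreement with
observed African weather or yields.

Site networks draw 1–3 buffers per water regime present in each country
(regime mixes and areas randomised per country), calibrate phenology per
buffer, simulate multi-year yield potential, and draw the actual farmer
yield uniformly between 35% and 75% of the implied attainable yield — so
every stratum carries a positive exploitable gap with fractions in the
25–65% band. Country profiles are rolled up from buffers with a plausible
trade balance (SSR 0.35–0.90), doubling-scale population growth, rising
per-capita demand, and milling rates in the 0.63–0.69 range.

## Upscaling and stability

Attainable yield is 0.8·Yp for irrigated and 0.7·Yw for rainfed rice; the
exploitable gap is attainable − actual, retained when negative (farmers at
or above attainable, the "gap closed" case) for reporting but floored at
zero as intensification headroom in scenarios. All aggregation uses
harvested-area weights. Reference-buffer selection is greedy by descending
area, skipping candidates overlapping an accepted buffer by more than 20%,
stopping at 50% cumulative coverage; a shortfall is a warning, not an
error, since sparse station networks routinely cover less.

Stability metrics: CV = 100·s/x̄ (sample standard deviation) and downside
semi-deviation `sqrt(mean(min(0, xᵢ − x̄)²))`, with the series mean as the
benchmark (configurable — the downside-risk literature also uses fixed
targets). For rainfed lowland, the reported stability is the 50:50
area-weighted mean of the two groundwater scenarios' metrics rather than
the metric of the pooled series. This was a genuinely open choice: the two
scenarios represent physically distinct halves of the lowland area, and
pooling their series first lets opposite anomalies (drought losses on deep
water tables versus radiation gains on shallow ones in dry years) cancel,
making the stratum look more stable than either of its environments — a
portfolio artifact, not an agronomic one. Yield *levels* still use the
50:50 blended series.

## Demand and scenarios

Baseline demand uses the supply identity
`production + imports − exports − stock change`, with positive stock change
read as stock build-up (withheld from consumption, hence subtracted); the
sign convention is configurable since reporting conventions differ.
Per-capita demand arrives on a milled basis and is divided by the national
milling rate (typically 0.63–0.69) before use; 2050 demand is population ×
per-capita paddy demand. Yield extrapolation continues the historical trend
linearly, capped at the attainable yield.

The scenario grid spans closure fractions f ∈ [0, 1] of the current
exploitable gap and expansion rates 0.2/0.4/0.6 M ha yr⁻¹ (the historical
rate ±50%) over a 30-year horizon. Expansion is allocated across countries
proportionally to current rice area and within countries pro-rata across
regimes (irrigated fraction and cropping intensity held fixed) — the total
rates are stated but the allocation is not, so this is documented as the
package's choice. Countries pool continentally (trade offsets local
deficits); summed demand is multiplied by 1.05 to cover minor consumers
outside the study set; producing countries outside the study set scale
their baseline production by the study-average relative yield increase
(the stated wording admits alternatives; this one is linear, conservative,
and configurable via `RestOfContinent`). Net imports are costed at the
constant US$289 Mg⁻¹ paddy price with no price response. Climate
sensitivity scales attainable yields and the expansion rate by −5% or −10%
before recomputing the grid. Headline roundings (SSR to 2 decimals, Mt to
integers) are applied only in reports, never in internal state.

`solve_closure_fraction` inverts the grid: production is piecewise-linear
and monotone in f, so the smallest f achieving self-sufficiency is found by
bracketing plus Brent's method (xtol 1e-6).

## Numerical choices and degenerate inputs

- Thermal-time phenology is evaluated via cumulative sums and
  `searchsorted`, so a season's phenology costs microseconds and
  calibration stays fast even over 20 years.
- Temperatures pinned at the 14 °C base never advance DVS and raise a
  cycle-incomplete error, as does any weather series ending before DVS 2.
- QC gap filling interpolates linearly between flanking observations;
  boundary gaps, where two-sided interpolation is impossible, take the
  nearest observed value and emit a warning. The operation is idempotent
  and never alters observed values.
- Weather CSVs are written with `%.17g` and read with round-trip float
  parsing, so stage hand-offs through files are bit-exact and pipeline
  reruns are byte-identical (verified by manifest checksums).
- Zero-mean yield series make CV undefined and raise; fewer than two years
  raise; all-zero area weights raise.

## Problem sizes

Defaults were sized for interactive use: the standard pipeline run is 5
countries (≈15–25 buffers) × 10 weather years and completes in a couple of
seconds; stability analyses use 20 years at a single site; the aggregate
gap-fraction check uses 20 countries × 4 years. All generators and the
pipeline are deterministic in (parameters, seed).

## Known limitations

- Absolute yield levels come from a fixed RUE/LAI/HI parameterisation; they
  land in the right range but are not validated against field trials, which
  the source analysis did do for its process model.
- One soil bucket cannot represent perched water tables, hardpans, or
  runoff-run-on positions in toposequences; the groundwater scenarios stand
  in for that heterogeneity.
- Sterility uses daily maxima, not panicle temperature; transpirational
  cooling (which shifts flowering-time heat exposure in hot irrigated
  systems) is not modelled.
- Demand projections treat population and per-capita demand as exogenous
  inputs; no price feedback links the import bill back to consumption.
- The climate-sensitivity mode perturbs attainable yields and expansion
  rates; it is not a climate-change projection.
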