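# Methods

This note documents the model equations, the parameter choices that matter,
the synthetic data the tests run on, and the numerical decisions taken where
the design was genuinely open.

## Scope and structure

`aquapot` simulates one potato season at a daily step for a drip-irrigated
field in an arid continental climate, and wraps that simulator in scenario
tooling for irrigation-schedule optimization. The chain per day is:

1. infiltrate rain and irrigation (cascade bucket),
2. read water-stress coefficients from root-zone depletion,
3. advance the canopy on the thermal clock,
4. extract soil evaporation and transpiration subject to availability,
5. accumulate biomass from realized transpiration.

Conservation takes precedence over demand everywhere: evaporation and
transpiration demands are capped by extractable water, never rejected, and
the water balance closes to machine precision (asserted to 1e-6 mm over
random 120-day seasons in the tests).

## Atmospheric demand

Daily FAO-56 Penman–Monteith ET0 with the standard reductions for sparse
daily records:

- `es` = mean of saturation vapour pressures at Tmax and Tmin (Tetens form);
  `ea` = RHmean/100 × es. Only mean relative humidity is available in the
  station record format the package targets.
- Net radiation from sunshine duration: Angstrom coefficients a_s = 0.25,
  b_s = 0.50 (no local calibration data), grass albedo 0.23, Brunt-type net
  longwave with the usual cloudiness correction. Clear-sky radiation uses
  the altitude correction (0.75 + 2e-5 z) Ra.
- Soil heat flux G = 0 at the daily step.
- T = (Tmax + Tmin)/2.
- A negative combination-equation result (rare winter radiative deficits)
  clamps to 0 with a logged warning; negative atmospheric demand must not
  propagate into the crop model.
- Sites/dates in polar day or night raise an unsupported-site error rather
  than returning a degenerate sunset hour angle.

## Soil water

The profile is the measured three-layer sandy loam (0–60 cm; wilting point
0.10/0.10/0.12, field capacity 0.19/0.20/0.23, saturation 0.32/0.35/0.38
cm³/cm³). Choices:

- **Drainage** is an instantaneous cascade to field capacity: excess passes
  to the next layer and then out of the profile. No drainage-characteristic
  data exist for the site; at a daily step on sandy loam the cascade is the
  simplest conservative rule.
- **Runoff** is neglected: small level plots, drip quotas ≤ 24 mm.
- **Soil evaporation** demand is Ke (1 − CC) ET0 with Ke = 1.10, scaled by
  the surface fraction wetted under drip (`wetted_fraction`, default 0.30 —
  the conventional planning value for drip systems with one emitter per
  plant; surface wetting outside the emitter bulbs is minor in this
  climate). Supply comes from a 0.10 m surface skin of the top layer with a
  two-stage drying model: full rate within 8 mm of readily evaporable
  water, then a linear falling rate down to an air-dry floor of 0.5 θwp.
  The wetted fraction also implicitly covers rain-wetted days; this
  underestimates evaporation after large rains, which are rare at ~270 mm
  per year.
- **Transpiration** is extracted from the rooted zone proportionally to
  each layer's water above wilting point.
- **Stress coefficients** are piecewise in relative depletion Dr/TAW:
  Ks = 1 below the upper threshold p_upper, 0 beyond p_lower, linear in
  between (a convex shape is available). The calibrated thresholds are
  expansion 0.26→0.66, stomatal closure 0.65→1, early senescence 0.69→1.
- **Roots** ramp linearly from 0.20 m at planting to the maximum effective
  depth 0.45 m by day 75 — about the start of tuber growth, when potato
  root systems are fully developed.
- **Initial condition** defaults to field capacity at planting (pre-season
  irrigation practice in the region); a fractional fill between wilting
  point and field capacity is available as a config knob because the
  experimental initial condition is unrecorded.
- Waterlogging is not modelled (θ is simply capped): an arid site with
  ≤ 24 mm drip quotas cannot sustain anaerobiosis.

## Canopy

Canopy cover CC (fraction of shaded ground) follows the canonical
exponential growth / decline pair, stepped incrementally so stress can vary
daily:

- growth: dCC/dGDD = CGC·CC for CC ≤ CCx/2, then CGC·(CCx − CC);
- decline after the senescence day: dCC/dGDD = −0.05·CDC·(21 − 20·CC/CCref),
  the derivative of the canonical decay curve expressed in the current
  cover.

Calibrated values: CC0 = 0.9% (read as percent cover — plausible for
33,345 plants/ha seedlings), CGC = 0.966 %/GDD, CCx = 94%,
CDC = 0.798 %/GDD, base/upper temperatures 10/35 °C.

**Both clocks run on thermal time.** The parameter table that these values
come from prints CGC per day and CDC per degree-day, but 0.966% per
calendar day cannot close a canopy inside a 150-day season (it would take
over 400 days to reach CCx/2 from 0.9%), while 0.966 %/GDD reproduces the
observed phenology — slow cover until ~50 days after planting, maximum
cover around day 110 — and matches the conventional GDD-mode magnitude of
this coefficient for potato. We therefore read the per-day unit as a
tabulation slip and run the whole canopy clock on growing degree days.

GDD per day caps both temperature extremes at the upper limit, takes the
mean, subtracts the base temperature and floors at zero.

Other canopy decisions:

- Cover snaps to CCx once within 1e-4 (the asymptotic approach would
  otherwise never attain the plateau exactly).
- Expansion stress multiplies CGC by Ks_exp. Depletion beyond the
  senescence threshold applies a decay proportional to current cover at
  CDC scaled by (1 − Ks_sen); the proportional form keeps a stressed
  seedling alive through a dry spell and lets cover regrow after rewetting,
  while sustained severe stress still collapses the canopy.
- Phase calendar defaults (emergence at planting for the cover state,
  senescence onset day 120, maturity day 150) bracket the observed
  trajectory anchors: maximum canopy ≈ day 110, biomass plateau ≈ day 140,
  harvest ≈ day 150.
- CC* (the transpiration-effective cover) defaults to the micro-advective
  cubic CC* = 1.72 CC − CC² + 0.30 CC³, which inflates partial covers for
  the extra demand intercepted by row crops; an identity policy is
  available.

## Production and yield

- Tr = Ks_sto (CC* KcTr,x) ET0 with KcTr,x = 1.15. The stomatal coefficient
  is the one entering transpiration; expansion and senescence coefficients
  act only on the canopy.
- B = WP* Σ(Tr/ET0), WP* = 20 g m⁻², accumulated from realized (post-cap)
  transpiration; g/m² → t/ha (×0.01) applied once at this boundary. Days
  with ET0 = 0 contribute nothing.
- Y_dry = fHI (HI0/100) B with HI0 = 55% and fHI = 1 by default: no
  stress-adjustment rule for the harvest index is parameterized, so the
  hook exists (`f_hi_policy`) but the default applies none.
- Fresh tuber yield = Y_dry / dm_fraction with dm_fraction = 0.11. The
  scenario tables this package ships print fresh yields about five times
  the dry biomass (e.g. 46.77 t/ha against 9.28 t/ha), implying an
  effective tuber dry-matter fraction of ≈0.109 — within the normal potato
  range of 0.18–0.25 only if part of the final biomass is excluded;
  taken at face value the implied conversion is 0.11 and that is the
  default, exposed in config.
- WUE = 100 · Y_fresh / ET with Y in t/ha and ET in mm (unit identity:
  1 t/ha = 1000 kg/ha, 1 mm = 10 m³/ha). WUE is always recomputed from the
  package's own Y and ET; the shipped tables' WUE column differs from
  100·Y/ET of the same rows by 1–3% (presumably computed from unrounded
  internal values) and is kept exactly as printed.

## Irrigation scenarios

The 30-scheme grid crosses five water levels with three cycle/event
triples — (5 d, 12 events), (7 d, 9), (10 d, 6) — in two scenarios:
scenario I fixes the seasonal amount (90–210 mm; per-event quota =
amount/events), scenario II fixes the per-event quota (10–24 mm; amount =
quota × events). Totals in m³/ha are 10 × mm. Plans start on May 18 and the
events must finish by August 26 (the experimental irrigation window) unless
overridden. Multi-year scenario results are unweighted means over years.
Optimum selection breaks ties toward less total water (an equal outcome
for less water is strictly preferable), then scheme order.

The quadratic irrigation–yield fit y = a + bx + cx² uses ordinary least
squares; the optimum is the vertex −b/2c when the curve is concave. On the
packaged fixed-quota 5-day pairs the fit gives vertex ≈ 2561 m³/ha and
R² ≈ 0.897. Three point-set presets exist (scenario-I-only, -II-only,
pooled-unique) because the exact published point set is ambiguous; the
scenario-II-only preset best matches the published narrative (optimum just
past 2500 m³/ha), and the published R² values (0.92/0.82) are treated as
approximate-agreement bands since they are not exactly recoverable from
rounded table values.

## Evaluation statistics

RMSE, NRMSE (% of the measured mean), Willmott's index of agreement

    d = 1 − Σ(Si−Mi)² / Σ(|Si−M̄| + |Mi−M̄|)²

(with absolute values on both deviations, the standard bounded-in-[0,1]
form), and the squared Pearson correlation. Degenerate inputs raise typed
errors: zero measured mean (NRMSE), all values at the measured mean (d),
zero variance in either series (R²). Observation/simulation alignment is
exact-date first, else nearest simulated day within ±1 day, else an error.
Qualitative report bands follow crop-modelling convention: NRMSE < 10%
very good, < 30% moderate; d, R² > 0.9 excellent.

## Synthetic weather

The generator produces what the analysis needs — realistic seasonal totals
and evaporative demand — and nothing more:

- Rain: monthly Bernoulli occurrence (probabilities peaking at 0.20 in
  July–August, near zero in winter) × Gamma(0.8, 10.6 mm) amounts. The
  preset's implied expectations are ≈270 mm/yr and ≈239 mm May–October,
  matching the site's multi-year mean and the two recorded growing-season
  sums (234.2 and 266.6 mm).
- Temperature: sinusoidal normals peaking mid-July (Tmax 14.5 ± 16 °C,
  Tmin 2 ± 15 °C) plus a shared AR(1) anomaly (σ = 2.8 °C, ρ = 0.7); the
  shared anomaly preserves Tmax ≥ Tmin by construction and a 5 °C diurnal
  floor reflects the large day–night contrast of the site.
- Relative humidity: monthly normals 35–55% with noise and a wet-day bump;
  wind: lognormal (median ≈ 2.1 m/s); sunshine: 68% of daylength, halved
  on wet days.
- One integer seed drives all streams through a single generator, so output
  is bit-reproducible; February 29 is skipped (365-day years).

Not represented: rainfall autocorrelation and extremes, humidity–
temperature coupling, inter-annual climate trends. Passing tests therefore
demonstrate the model's response to realistic *totals and demand levels*,
not fidelity to any particular historical year. The site's reported annual
pan evaporation (~2325 mm) is not a calibration target for ET0, which is a
different quantity (the generator's years produce ~1100–1200 mm of ET0).

## Numerical choices and degenerate inputs

- Plateau snap tolerance 1e-4 (canopy); balance closure asserted to 1e-6 mm
  per season; statistic oracles agree to 1e-12; ET0 agrees with the
  independent straight-line chain to 1e-9 mm/day.
- Tie-breaks in scheme selection: less water first, then scheme order.
- Empty weather series pass through ET0 attachment unchanged; weather gaps
  and missing fields raise errors naming the date and field.
- Problem sizes used by the consistency checks — 100 random 120-day
  seasons, 1000 random days/series, a 30-scheme × 6-year scenario study —
  are the package's own verification scale, chosen to exercise every branch
  at machine precision.

## Known limitations

- No salinity, fertility, cold or heat stress modules; fHI is constant.
- The bucket model has no capillary rise or Richards dynamics; drainage is
  same-day.
- Soil evaporation under mixed rain/drip wetting uses a single wetted
  fraction.
- The canopy early-senescence rule is a smooth proportional decay, not a
  mechanistic leaf-death model; its coefficient is the decline coefficient
  CDC scaled by stress.
- Scenario results over synthetic weather reproduce the *structure* of the
  published study (concave response, cycle ordering, optimum region), not
  its absolute values, which depend on the unavailable 2015–2020 station
  record.
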