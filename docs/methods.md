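# Methods

This note records the model structure, the parameter choices that matter,
what the synthetic weather emulates (and does not), and the numerical and
design decisions taken where the underlying model family leaves latitude.

## Model structure and assumptions

The simulator advances a single representative plant (scaled by surviving
plant density) on an hourly weather clock from planting to a fixed harvest
date. Within each day: leaf-tip appearance and scape progress accumulate
hourly; canopy assimilation is solved for all 24 hours at the day's leaf
area index; cold stress, leaf elongation, senescence, pool drainage,
partitioning and stage transitions update once per day. The model assumes
non-limiting water and nitrogen throughout — outputs are potential growth
for the given weather, which is why simulated biomass is expected to sit at
or above what field observations under real management would show.

### Phenology

* Initial appearance rate: sigmoid of storage duration SD with
  `LTAR_max,a = 0.4421 d^-1`, `SD_m = 117.7523 d`, `alpha = 0.0256 d^-1`.
  SD is computed from an assumed June 30 seed harvest to the planting date.
  Storage temperature (8 degC) is carried in the configuration but inert:
  only duration enters the rate equation here.
* Convergence: linear in leaf rank toward `LTAR_max,a / 2`, clamped once
  rank reaches the generic leaf number `N_g = 10`. For ranks beyond `N_g`
  the rate is held at the target (the convergence is "done"); this clamping
  is an interpretive choice.
* The scape-appearance counter accumulates three phyllochron-equivalents at
  the *current* dynamic rate (not a rate frozen at onset) — the alternative
  reading; chosen because the dynamic rate is the model's point.
* Temperature response of appearance and elongation: a beta function with
  base 0 degC, optimum 22 (appearance) / 20 (elongation), ceiling 34 degC.
  The underlying model family uses this form; the optima are estimates.
* Emergence and reproductive onset fire on growing-degree-day thresholds
  (base 4 degC): 100 degC d from planting to emergence and 800 degC d from
  emergence to onset. The 800 value was chosen once so that an
  early-October subtropical planting turns reproductive in late March and
  shows its scape in mid-late April, the field-typical window; it is a
  configurable trigger, with photoperiod gating left out of scope.
* Leaf initiation runs at twice the appearance rate from the initial leaf
  number (ILN = 6) up to a 16-leaf cap — a plausibility default, not a
  fitted value; it only gates appearance.

### Cold stress

* Injury: `D` updates once per day from the daily minimum temperature
  (injury and frost act through night-time extremes); the typeset form of
  the cumulative-days rule is ambiguous and the implemented reading is a
  running sum clipped at zero, so warm days erode an episode. The effect
  uses `E = 1 - C^(1/D)`: the only reading in which longer exposure worsens
  injury and E stays in [0, 1]. It lives behind a single function
  (`injury_effect`) so an alternate reading can be swapped.
* The injury curve `C` uses the natural log; with `a = -0.1, b = 1.6` it
  clamps to full injury near -11 degC, consistent with mortality peaking by
  -20 degC. Where the log argument reaches zero (warm side for negative
  `a`), C clamps to zero by continuity.
* Mortality is evaluated once per day on the daily minimum and applied
  multiplicatively to density, so repeated frosts compound — a single-event
  reading would not produce stand collapse. The update is gated to days
  whose minimum falls below the injury threshold (0 degC): the logistic
  tail is nonzero everywhere, and without the gate a frost-free season
  would not leave the stand bit-identical, which the model treats as a
  structural requirement (cold modules must be exact no-ops in warm runs).
* Mortality is independent of developmental stage; dormant plants are not
  treated as hardier.

### Carbon

* Coupled route: Farquhar-von Caemmerer-Berry C3 kinetics (Bernacchi
  temperature responses, peaked Vcmax/Jmax), Ball-Berry conductance
  (`gs = g0 + g1 A h_s / C_s`), a boundary layer scaling with wind, and a
  linearized leaf energy balance (absorbed shortwave less latent heat,
  vented as sensible heat; leaf-air difference clamped to +/-10 degC).
  Solved per canopy layer by damped fixed-point iteration on Ci (damping
  0.3 old / 0.7 new) with a full step on leaf temperature; tolerance 1e-3
  umol mol^-1 within 100 iterations across the realistic input grid (an
  independent bisection oracle in the tests confirms the fixed point).
  The sunlit/shaded split is a simplified two-big-leaf scheme: fixed 70/30
  beam/diffuse partition, sunlit leaf area from beam extinction (k = 0.5),
  shaded leaves receiving mid-canopy attenuated diffuse light.
* Garlic-specific leaf parameters (Vcmax25 = 100, Jmax25 = 180, Rd25 = 1.5
  umol m^-2 s^-1, g1 = 9) are estimates standing in for values calibrated
  elsewhere; no analytic result in the package depends on them. PAR is
  2.3 umol photons per joule of shortwave (half of shortwave as PAR).
* RUE route: Beer-law interception times 1.5 g CH2O MJ^-1. It exists so
  downstream behaviour (phenology, cold stress, allocation) can be tested
  independently of the gas-exchange parameterization; the fast test suite
  uses it, the acceptance scan exercises the coupled route.
* Pool accounting: the pool is drained the same step it is filled
  (supply = pool/dt), maintenance (Q10 = 2 about 25 degC) is paid first,
  growth converts at `Y_g = 0.75` (standard for this lineage), and the
  (1 - Y_g) share is growth respiration. The pool floors at zero; carbon
  debt from net-negative days is not tracked (it does not occur while the
  canopy exists, because daytime assimilation dominates dark respiration at
  the daily step). A 2 g seed-clove reserve fuels pre-emergence growth.
* The partitioning table's numeric coefficients are not published; the
  defaults here were set teleonomically (vegetative growth root/leaf/
  sheath-heavy; reproductive stages progressively bulb-dominant, with the
  scape column nonzero only in R1/R2) and every conservation test is
  value-independent. Rows are renormalized at use against float drift, so
  increments sum to the allocation exactly.

### Morphology

* Rank profile of potential final length: half-sine rise from 30% of
  `LM_min = 100 cm` at rank 1 to the maximum at 70% of the total leaf
  count, flat after. Only the maximum is a cultivar parameter; the shape is
  a documented choice.
* Area allometry: `area = length * (0.02 * final_length) * 0.75`
  (width ratio and form factor are estimates; they give a peak green area
  of roughly 1.5-1.7 x 10^3 cm^2 per plant, the right order for this crop).
* Senescence: after full expansion a leaf stays green for
  500 degC d x SG (SG = 1.5, dimensionless multiplier — the unit ambiguity
  in the source tables is resolved as a multiplier), then fades linearly
  over 300 degC d x SG. A thermal-lifespan rule substitutes for the
  original model's unstated onset rule; it reproduces the qualitative
  orderings (warmer season -> earlier peak and earlier senescence).

### Experiment machinery

Planting dates day-of-year 240-350 in 10-day steps (12 dates; planting in
year Y, harvest fixed May 15 of Y+1); historical scenarios use 10 seeded
weather datasets (120 runs), future scenarios 8 decade-windows x 10
repetitions = 80 datasets (960 runs); future period groupings pool
10 seeds x 5 decades = 50 samples per data point. Optimal planting date is
the per-replicate argmax over dates (computed per replicate, then
summarized), ties broken toward the earlier date. Scenario CO2 is a
piecewise-linear trajectory between anchor years, with no extrapolation.

## Synthetic weather

The generator is a stand-in for stochastic climate-ensemble products: an
annual sinusoid for daily mean temperature (asymmetric winter/summer
amplitudes, warmest day pinned near July 25), a clipped AR(1) daily
residual (rho 0.7, sigma 2 degC subtropical / 4 degC continental), a fixed
diurnal range expanded to hours by the same dawn-minimum / mid-afternoon-
maximum scheme used for downscaling and re-centred on the daily mean, and
daily solar as a noisy clear-sky fraction of the astronomical maximum at
the profile latitude. The `severity` argument scales the winter amplitude.

Profile targets, chosen once to represent the two study climates: the
subtropical profile (lat 33.3) has January daily minima averaging about
+4 degC and never reaches -5 degC, so cold pathways stay inert; the
continental profile (lat 37.9) has January daily minima averaging below
-10 degC with recurring excursions past -15 degC, so frost mortality
reliably collapses the stand at default severity. The continental winter is
drawn toward the severe end of its climate class so that the mortality
pathway is exercised decisively for any seed.

What the generator does *not* emulate: weather fronts and multi-day
synoptic structure beyond AR(1) memory, humidity-temperature coupling,
precipitation (unused by the model), and real inter-annual variability of
ensemble products. Passing tests on this weather demonstrate the model's
internal behaviour and orderings, not skill against observed seasons.

## Numerical choices and degenerate inputs

* Downscaling pins the coldest sampled hour (floor of sunrise) exactly at
  T_min and 14:00 at T_max, with nighttime exponential decay (0.5 h^-1), so
  daily aggregation inverts it within 0.01 degC; hourly solar is normalized
  so the daily integral is exact. A zero-amplitude day yields a constant
  profile; polar day/night fall back to clamped sunrise/sunset.
* Appearance accumulators cannot bank more than one leaf of progress past
  the initiation cap; stage transitions are validated forward-only.
* Yield problem sizes: the test suite runs single seasons and small scans
  on the RUE route (seconds); the acceptance script runs the two full
  120-run scans with coupled gas exchange, about three minutes on one core.

## Known limitations

Absolute yields are potential yields under estimated gas-exchange and
partitioning parameters and should not be read as site predictions; no
vernalization, soil water, nitrogen, or stage-dependent cold hardiness; the
scape's pre-appearance growth window is short under the default triggers,
so removed scape mass is small; fresh-yield moisture is a constant 85%.
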