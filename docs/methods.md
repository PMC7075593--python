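# Methods notes

This note records the models, defaults and numerical choices behind
`gannetrack`, and what the synthetic generator does and does not emulate.

## Sensor model and geolocation

The logger is modelled on archival GLS units: maximum light per 10 min on
an arbitrary saturating scale, saltwater immersion sampled every 3 s and
integrated to a count 0–200 per 10 min, and water temperature recorded 20
and 40 min into each continuously wet spell.

Light is rendered as a logistic response of geometric solar elevation at
the true position, `L = 64 / (1 + exp(-(elev + 2)/1.8))`, saturating at 64.
This mapping puts the conventional threshold value 16 at an elevation of
−4.0°, inside the −6…−3° band typical of field calibrations, so the
calibration step is exercised with the threshold as actually used.
Optional shading noise is multiplicative log-normal on the light value.

Geolocation inverts the threshold model: longitude from the midpoint of a
twilight pair being local apparent noon/midnight (equation of time from
the NOAA solar-calculator series, which tests cross-check against an
independently coded Astronomical Almanac ephemeris to <1 min); latitude by
Brent root-finding of the day-length equation on [−70°, 70°] at 0.01°
tolerance. Refraction is not modelled anywhere: the calibrated sun
elevation angle is an effective constant that absorbs it on both the
forward and inverse paths.

*Equinox handling.* Latitude is declared unresolvable — flagged, never
guessed — when a ±4-min perturbation of day length (one sampling interval
of timing error) moves the solution by more than 20° of latitude. The
date-window filter additionally drops fixes within ±15 days of each
equinox; the width is a configurable default, since the convention is
cited but unspecified in the source literature.

*Filters.* Order: equinox → inland → speed. The inland test uses a coarse
built-in polygon of eastern North America (~50 vertices; Newfoundland and
Caribbean islands omitted, Nova Scotia fused to the mainland) — adequate
for a >200 km threshold against ~200 km geolocation error, not for
cartography. The 1,200 km/24 h speed ceiling is pro-rated to the actual
interval between a fix and the previous *kept* fix (fixes are nominally
12 h apart); comparing against kept-only fixes is a documented choice
where the convention is ambiguous.

## Activity, bouts and phenology

Days are UTC civil days (the logger clock); a complete day satisfies
wet + dry = 24 h exactly because the 0–200 count encoding is conservative.
A flight bout is a maximal run of intervals with count < 200 bounded by
fully wet intervals — the finest definition the 10-min integration
supports — so mean bout duration approximates, rather than equals,
per-flight minutes; bouts are dated by their midpoint, which breaks exact
per-day bout/budget agreement only for runs spanning midnight. The 12-h
phenology rule uses a persistence window of N = 3 days against single
stormy days; N = 1 reproduces the literal first-crossing rule. Daily SST
is the mean ± sample SD of all wet-triggered readings that day; a single
reading has an undefined (NaN) SD by convention, and empty days are
absent, not zero.

The winter-arrival date used for season segmentation is the first kept fix
within 250 km of the individual's winter centroid sustained for two
consecutive fixes. The natural alternative — first entry into the assigned
region's bounding box — is degenerate for NE birds, whose box boundary
(45°N) lies a few days from the colony.

## Winter ranges

Positions are projected with a spherical Lambert conformal conic
(standard parallels 25°/45°N, origin 40°N/75°W — low distortion over the
NW Atlantic; the projection family is conventional, the parameters are
ours). The LCV bandwidth maximises the leave-one-out log predictive
density, coarse log-grid search refined by bounded minimisation;
coincident-point degeneracy falls back to a reference bandwidth with a
warning. The KDE grid defaults to 10 km cells, refining to h/2 when the
bandwidth is small, padded 5h so the utilization mass closes to ~10⁻⁶.
The 50 % contour thresholds density where cumulative sorted cell mass
reaches 0.5 (the minimal-area half-mass region).

Region boxes: GM = lon < −81° and 18° ≤ lat < 31°; SE = lon ≥ −81° and
lat < 34°; NE = 34° ≤ lat ≤ 45°. The source description of GM ("west of
Florida (east of 81°W)") is self-contradictory; west of 81°W matches the
geography and is what we implement. Assignment is by centroid by default;
assigning by 50 %-range majority is possible from the same objects.

## Energetics

Mechanical power follows the standard Pennycuick decomposition with the
model family's usual defaults, none of which the source study restates
(it delegates them to the Flight software): induced-power factor k = 1.2,
body drag coefficient 0.1, body frontal area 0.00813·Mb^0.666 m²,
ρ = 1.23 kg m⁻³, g = 9.81 m s⁻². Profile power is X₁·P_am with
X₁ = 8.4/aspect-ratio. Chemical power adds respiration overhead R = 1.1
and BMR = 3.79·Mb^0.723 W outside the muscle-efficiency conversion
(E_fm = 0.3·Mb^0.137); the variant with BMR inside the R bracket is one
switch away (`bmr_in_chemical`) and lands within 1 W for this morphology,
so the printed anchors cannot discriminate them. With the study
morphology (3.03 kg, 1.83 m, 0.262 m²) these defaults give V_mp = 15.1
m s⁻¹, P_min = 83.9 W, V_mr = 23.2 m s⁻¹, P_mr = 102.0 W — i.e. 9.9× and
12.1× BMR — which is the calibration target; the flap:glide ratio 0.7 is
carried in `Morphology` and discounts profile power only when
`flap_glide=True`, because applying it by default would break those
anchors. Characteristic speeds come from golden-section/bounded
minimisation of P(V) and P(V)/V to 10⁻³ m s⁻¹; V = 0 is outside the
domain (induced power is singular).

Thermoregulation is linear conductive loss (0.93 J °C⁻¹ g⁻¹ h⁻¹, core
39 °C) times wet hours times body mass; SST at or above core temperature
is a domain error. Daily flight energy = dry hours × P_mr (migration
seasons) or P_min (otherwise). Seasonal cumulative energy is mean daily
cost × season duration, matching the aggregation that treats each season
as homogeneous. Swimming, diving and digestion costs are excluded by
scope.

## Survival

The CJS likelihood is the product multinomial over m-array release rows;
re-releases pool with new marks, and a detection at the final occasion is
not tabulated as a release (it carries no information — rows exist for
occasions 1…T−1 only). Parameters live on the logit scale; additive
(g+t) structures are additive there. Fits use L-BFGS-B from five seeded
starts. The AICc parameter count K is the numerical rank of the Jacobian
of all multinomial cell probabilities at the optimum — the
estimable-parameter convention. It automatically counts the confounded
terminal φ·p product once under full time dependence and drops
boundary-pinned parameters, reproducing the classic counts (15, 18, 31 …
for 9 occasions × 3 groups); note that boundary dropping makes K mildly
data-dependent, exactly as in mainstream software. Effective sample size
for AICc is total releases. Deviance is reported against the saturated
multinomial (ΔAICc is invariant to that constant). Profile CIs bracket
the deviance-rise-3.84 points by expansion plus Brent root-finding; a
side that never reaches the cutoff within ±25 logits is reported as the
0/1 boundary. Overdispersion ĉ = Σχ²/df is reported but fixed at 1 for
selection.

Goodness of fit implements the published descriptions of U-CARE's 3.SR,
3.SM, 2.CT and 2.CL per-occasion contingency tables, pooling columns with
expected counts < 2 and flagging untestable tables as df 0; directional
z statistics for transience and trap-dependence are Mantel–Haenszel-style
sums over the per-occasion 2×2 margins. Exact agreement with U-CARE's
internal pooling is not claimed.

## Synthetic cohort: what it emulates

The generator states one "world" and keeps it fixed:

* Strategy phenology: departures 3/10/13 Oct (SD 15/9/6 d), arrivals
  22/20/20 Apr (SD 6/5/5 d) for GM/SE/NE; transit 64/38/32 d per leg
  (SD 6/4/4). These make GM migration ≈ 2× NE's and GM winter ≈ ½,
  with near-equal total non-breeding duration. Net transit progress is
  ~50–75 km d⁻¹ — far below flight-hours × 58.4 km h⁻¹, because most
  daily flight is foraging, not displacement; the kinematic ceiling
  (min of 1,200 km d⁻¹ and flight capacity) is enforced as a rejection
  rule, not as the travel speed.
* Behaviour: migration flight 5.4 ± 0.8 h d⁻¹ and winter flight
  3.4/3.9/4.0 h d⁻¹ for GM/SE/NE (cohort mean ≈ 3.8, GM lowest by ~30
  min), split into ≈39 bouts d⁻¹; colony days have 15 ± 1 h dry. The
  within-day placement of flights is controlled by a `diurnal_bias`
  parameter (default 0.5 toward local midday) because the real diel
  structure is unknown.
* SST: a latitude × day-of-year sinusoid solved analytically so the
  colony breeding-coverage mean is 13 °C and the GM/NE winter-season
  means are 16 and 9 °C at the default winter latitudes (SE falls out at
  ≈13 °C); valid for ~18–50°N. Individual spread comes from per-strategy
  winter-site scatter (SD 1.2/1.5/2.0°) plus a 0.8 °C day-level anomaly
  and 0.3 °C sensor noise.
* Demography: annual survival 0.85, recapture 0.86, Bernoulli per
  interval/occasion; hatching success 45–100 % with shared good/bad
  years.
* Migration routes follow fixed offshore corridors (Cabot Strait, shelf
  edge, around Florida for GM) so tracks stay off the built-in land
  polygon; there is no weather, wind drift, ocean current, or individual
  heterogeneity beyond the stated SDs.

A green end-to-end test therefore establishes that the analysis chain
recovers the stated world's structure (timings, budgets, SST contrasts,
energetic patterns, survival rates) — not that it would do so under real
shading regimes, behavioural idiosyncrasy or sensor failure.

## Known limitations

* The real study's m-array (supplementary data) is not bundled; the
  model-selection table on real data is reproducible only after placing
  per-group CSVs under `data/s1_marray/`.
* Latitude accuracy degrades near the equinoxes by construction of the
  method; the pipeline relies on the equal-transit-time assumption for
  the spring leg, as the original analysis does.
* The land polygon is deliberately coarse; do not reuse it for distances
  below ~50 km.
* GOF component tests approximate U-CARE's pooling; ĉ from them should
  be read qualitatively.
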