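# Methods

This note documents the models, parameter choices and numerical conventions
behind `frostmap`, and what the synthetic-scene experiments do and do not
demonstrate about real imagery.

## Season window and day indexing

All curves live on a fixed daily window, canonically 1 March – 31 May
(92 days), chosen because winter wheat green-up ends in March, frost
sensitivity peaks in the April elongation–booting stages, and after
mid-May grain filling NDVI declines for physiological reasons that cannot
be separated from frost damage spectrally. Internally day indices are
0-based from the window anchor (index 33 = 3 April for a 1 March anchor);
report-facing layers print 1-based day labels. Date↔index conversion is
exact integer day arithmetic; no calendars beyond `datetime.date` are used.

## NDVI, gaps and smoothing

NDVI = (NIR − red)/(NIR + red). Negative reflectance, non-finite input or a
zero band sum flag the sample invalid (NaN) rather than raising — these are
per-pixel data defects in raster practice. Results are clamped to [−1, 1].

Cloud gaps are filled by linear interpolation in time between the nearest
valid days; leading/trailing gaps hold the nearest valid value; a pixel
with a single valid day becomes a constant series and a pixel with none is
unusable (error). The original validity mask is preserved as metadata.

Smoothing is Savitzky–Golay with a 7-day window and polynomial degree 2 —
the standard configuration for daily vegetation-index series; both are
configurable. Edge values come from the polynomial fitted to the first/last
full window evaluated at the edge positions (`scipy` `mode='interp'`); no
reflection padding. Consequences relied on by the tests: the smoother is
linear and reproduces polynomials up to its degree exactly over the whole
support, including edges.

## Reference curve (shape-model fitting)

A frost-year pixel has no observable normal trajectory, so the reference is
the multi-year mean curve `g` of frost-free years, rescaled onto the
smoothed frost-year curve:

    h(x) = sy · [ g(sx · (x + t0)) + bias ] − bias

The grouping — bias added before and subtracted after the magnitude
scaling — follows the shape-model-fitting lineage this transform comes
from; it makes `bias` a baseline-centring constant, and with sy = 1 the
transform is bias-independent (a tested invariant). The typeset form of
this equation is ambiguous in parts of the literature; the choice here is
deliberate and recorded once. `bias` = 0.61 for winter wheat, taken as a
fixed crop-specific constant.

Parameter box: sx ∈ [0.9, 1.1], sy ∈ [0.5, 1.85], t0 ∈ [−10, 10] days.
`g` at non-integer or out-of-window arguments is linearly interpolated with
constant extension beyond the ends.

Fitting minimises weighted RMSE (uniform weights by default; a weight
vector is injectable). The optimiser is deterministic: an exhaustive
lattice search at steps (0.01, 0.05, 1 day) including the identity point,
followed by bounded Nelder–Mead refinement accepted only when it does not
worsen the objective. Lattice ties break toward the identity, comparing
|sx−1|, then |sy−1|, then |t0|. There are no stochastic restarts, so fits
reproduce bit-for-bit without seeds. The returned fit is therefore never
worse than no transformation, and never worse than the lattice optimum.

A zero-variance target has no shape to match; the fit degenerates
gracefully with a warning rather than erroring.

### Region vs pixel fitting in the pipeline

The raster pipeline fits the shape model once per scene on regional curves
by default (`fit_mode="region"`) and applies the fitted parameters to every
pixel's multi-year mean; `fit_mode="pixel"` fits each crop pixel
independently (much slower; intended for small windows). Two robustness
choices matter here:

* the regional curves are per-day **medians** across crop pixels, not
  means, so a minority of frosted pixels cannot drag the frost-year target
  down (breaks down if more than half the crop area is frosted — a known
  limitation);
* when the meteorological onset date is known, days from onset to the
  shape model's peak get **zero weight** in the fit: the reference is a
  no-frost counterfactual, and fitting it through frost-contaminated days
  would absorb part of the damage signal into sy.

## Frost window and SFDI

The summation window starts at the meteorological onset date when a record
exists. Otherwise onset is detected as the first sustained decline of the
smoothed affected curve: a first difference below −0.005 NDVI/day
persisting ≥ 2 consecutive days (both configurable). The tolerance exists
because smoothing leaves correlated residual noise whose tiny negative
differences are not frost; real frost dips fall an order of magnitude
faster. The reported onset day is the first day observed *below* its
predecessor — the day the downward trend shows — not the pre-decline
maximum. Smoothing spreads a dip backward by up to half the filter window,
so detected onsets sit within about one day of truth (measured in the
acceptance run).

The window ends where the reference curve peaks (earliest day on ties);
past the peak, grain-filling senescence makes frost damage spectrally
indistinguishable. A peak preceding the onset is an error, as is no decline
with no record.

SFDI sums the daily reference-minus-observed gap over the inclusive
window. Days where the observed curve sits above the reference contribute
negative terms and are summed as-is by default (the literal summation);
`clip_negative_terms=True` floors daily terms at zero for users who prefer
a non-negative accumulation — the method's source is silent on this point.
SFDI is exactly additive over window partitions, zero for an unaffected
pixel, monotone in dip depth, and homogeneous of degree 1 in the curve
difference; all four are tested invariants.

## SASC

Score table: SFDI ≥ 16 → 1; 15 ≤ SFDI < 16 → 2; …; 1 ≤ SFDI < 2 → 16
(equivalently 17 − ⌊SFDI⌋ inside [1, 16)). SFDI below 1 is unscored and
treated as non-affected — the bins simply stop there, and the floor doubles
as the noise threshold.

Selection accumulates whole score classes in score order; among all
whole-class cutoffs *including the empty selection*, the one whose
cumulative crop-fraction-weighted area is nearest the official statistic
wins, ties going to the smaller selection. Optimality over all cutoffs is
verified against exhaustive enumeration in the tests. If even all scored
pixels fall short of the target, everything is selected with a warning.
`within_class=True` additionally refines the boundary class pixel by pixel
in descending-SFDI order while that improves the match; the default keeps
whole-class granularity.

Areas are in mu throughout (1 mu = 10⁴/15 m² ≈ 666.67 m²; a 500 m pixel is
exactly 375 mu), with hectare helpers. Projected grids use width × height;
geographic grids use the spherical zone formula
R²·Δλ·(sin φ_top − sin φ_bot) at the cell's latitude on a sphere of radius
6 371 007.181 m (the radius used by the sinusoidal land products this
pipeline emulates).

## Validation metrics

* Accuracy rate P = 100 · min/max of the two areas: symmetric, scale
  invariant, 100 at equality.
* Yield reduction = 100 · (normal-year mean − frost-year yield)/mean, with
  the baseline years supplied by the caller from meteorological records —
  no frost-year detection from yields themselves. Gains report as negative.
* Severity bands: none ≤ 0% < mild < 10% ≤ medium ≤ 30% < severe. The
  official band wording leaves 10–11% unassigned; since the affected-area
  definition is "loss above 10%", the boundary region goes to medium.
  Thresholds configurable.
* Regression of a covariate on SFDI is ordinary least squares
  (`scipy.stats.linregress`) reporting slope, intercept, R² and the
  two-sided slope p-value; R² equals the squared Pearson correlation in
  this simple-linear case (cross-checked in tests).
* The per-pixel severity *map* splits selected pixels at SFDI quantiles
  (defaults 0.5, 0.85). This is an exploratory rendering aid — SFDI has no
  absolute severity scale — and is not a yield-based classification.

## Synthetic scenes: what they emulate and what they don't

The generator produces everything the pipeline consumes: multi-year red/NIR
stacks, a crop-fraction raster, a frost record and a truth bundle.

* **Phenology** is a double logistic (baseline 0.35, amplitude 0.45,
  inflections at days 18 and 80, rates 0.15 and 0.12 per day), placing the
  seasonal NDVI peak in mid-late April — after the early-April frost window,
  as for winter wheat. Static per-pixel jitter on baseline, amplitude and
  inflection days stands in for soil, variety and management differences.
* **Inter-annual variability** applies one global scale-shift per year
  (sx within ±0.02, sy within ±0.05, t0 within ±2 days) — the same family
  the shape-model fit is designed to absorb, which is precisely the
  modelling assumption behind the reference-curve method.
* **Frost** hits a Bernoulli(0.3) pixel mask on day 33 (3 April) with dip
  depths uniform in [0.25, 0.5] NDVI recovering over 10 days as a linear
  vee. A vee of depth d integrates to 5d SFDI units on the daily grid, so
  every frosted pixel clears the lowest score bin (SFDI ≥ 1.25) and the
  frosted/clean separation is decided by the method, not by construction
  noise. An exponential-decay profile is also available.
* **Observation defects**: i.i.d. Gaussian NDVI noise (default σ = 0.01)
  and Bernoulli missing days (default 5%).
* **Bands**: NDVI inverts to reflectance via nir = 0.25(1+ndvi),
  red = 0.25(1−ndvi), so the index computation recovers the simulated NDVI
  exactly and band handling is tested without radiative-transfer modelling.

Not emulated: BRDF/atmospheric residuals, spatially correlated cloud
fields, mixed-pixel spectral mixing (crop fraction enters only as an area
weight), multiple frost events per season, non-wheat vegetation dynamics,
and real sinusoidal-grid geometry. Passing end-to-end tests therefore
demonstrates the internal consistency and statistical behaviour of the
chain under the stated noise model — not calibration against real MODIS
scenes, which requires the survey data the method is designed to consume.

All randomness flows from one `numpy.random.default_rng` seed; identical
seeds give byte-identical truth tables.

## Problem sizes

Default experiment sizes — 24×24 scenes, 92-day seasons, three reference
years, 50-seed recovery and optimality studies — keep the full test suite
and the acceptance script in the tens of seconds on a single CPU while
leaving every estimate comfortably clear of its acceptance margin. The
pipeline itself is vectorised over pixels (the per-pixel fit mode being the
deliberate exception) and scales linearly in pixels × days.

## Known limitations

* One frost event per season; one crop. SFDI accumulates any NDVI
  depression in the window, so drought or disease in the same window would
  be attributed to frost.
* SASC inherits the official statistic's error: the map's *area* is only as
  good as the survey, and only the ranking comes from remote sensing.
* Region-mode fitting assumes a minority of the crop area is frosted (the
  median regional curve) and one climate zone per scene; per-zone targets
  require running the pipeline per zone.
* The default uniform fit weights are replaced by frost-window masking only
  when an onset record exists; without any record, a long shallow dip can
  bias the fitted sy slightly downward.
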