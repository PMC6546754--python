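# Methods

## Scope and data model

`phenotrend` studies growing-season timing (SOS/EOS, day of year) and its
decadal trends on two data streams: gridded NDVI composites and daily
flux-tower GPP. All calendars are 365-day years without leap days;
day-of-year is 1-based; a year is divided into K composites (default 24),
composite k covering days ⌈365(k−1)/K⌉+1 … ⌈365k/K⌉ and timestamped at
the window midpoint. Interval windows are inclusive on both ends.

## Seasonal curve

The per-year seasonal cycle is the difference of two logistics,

y(t) = a + b·(1/(1+e^{c(t−d)}) − 1/(1+e^{e(t−f)})),  c<0, e<0, d<f,

so y → a in the dormant season and y → a+b on the plateau. A sum of two
rising logistics cannot produce both of those limits simultaneously; the
difference form is the parameterisation under which "a is the background"
and "a+b is the maximum" both hold, and is what the package fits and
simulates.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trf)
with an analytic Jacobian, bounds a∈[−0.2,1], b∈(0,1.5], c,e∈[−1,−0.005],
d∈[1,180], f∈[150,365], initial values a=min, b=max−min, c=e=−0.1 and
d/f at the first/last half-amplitude crossings of the raw samples, at
most 500 function evaluations. Non-convergence, amplitude ≤ 0.05, or a
violated invariant (d ≥ f) yields an invalid fit, never an exception.
On noise-free 24-composite samples the fit recovers the generating
parameters to better than 10⁻³ relative.

## NDVI phenology retrieval

A Savitzky–Golay filter (window 9 composites, order 2, single pass; both
configurable) is applied along time before retrieval; interior gaps are
linearly interpolated first. Methods 1–4 operate on the fitted curve
evaluated on a 1-day grid:

* **Method 1** — extrema of y″ on each limb, refined sub-day by parabolic
  interpolation. Closed forms d ± ln(2+√3)/|c| (and mirrored on the
  autumn limb) hold for well-separated limbs and are the test oracle;
  fits with f − d < 30 days are rejected as overlapping. The four
  landmarks (green-up onset, maturity onset, senescence onset,
  dormancy onset) are returned in that order.
* **Method 2** — extrema of y′: SOS = d, EOS = f for separated limbs.
* **Methods 3/4** — first upward / last downward crossing of the
  normalized curve (y − min)/(max − min) at ratio 0.2 / 0.5, located by
  linear interpolation on the daily grid, before/after the annual
  maximum.
* **Method 5** — thresholds are taken from the multi-year mean cycle
  where its relative change rate NDVI_RC = (NDVI(t+1) − NDVI(t))/NDVI(t)
  attains its maximum (SOS) and minimum (EOS). Two numerical choices
  matter here. First, RC is evaluated on a daily densification of the
  mean cycle obtained from its double-logistic fit (linear interpolation
  as fallback): on the raw 15-day composite grid the RC extrema lock
  onto sampling knots, so the threshold values — and hence the retrieved
  dates — would depend on the sampling phase rather than on the curve,
  breaking translation equivariance. Second, the per-year degree-6
  polynomials are fitted over balanced transition windows — from 45 days
  before green-up onset (2 % of cycle amplitude) to one composite past
  plateau entry (90 %), mirrored in autumn, widened away from the
  transition when fewer than 7 composite points fall inside — rather
  than over literal half-years: a degree-6 polynomial asked to represent
  a flat background, a steep limb *and* a long plateau overshoots the
  limb by ~0.04 NDVI, which shifts threshold crossings by 2–3 days;
  restricted to the balanced window the crossing error stays below one
  day at composite resolution. Dates are the interpolated threshold
  crossings of the polynomials evaluated daily. Cells whose mean cycle is non-positive
  anywhere (RC undefined) or constant (no unique extrema) are invalid.

Cells are retained when mean NDVI ≥ 0.1 (boundary inclusive) and
latitude ≥ 30°N. The cross-method "mean" estimate averages the valid
per-method dates of a cell-year and requires at least 3 valid methods
(configurable). Hemisphere series are unweighted annual means over valid
cells; cos-latitude weighting is available behind a flag — on synthetic
grids with spatially uniform phenology statistics the two coincide in
expectation, and the reference analysis does not state a weighting.

## Flux (GPP) phenology

A year of daily GPP is smoothed with a Gaussian-weighted moving average
(window 15 days, σ = 4 days, weights renormalised within the window so
constants are preserved at the edges). Gaps up to 30 consecutive days are
linearly interpolated; longer gaps invalidate the year. The threshold is
a fixed fraction (default 15 %) of the maximum smoothed GPP over all
usable years of the site. SOS is the first day of a run of at least 5
consecutive days at/above the threshold; EOS is the first day of the last
run of at least 5 consecutive days below it. The persistence rule (not
stated in the reference description) suppresses noise-induced crossings;
5 days is short relative to the season but long relative to daily noise.
Years with relative seasonal amplitude (max − min)/max < 0.3 are invalid
— an operational stand-in for the qualitative exclusion of evergreen
sites. Sites qualify when at least 7 years have ≥ 75 % good-quality daily
data (both boundaries inclusive).

Because the crossing is reported as an integer day and the Gaussian
smoother shifts an exponential tail by about rate·σ²/2 (~1 day on a slow
autumn limb at σ = 4), noise-free recovery of the continuous latent
crossing is accurate to ~2 days, not to the day; the recovery tests are
set accordingly. The threshold-sensitivity scan repeats the retrieval for
fractions 4–30 % in steps of 2 % on both GPP variants and reports the
mean over years of the between-variant standard deviation.

## Trend statistics

Mann–Kendall: S = Σ_{i<j} sign(y_j − y_i); var(S) carries the standard
tie correction Σ t(t−1)(2t+5); z = (S∓1)/√var(S) with continuity
correction (0 when S = 0); p is the two-sided normal tail; tau-b
normalises S by the tie-adjusted pair counts. The normal approximation is
used at all n (documented small-sample bias below n ≈ 10); the windows of
interest have n ≈ 17, where the empirical type-I error at α = 0.05 is
within [0.03, 0.07]. Slopes are Theil–Sen with the joint-median intercept
median(y − slope·x). Missing values are dropped, never interpolated.
Segmented analysis splits at an imposed breakpoint year that belongs to
both windows (mirroring period labels like 1982–1998 / 1998–2014);
windows with fewer than 4 usable values are flagged invalid. A
sensitivity grid recomputes the trend over every candidate
(start, end) window.

## Attribution

Monthly meteorology is aggregated to climatological seasons, with winter
of year Y spanning Dec(Y−1)–Feb(Y); state variables (TA, TS, VPD, SW_IN,
SWC) are averaged, precipitation and carbon fluxes summed. A season is
missing if any month is missing or has a QC fraction below 0.75 — the
stricter per-month reading of the QC rule, chosen so a single bad month
cannot leak into a seasonal mean. Associations are Pearson r
(pairwise-complete deletion, n ≥ 5) with two-sided t-based p; SOS is
examined against spring and winter drivers, EOS against summer and
autumn. Partial correlations control each driver for the others of the
season and use listwise-complete years (n ≥ n_vars + 3); they are
computed from the inverse correlation matrix, with the recursive
elimination formula retained as an independent route that must agree to
10⁻¹⁰. Census summaries classify per-site trends by slope sign and
cumulative significance class (p < 0.05 ⊂ p < 0.1); exact-zero slopes are
excluded from both directions and reported separately.

## Simulator

The generator draws everything from one `numpy.random.default_rng(seed)`
stream, so identical configurations are bit-identical. Grid cells share a
piecewise-linear SOS/EOS trajectory — baseline + slope_pre·(year−start)
up to the breakpoint year, continuing at slope_post — plus independent
N(0, noise_sd_pheno) jitter per cell-year; NDVI is sampled at composite
midpoints with additive N(0, noise_sd_ndvi) noise clipped to [0, 1].
Default trend magnitudes are the hemisphere-scale reference values
(SOS −0.337/−0.020, EOS +0.256/−0.027 days yr⁻¹ before/after 1998);
default curve shape a = 0.2, b = 0.5, c = −0.15, e = −0.12 — a temperate
deciduous seasonal cycle. An exact count round(frac_nonveg · n_cells) of
cells is flat (NDVI < 0.1). Flux sites scale the same curve shape to
gpp_max (default 10 g C m⁻² day⁻¹, a productive temperate canopy), emit
two GPP variants whose noise terms share a common component (correlation
0.95, standing in for the two flux-partitioning estimates), and derive
ER = 0.6·GPP + 0.5 and NEE = ER − GPP exactly. Seasonal air-temperature
anomalies (sd 1 °C) shift SOS by −3 days/°C and EOS by +2 days/°C by
construction, giving the attribution stage a known target. QC flags mark
a configured fraction of days good per year; gaps remove a configured
fraction of days at random.

What the simulator does **not** emulate: sensor artifacts (orbital drift,
calibration steps, snow/cloud contamination), gap-filling or u*-filtering
of real flux data, spatially correlated climate fields, asymmetric or
double-peaked seasons, and disturbance. Passing tests therefore
demonstrate correctness of the estimators and statistics under the
stated generative model, not robustness to every pathology of real
archives.

## Problem sizes and tolerances

The bundled demo and the acceptance checks use desk-scale problems chosen
to exercise every code path: 200–400-cell grids over 33 years (the
reference record length), 10–50 flux sites of 15 years, 20 replicate
seeds for trend recovery, 1000 replicates for test calibration. Closed
form vs numerical landmark agreement is asserted at 0.5 day (sub-grid
parabolic refinement is good to ~0.01 day); method-vs-oracle agreement at
1 day (the evaluation grid step); trend-statistic oracle agreement at
10⁻¹²; slope recovery at ±0.10 days yr⁻¹ of the injected −0.34 (the
sampling spread of a 17-year Theil–Sen window at 1-day jitter).

## Known limitations

* The Mann–Kendall normal approximation is anticonservative for n < 10.
* Method 5 requires a strictly positive mean cycle; winter NDVI ≤ 0
  invalidates the cell (real boreal winters can dip below 0).
* The GPP crossing is day-quantized; sub-day precision would require
  interpolating the smoothed series.
* No autocorrelation correction (prewhitening) is applied to the trend
  tests, and no formal change-point detection is performed — the
  breakpoint year is imposed, which is the design of the segmented
  analysis, not an inference about where the series breaks.
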