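# Methods

## Observation-day grid

All series are cut into observation days running 17.00 → 16.55 (+1 day)
local civil time: a boundary chosen so each row contains one continuous
night, which is where the temperature maximum falls. At the 5-minute
individual cadence a day has 288 slots; outdoor 3-minute series are
regridded to the same 5-minute grid by nearest-reading selection so both
source classes share one window engine. Readings snap to the nearest slot
centre, exact halfway ties to the earlier slot; when two readings contend
for one slot the reading closest to the centre wins. Civil time is used as
logged; sampling weeks surround solstices and equinoxes, away from DST
transitions, so the 23/25-hour civil days never occur inside a session.
Trailing partial days are kept for time-of-day averaging but excluded from
daily AUC totals.

## Light metrics

Illuminance is log10-transformed with readings under the loggers' 10 lux
detection limit floored to 0 log10lux: darkness then contributes zero
exposure and log(0) never arises, and the 10 lux floor maps to exactly 1.
Exposure over a window is the trapezoidal integral of the slot values
against minutes. The day is treated as a closed 24 h cycle — the
1440-minute endpoint reuses slot 0's value — so a constant 1 log10lux day
integrates to exactly 1440 log10lux·min and the four fixed 6 h windows
tile the day additively. Windows whose clock bounds straddle 17.00
integrate across the grid boundary within the same observation day; since
solar events drift under a minute per day this is chronologically
equivalent to using the adjacent calendar day's sunset, and it behaves
correctly both in summer (sunset after 17.00) and winter (sunset before).
The "approximate hour of sunset" bound of the daytime window rounds sunset
to the whole clock hour; other solar bounds round to the nearest slot.

Missing light data: interior gaps of at most 30 minutes are bridged by the
trapezoid between flanking observed slots; edge gaps of at most 30 minutes
shrink the window; anything longer makes that window's AUC missing for the
day (never zero). Cohort dispersion is summarized as the relative standard
error, reported in percent: 100·(sd/√n)/mean.

## Temperature phase

Order of operations: mask → filter → impute → smooth → max.

* **Masking.** Readings outside 29.5–38.5 °C become missing (the bounds
  themselves are kept; the rule is strictly "less than"/"greater than").
  Out-of-range readings are interpreted as device removal.
* **Filter.** A day is kept iff its missing fraction is strictly below
  28%: 80/288 missing is kept, 81/288 dropped.
* **Imputation.** Predictive mean matching on the pooled kept-day matrix
  (rows = days, columns = slots), mirroring mice's rows-as-observations
  layout. For each slot column, observed values are regressed on the
  day's nearest observed readings to the left and right (circular within
  the day); each missing cell is filled with the observed value of a
  donor drawn uniformly from the k = 5 rows with the closest predicted
  means, under a fixed seed. A first-harmonic time-of-day pair adds
  nothing here — within a column, time of day is constant and collinear
  with the intercept — so the predictors are intercept plus the two
  flanks. Observed values are never altered; a column with no observed
  values anywhere is an error.
* **Smoothing.** A natural cubic smoothing spline in the Reinsch
  formulation, penalty chosen per day by generalized cross-validation
  (GCV = n·RSS/(n − tr S)²) over a wide log-spaced λ grid, with the
  Demmler–Reinsch eigendecomposition cached per grid so a day costs two
  matrix–vector products. This selector matches R's `smooth.spline`
  behaviour; on noiseless cosines it reproduces the input to <0.05 °C and
  under iid noise of sd 0.3 °C it recovers known acrophases with a mean
  absolute error near 0.2 h. scipy's `make_smoothing_spline` GCV was
  measured to undersmooth for this purpose (phase MAE ~0.67 h under the
  same conditions), which is why the smoother is implemented here.
* **Phase.** The arg-max of the smoothed curve, ties to the earliest
  slot, in decimal observation hours (slot·5/60; 19.45 clock → 2.75 h).
  Resolution is one slot, 1/12 h.

## Cluster analysis

Light and temperature day-rows are stacked into identically gridded
matrices and analysed as abstract spatial grids (no geographic meaning;
matrix edges are true edges, with no wraparound between rows). "Eight
orders of queen contiguity" is read cumulatively: a cell's neighbours are
all cells within Chebyshev distance 8, row-standardized — the ring-only
reading would disconnect adjacent readings and is rejected. Because the
cumulative queen ball is a square, spatial lags are computed with
summed-area tables in O(cells). The statistic is Iᵢ = z_x,i · Σⱼ wᵢⱼ z_y,j
with both matrices z-standardized over all cells (global standardization;
per-row was considered and rejected as it erases the day/night contrast
the map is meant to show). Significance uses conditional permutation —
each cell's neighbour values redrawn from all other cells, two-sided
p = (#{|I*| ≥ |I|}+1)/(n_perm+1) — with defaults α = 0.05 and
n_perm = 999 for the library function; the pipeline's default run uses
n_perm = 199 on a 24-row subsample to keep a full run interactive, both
exposed in `RunConfig`. No multiplicity adjustment is applied, following
standard LISA practice; the labels are descriptive, not inferential.
Labels at significant cells come from the sign pair (z_x, lag z_y):
(+,+) high-high, (−,−) low-low, (+,−) high light/low temperature, (−,+)
low light/high temperature.

## Inference

Seasonal comparisons use Tukey's HSD via the exact studentized-range
distribution (Tukey–Kramer for unbalanced groups), applied to daily AUC
values pooled across participants within season; with two groups it
reduces to the two-sample t-test to ~1e-16. The phase model is plain OLS
on participant-season means — no random effects, matching the design of
one averaged row per participant-season. Season enters as indicators with
winter as reference; only seasons present in the data get a dummy, and a
rank-deficient design raises an error naming the involved terms. AICc is
computed from the Gaussian log-likelihood with k = coefficients + 1
(error variance), the R MuMIn convention; candidates default to all eight
subsets of {morning, night, season}, with ties broken by declaration
order. `predict_shift` exposes the raw linear contract
shift = β_night·Δnight + β_morning·Δmorning; the "one hour earlier"
worked examples are reported under both readings of the dim endpoint
(0 and 1 log10lux), since "dim" is bounded only as <1 log10lux.

## Synthetic cohort

The generator emulates the study conditions rather than any real
participant: an urban site at 40.85° N where outdoor illuminance follows a
solar-elevation curve peaking at 10³–10⁵ lux (lit vs shaded sites) with
sub-10-lux light pollution after sunset; participants with 09.00–17.00
indoor plateaus of 100–500 lux, dim mornings, evening light-at-night of
30–1000 lux until a per-participant bedtime, and bright outdoor-style
weekend days with probability 0.6; per-season cohort sizes 18/16/15/12
with 7 days each, and two-week outdoor sessions (9 days by default).

Wrist temperature is a cosine (mesor 33.5 °C, amplitude 1.5 °C — inside
the 29.5–38.5 °C masking range) whose daily acrophase follows the pure
phase-shift mechanism φ_d = 8 + β_night·AUC_night(d) + β_morning·
AUC_morning(d) + N(0, 1.5 h), with β_night = 0.0056 and β_morning =
−0.0042 h per log10lux·min and both AUCs computed from the same realized
light series the pipeline later ingests. The base acrophase of 8
observation hours (01.00 clock) places unperturbed peaks in the
00.00–03.00 band. Exposure acts on the same observation day's peak (the
standardized night window 21.00–02.00 precedes the post-midnight peak
within that day); which night acts on which peak is configurable but this
convention is the default. High-frequency variation is AR(1) noise
(ρ = 0.7, sd 0.3 °C). Device handling appears at two scales: short
artifact runs (30–120 min of out-of-range values, rate 0.25/day) that the
masking-imputation path must absorb, and long removals (7–16 h, rate
0.2/day) that push days over the 28% filter — yielding ~80% day survival,
the attrition scale of real wrist-logger deployments. A `truth.csv`
sidecar records each day's realized acrophase and AUCs so extraction error
is directly measurable.

What the generator does **not** emulate — so passing tests say nothing
about these aspects of real data: rhythm-shape distortion as an
alternative to phase shifts; sleep/activity masking effects on skin
temperature; sensor occlusion by sleeves; weather; the empirical lux
distribution within a day (profiles are piecewise-stylized); day-to-day
habit correlation beyond fixed participant traits; and it does not force
individual total exposure below outdoor exposure in every season (its
indoor plateau plus evening light can out-integrate a short winter
photoperiod in log units).

## Problem sizes and numerical choices

The default cohort (61 participant-seasons, 427 days) runs the full
pipeline in a few seconds; the Moran stage subsamples 24 day-rows at
n_perm = 199 by default. The end-to-end recovery study uses 50
participants × 4 seasons (200 participant-season rows) per replicate and
30 replicates in the test suite (20 in the acceptance script), chosen as
the smallest design that pins mean coefficient bias to a few percent with
Monte-Carlo error well below the 15% band being checked. Tolerances:
trapezoid-vs-oracle 1e-6 relative; Moran-vs-brute-force 1e-12 absolute;
spline constants to 1e-8; OLS noiseless recovery to 1e-8. Degenerate
inputs fail loudly by design: zero-variance Moran matrices, all-missing
imputation columns, windows with fewer than two resolvable slots, groups
of size one in Tukey, and saturated AICc designs (n − k − 1 ≤ 0) all raise
named errors rather than returning numbers.

## Known limitations

Phase resolution is bounded by the 5-minute grid (1/12 h). Under strongly
autocorrelated noise GCV undersmooths (a known property of
cross-validation with correlated errors), inflating phase-extraction
error from ~0.2 h to ~0.9 h MAE; this propagates as extra residual noise,
not bias, and the recovery study covers exactly this regime. The Moran
permutation test treats cells as exchangeable under the null, ignoring
within-row autocorrelation, as is standard for LISA maps — its labels
should be read descriptively. Circular wrap of acrophases near the
observation-day boundary can, very rarely, place a generated peak just
past 24 h, which reads back as a near-zero timing; at the default
parameters this affects well under 1% of days.
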