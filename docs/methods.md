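# Methods

## The model

During the ice-covered season of a shallow seasonal lake, dissolved
heavy-metal concentrations beneath the ice develop a characteristic
C-shaped vertical distribution: solute rejection from the growing ice
enriches the water just below the ice–water interface, pore-water
exchange at the sediment enriches the bottom, and the middle layer stays
comparatively dilute. `underice` models one metal's profile at one
sampling date as a sum of two exponentials in depth *h* (cm, measured
downward from the ice–water interface):

    HM(h) = a · e^{b·h} + c · e^{d·h}

with amplitudes *a*, *c* (μg/L) and rates *b*, *d* (1/cm). For
*a*, *c* > 0 and *b* < 0 < *d* the profile is convex with a unique
interior minimum at

    h* = ln(−a·b / (c·d)) / (d − b),

which is the closed form used by `profile_minimum` and checked in the
tests against a 0.001 cm grid search. The model is symmetric under
swapping the two terms, so all fitted parameters are reported in the
canonical ordering *b* ≤ *d*; without this convention the stage-2
regression below would be corrupted by label switching between dates.

Each of the four characteristic parameters is assumed to evolve linearly
with freeze duration *t* (days since the lake surface began freezing):

    Y(t) = α·t + β,   Y ∈ {a, b, c, d}.

Identification is two-stage least squares: (1) a bounded nonlinear
least-squares fit of (*a*, *b*, *c*, *d*) per metal per sampling date;
(2) an ordinary least-squares line per parameter through the per-date
estimates. Composing the two stages reconstructs the concentration
surface HM(*h*, *t*) on any depth × time lattice (`reconstruct_surface`),
with no additional smoothing. An optional one-shot joint refinement of
all eight coefficients against all samples exists (`refine_evolution`)
but is off by default; the reference procedure is strictly two-stage.
Metals are fitted independently; nothing is shared across metals.

### Assumptions

* The profile family is the biexponential above; no polynomial or spline
  alternatives are offered.
* Parameter evolution is linear in *t* over the sampling window; the
  model is not meant to extrapolate far outside it.
* Fits are unweighted (homoscedastic in absolute concentration); no
  per-depth weights are applied.
* Depth is measured from the ice–water interface in cm; concentrations
  in μg/L; ice thickness in mm; time in days.

## Numerical choices

* **Optimizer.** `scipy.optimize.least_squares` (trust-region
  reflective) with bounds *a*, *c* ≥ 0 and *b*, *d* ∈ [−0.5, 0.5] 1/cm.
  The rate bound keeps e^{rate·h} within sane floating-point range over a
  0–150 cm column and is configurable (`FitOptions.rate_bound`).
* **Multi-start.** A fixed 2 × 2 grid of rate starts, b₀ ∈ {−0.1, −0.02}
  and d₀ ∈ {0.02, 0.1}, covering the decay/growth magnitude patterns of a
  C-shaped profile. Amplitude starts come from a log-linear split: the
  top third of the profile seeds the first term and the bottom third the
  second, each scaled so its term alone reproduces that third's mean at
  its mean depth. The best converged residual wins. On 360 noisy
  synthetic fits the chosen start never produced a residual above that of
  the generating parameters.
* **Tolerances.** `ftol = xtol = gtol = 1e-12`, at most 500 function
  evaluations per start. The tight tolerances matter because the
  stage-2 slopes of the rate parameters are of order 10⁻⁵ per day: to
  recover them to 0.1% the per-date rates must be accurate to ~10⁻⁶.
  With these defaults the zero-noise pipeline recovers all coefficients
  to ~10⁻¹² relative.
* **Degenerate inputs.** A constant profile is representable
  (*b* = *d* = 0) and fits with essentially zero residual. Fits require
  at least 6 samples (4 parameters plus 2 degrees of freedom); the
  stage-2 regression requires at least 3 distinct sampling times, and all
  times identical raises a degenerate-design error. Sample order within
  a profile is normalised on construction, so fits are order-invariant.
* **Tie-breaks.** Canonical ordering swaps terms when *b* > *d*; exact
  ties (*b* = *d*) are left as-is. Depths exactly 15 cm from either end
  of the column go to the outer (upper/lower) layer. The stage
  boundaries are inclusive on the left stage (Feb 2 is rapid, Mar 2 is
  stable, for the default season).

## Baseline smoothers

Two generic comparison predictors are provided. Both smooth each date's
depth series independently and are scored at the observed points (the
time direction is left untouched).

* **Moving average**: centred window of odd span (default 3 points,
  i.e. 15 cm of column); at the series ends the window is truncated to
  the available neighbours, so the first point averages two values.
  A span of 1 is the identity.
* **Dyadic wavelet smoothing**: orthogonal DWT (default Daubechies-4)
  with symmetric extension for non-dyadic lengths, decomposition level
  ⌊log₂ n⌋ − 2 (minimum 1, default n = 30 ⇒ level 2), and one of three
  detail rules: `universal-soft` (default; soft threshold at
  σ̂·√(2 ln n), with σ̂ from the MAD of the finest details),
  `approx-only` (details zeroed), or `none` (perfect reconstruction).
  The defaults are the standard denoising recipe; family, level, rule and
  span are all configurable.

## Stratification statistics

Layers are positional: the top and bottom 15 cm of the under-ice water
column are the upper and lower layers, the rest is the middle. The
column depth may be supplied per date, since the water column shrinks as
ice thickens. A (metal, date) profile is classified **C-shaped** when
its middle-layer mean is strictly below both the upper and lower means.
Ice stages are calendar-bounded: rapid growth up to Feb 2 (inclusive),
stable growth to Mar 2 (inclusive), melting afterwards, all configurable.
Dates outside a configured freeze season get an `off-season` sentinel and
a warning rather than an error. Stage-change arithmetic reports the
difference (previous − current), the signed percent change, and the
fold-decrease (previous / current).

## Error metric

The per-metal score is the mean absolute relative error in percent
against the measured values, aggregated jointly over all dates and
depths. It is scale-invariant and undefined when any observed value is
non-positive (such rows are rejected). A relative-RMSE variant is
available behind the `metric` switch.

## The synthetic-data generator

The generator emulates the statistical structure of the study design,
not its physics: 8 sampling dates (freeze-duration days 64, 77, 91, 96,
106, 113, 123, 130 for a Nov 1 onset, i.e. Jan 4 – Mar 11), 30 layers at
5 cm spacing with depths at layer midpoints (2.5, 7.5, …, 147.5 cm), and
nine metals (As, Cd, Cr, Cu, Fe, Hg, Mn, Pb, Zn). Ground truth is an
exact two-stage model, so the full pipeline is an unbiased recovery
problem with known answers.

* **Magnitudes.** Each metal's amplitudes scale with a realistic
  surface-level concentration (As 5.90, Cd 0.12, Cr 8.07, Cu 4.92,
  Fe 0.75, Hg 0.33, Mn 0.07, Pb 1.21, Zn 0.36 μg/L), matching published
  layer-mean levels for a heavily monitored seasonal lake.
* **Shape.** Default rates b(t) ≈ −0.015 → −0.019 1/cm and
  d(t) ≈ 0.0075 → 0.0088 1/cm (with a ±10% per-metal shape factor) keep
  every metal's interior minimum between 50 and 100 cm over the whole
  window — the middle layer is always the dilute one. Amplitudes grow
  ~30% over the season, mirroring the concentration effect of ice growth.
* **Noise.** Multiplicative Gaussian: each record is the surface value
  times (1 + ε), ε ~ N(0, cv), default cv = 0.05, resampled (not
  clipped) where a draw would make the concentration non-positive.
  Multiplicative noise matches the relative scale on which such
  measurements are reported; replicate analyses of this kind are quoted
  at better than 10% relative error, so a 5% CV is a realistic choice.
* **Ice.** Thickness is piecewise linear through four knots — 267.41 mm
  (day 48, monitoring start), 492.30 mm (day 93, end of rapid growth),
  569.76 mm (day 121, seasonal maximum) and 542.65 mm (day 130) — with
  the middle knots doubling as the stage boundaries.
* **Determinism.** All randomness flows from a single
  `numpy.random.default_rng(seed)` drawn in a fixed metal-major order;
  a fixed seed gives byte-identical datasets and, because the pipeline
  itself contains no randomness, byte-identical artifacts.

What the generator does **not** emulate: vertical correlation of
measurement errors, non-biexponential fine structure (thermocline kinks,
nepheloid layers), date-to-date deviations from linear parameter
evolution, censoring at detection limits, and the shrinking of the
sampled column as ice thickens (profiles always span 150 cm). Passing
tests therefore demonstrate correctness of the estimation machinery on
data that satisfies the model's assumptions, not the model's adequacy
for any particular lake.

## Problem sizes used in tests and the acceptance run

Unit tests run a 3-metal zero-noise pipeline (720 records); the
acceptance checks run the full design (9 × 8 × 30 = 2160 records) once
noise-free for parameter recovery and ten times at cv = 0.05 (seeds 1–10)
for the method comparison. One full pipeline takes a few seconds on one
CPU; the whole comparison about half a minute.

## Known limitations

* **In-sample scoring favours interpolating smoothers.** The error
  report scores every method at the very points the baselines smooth.
  With independent multiplicative noise, any prediction that is
  uncorrelated with the noise — including the exact ground-truth
  surface — has a mean-relative-error floor of cv·√(2/π) (≈ 3.99% at
  cv = 0.05), while a span-3 centred average retains one third of each
  point's own noise and scores ≈ cv·√(2/3)·√(2/π) ≈ 3.26%. Under these
  conditions the smoothing baselines will typically *out-score* the
  C-type model even when the model is exactly right, so the error table
  should be read as agreement-with-measurements, not as out-of-sample
  predictive skill. Held-out scoring (e.g. leave-one-date-out) would
  rank a correct model first, but is not part of the reference procedure
  implemented here.
* The two-stage estimator propagates per-date fit noise into the
  evolution lines; at 5% noise, per-metal model errors of 4–10% against
  the observations are typical for ill-conditioned biexponential fits.
* The linear evolution law has no mechanistic content; it is a
  within-season description.
* The wavelet default level for 30-point profiles is 2; shorter series
  (n < 16) are smoothed at level 1, where boundary effects dominate.
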