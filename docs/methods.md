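# Methods

## The response model

`filmcal` models the sensitometric curve of radiographic film (XV-class
film read on a laser scanner) with the single-target single-hit model:
one ionising event per silver-halide grain suffices to render it
developable, so the developed-grain fraction is `1 − e^(−R)` with `R`
proportional to dose. Because the scanner is linear in optical density
over the working range, the same saturation exponential holds directly in
pixel value:

```
P(D) = P0 + Ps · (1 − e^(−m·D/Ps)),      D(P) = −(Ps/m) · ln(1 − (P−P0)/Ps)
```

Conventions that matter:

- **`Ps` is net**: the saturation pixel value *above* background, so the
  total signal tends to `P0 + Ps`. All bundled and fitted values use this
  convention.
- Pixel values are real-valued ROI averages, never integer counts.
- `m` is exactly the initial slope `dP/dD|₀` (counts/cGy). It factorises
  as `m = mE(E, FS, d) · mFP(FP)`; the processing factor `mFP` varies
  day to day, the energy/geometry factor `mE` does not.
- Dose is cGy everywhere; there is no unit layer.
- Inversion refuses pixels within 1e-9 (relative to `Ps`) of saturation
  rather than returning a huge dose: the scanner-saturation regime is
  outside the model's validity.

The model intentionally excludes the microscopic grain picture (grain
area, intrinsic sensitivity), dose-rate (Schwarzschild) effects, scanner
nonlinearity/saturation correction, and phantom-material dependence.

## Fitting

The objective is unweighted least squares on pixel residuals: readout
noise is roughly proportional to `P`, but over the narrow 16–128 cGy
calibration range the weighting difference is negligible.

- **Full fit** — `scipy.optimize.least_squares` with box constraints
  (`Ps, m > 0`; `P0 ∈ [0, min pixel]` when floated). `P0` is fixed to the
  measured background film when present (≥3 points); floating `P0` needs
  ≥4 points. Initialisation: `m₀` from the secant through the
  lowest-dose net pixel, `Ps₀ = 1.2 ×` max net pixel — this keeps the
  implied response fraction below 1 from the first iteration.
  Convergence: `xtol = ftol = 1e-10`, ≤200 iterations per free parameter.
- **Exactly-determined cases** are never sent to the optimiser. One
  point/one unknown uses the closed form
  `m = −(Ps/D)·ln(1 − (P−P0)/Ps)`; the two-point/two-unknown system of
  Method III eliminates `m` and solves the monotone scalar equation
  `Ps·(1 − (1 − y₁/Ps)^(D₂/D₁)) = y₂` by Brent bracketing. This makes
  the reduced-point methods deterministic to machine precision.
- **Two-point slope fits** (Methods I/II with 2 points) minimise over `m`
  alone with `minimize_scalar(bounded)`, bracketed by 0.5–2× the
  per-point closed-form slopes.
- **Identifiability**: if the fitted curve's maximum probed response
  fraction `m·D_max/Ps` is below 0.02 the data never leave the linear
  toe, `Ps` is unconstrained, and an `UnidentifiableError` is raised
  instead of returning an arbitrary large `Ps`. Exactly proportional
  two-point data raise the same; super-linear data are infeasible for a
  saturation model. Positivity violations raise, never clip silently.
- **Batch two-step fit**: every film of a batch is fitted freely
  (background-subtracted), the batch-optimal `Ps` is the plain mean of
  the fitted values excluding any film flagged as the 8-field reference
  (its `Ps` is systematically depressed by inter-subfield scatter
  cross-talk and scanner non-uniformity), then each film's `m` is refit
  with `Ps` pinned.

Datasets sort their points by dose on construction, so all fits are
order-invariant; duplicate doses, non-positive doses and non-monotone
pixels are rejected at construction.

## Calibration transfer

Same-day slope ratios `m_standard / m_8field` cancel `mFP`, leaving a
ratio that depends only on field size and depth; together with the
standard/8-field saturation ratio (1.083 ± 0.5% for the bundled system)
one reference curve derives the curve of any tabulated geometry:
`P0' = P0`, `Ps' = Ps·ps_ratio`, `m' = m·m_ratio(FS, d)`.

The m-ratio table is user-supplied data — no numeric table ships because
the underlying per-geometry values are instrument-specific; the package
instead ships the physical plausibility check (ratios within
[0.99, 1.05], decreasing with depth in the sub-0.5 cm build-up region,
increasing beyond). Lookup is exact-key by default; linear interpolation
in depth at fixed field size is opt-in and never extrapolates, since no
interpolation rule is established for these ratios.

Curve agreement is always quantified as **local dose error**: invert the
truth curve's pixel value through the test curve and report the relative
dose difference. The default grid is 1 cGy steps over [10, 150] cGy;
below 10 cGy relative errors are background-dominated (absolute
differences ~0.1 cGy) and are reported separately when needed. Grid
points outside the test curve's invertible range are flagged and excluded
from the maximum with a warning rather than aborting.

## Uncertainty

First-order propagation of the dose inversion gives
`(σ_D/D)² = c_Ps(σ_Ps/Ps)² + c_m(σ_m/m)² + c_P(σ_P/P)² + c_P0(σ_P0/P0)²`
with logarithmic-sensitivity weights evaluated at a response fraction
`f = (P−P0)/Ps`:

- `c_m = 1` identically (`∂D/∂m = −D/m`);
- `c_Ps = (1 + [f/(1−f)]/ln(1−f))²` → 0.196 at `f = 0.5`;
- `c_P`, `c_P0` use the *total* pixel value and the background
  respectively as scales (2.75 and 0.047 at midrange for the mean curve),
  matching how readout and background uncertainties are quoted.

The conventional rounded weights (0.25, 1, 3, 0.05) are the default in
`propagate_analytic` and reproduce the ~2% 1-sigma total for the default
budget (0.5%, 1%, 1%, 0.5%); exact weights from
`propagation_coefficients` are one call away and differ by <0.1
percentage point at midrange. Every term enters squared — a quadrature
sum is the only dimensionally consistent first-order combination, and the
only one consistent with the ~2% total (a linear saturation term would
roughly double it). The systematic/random split is (`Ps`, `m`) vs
(`P`, `P0`): curve parameters are fixed per batch/day, readout and
background fluctuate per measurement.

The Monte-Carlo cross-check perturbs `Ps`, `m`, `P0` and the observed
pixel by independent Gaussian relative errors (no parameter covariance is
modelled — none is available from the fits as used), inverts each draw,
and reports the sample SD with a 200-resample bootstrap CI. Draws outside
the invertible range are rejected; >1% rejections abort because the
truncated SD would be biased. For combining a systematic bound with an
expanded random error, `combine_systematic_random` reports both the
additive and the quadrature total, endorsing neither convention.

## Variation analysis

Ensemble statistics use the sample (n−1) SD — ensembles are small (7–12
films). The dose-spread statistic takes every unordered pair of curves in
*both* directions (either member may act as the truth curve; no reference
is privileged) and reports the maximum |local dose error| over the grid,
by default [10, 128] cGy.

## Synthetic data

The generator's defaults are the study conditions of the bundled
reference system: mean curve (245, 3271, 31.7); inter-day relative SDs
(1.8%, 5.7%, 7.7%) for (P0, Ps, m); intra-day (1.8%, 0.8%) for (Ps, m);
1% Gaussian relative readout noise; dose schedule
{16, 24, 32, 48, 64, 80, 96, 128} cGy — the published range is 16–128 cGy
with eight subfields, the specific interior values are this package's
choice and are configurable. Parameter perturbations are independent
across parameters and days. Draws violating positivity are redrawn
(logged); configurations rejecting >10% of draws are refused.

The 8-field image is a 2×4 grid of 3×3 cm² subfields with 1 cm gaps and
border at 0.123 mm pitch (243 px per subfield edge, floor of 30/0.123).
Pixel coordinates are row-major, origin top-left, position = index ×
pitch with half-open footprints; an ROI averages pixels whose centres lie
in the half-open square, so 1.23 mm and 12.3 mm ROIs cover exactly 10×10
and 100×100 pixels. Optional `crosstalk` adds a fraction of each adjacent
subfield's dose before evaluating the model — a deliberately crude
stand-in for inter-field scatter that reproduces its one observable
consequence, a depressed fitted `Ps` on 8-field films. Noise is Gaussian
and relative, not Poisson: scanner counts here are post-processed
averages. Images serialise as 16-bit single-channel TIFF with the pitch
and layout in the description tag.

Because the generator draws from the model itself with independent
Gaussian noise, passing tests demonstrate correctness of the estimators
and the pipeline plumbing — not robustness to real-film artefacts
(spatial nonuniformity, correlated processing drift, scanner glare),
which the generator does not emulate.

## Problem sizes

Default test and validation sizes are chosen to make sampling error
negligible relative to the asserted tolerances while staying quick:
noiseless-recovery sweeps use 100 random curves; noise-bias checks
300–400 replicates; Monte-Carlo cross-checks 10⁵ draws with a 3×
bootstrap-SE acceptance band; ensemble-recovery checks 200 independent
12-film ensembles against two-sided 95% χ²₁₁ intervals (asserting
coverage, since individual samples legitimately fall outside).

## Known limitations

- Validity is limited to XV-class film with a linear-OD scanner; other
  film/densitometer combinations need their own response model or
  transfer characterisation.
- The universal saturation value fails when a batch deviates by more than
  ~5% (the bundled geometry-3 case, 9% low, shows >5% dose error);
  Method III is the fallback.
- Fit uncertainties are not propagated from the least-squares Hessian;
  the budget takes component uncertainties as inputs.
- The m-ratio table carries no uncertainty model beyond the ±1% quoted
  for its measurement.
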