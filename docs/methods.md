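# Methods

## Physical model

### Excitation

Objective-type TIR illumination at incidence `theta_i` beyond the critical
angle `theta_c = arcsin(n_s/n_i)` produces an evanescent field of
penetration depth `d = lambda0 / (4 pi sqrt(n_i^2 sin^2 theta_i - n_s^2))`.
Scattering in the optics adds a component that is effectively constant over
the sub-micron TIRF range, so the excitation profile is modelled as
`I(z)/I0 = alpha e^(-z/d) + (1 - alpha)` with `alpha` the evanescent
fraction (typically 0.85–0.92 in objective-type setups). `alpha` is a
configuration input, not estimated from data.

### Emission near the interface

A fluorophore within ~one wavelength of the coverslip does not radiate
like a free dipole: its near field couples into propagating substrate
modes beyond the critical angle (supercritical-angle fluorescence, SAF),
and the interference of direct and reflected waves restructures the
sample-side pattern. `emission_model` implements the standard
angular-spectrum treatment of a point dipole at height `z` in the sample
medium above a semi-infinite substrate: the dipole field is decomposed
into plane waves, each transmitted/reflected with Fresnel coefficients,
and the far-field power density is obtained by stationary phase in both
half-spaces. Supercritical substrate modes carry the weight
`exp(-2 kappa z)` with `kappa = sqrt(k_rho^2 - k_s^2)`, which is the
physical origin of the extra z-contrast the method exploits.

Verification is dual-route: the far-field quadrature over both
half-spaces is compared in the test suite against the classical
mode-expansion (local-density-of-states) integral for the total
dissipated power — an unrelated formula — and agrees to ~1e-9 relative;
the free-space limit (`n_i -> n_s`) reproduces the sin^2 dipole pattern,
and the collection integrals are cross-checked against 100x-finer
brute-force integration of the same integrands.

### Collected fluorescence and its normalization

`CF(z)` is defined as the power a *fixed-amplitude* dipole radiates into
the collection cone `theta <= arcsin(NA/n_i)` of the objective (through
the glass), normalized to the same quantity for a molecule far from the
interface (reference height `10 lambda_em`). This includes the
interface modification of the total emitted power, i.e. it is collected
*power*, not collection *efficiency* (collected/total). The distinction
matters: only the fixed-amplitude definition reproduces the reference
exponential calibration (`d_F ~ 87 nm`, `alpha_F ~ 0.92–0.93` for the
NA 1.42 / 670 nm configuration); the efficiency variant yields
`d_F ~ 107 nm` and a visibly poorer exponential approximation. The
efficiency variant remains available via
`collection_fraction(..., efficiency=True)` for comparison.

The isotropic average for a fluorophore that rotates faster than both
its excited-state lifetime and the frame time uses power weights
2 (parallel) : 1 (perpendicular); averaging the per-orientation
normalized ratios instead changes `d_F` by < 0.1 nm.

### Exponential calibration

`F(z) = I(z)/I0 * CF_avg(z)`, normalized to `F(0) = 1`, is fitted with
the constrained two-parameter form `alpha_F e^(-z/d_F) + (1 - alpha_F)`
on a 0.5-nm grid over [0, 250] nm. The fit minimizes residuals of
`log F`: the response spans about a decade, the axial inversion error is
governed by the relative (not absolute) residual, and the log-domain fit
distributes it evenly across the range. For the reference configuration
(642 nm excitation at 69.5 deg, n_i = 1.517, n_s = 1.33, alpha = 0.9,
NA = 1.42, emission 670 nm) this gives `d_F = 86.1 nm`,
`alpha_F = 0.919`, with a maximum inversion discrepancy of 0.74 nm below
150 nm and 2.6 nm below 250 nm. A linear-domain fit on the same grid
gives `d_F = 84.9 nm`, `alpha_F = 0.915` and roughly twice the
deep-range discrepancy; the choice affects nothing downstream except
through those two constants.

The exact response is tabulated to 350 nm (beyond the 250-nm fit range)
so that exact-curve inversions that overshoot the TIRF range stay on the
sampled curve.

## Pipeline conventions

* Coordinates in nm, frames 0-based; pixel-unit tables require an
  explicit pixel size (133 or 160 nm are common camera configurations).
* Trace linking chains detections in strictly consecutive frames within
  20 nm (configurable); no gap frames, nearest candidate wins, ties are
  broken deterministically by distance then table order.
* Frame filtering drops the first and last record of every trace and
  entire traces shorter than three frames; partial-exposure frames
  otherwise bias counts low and z high.
* Illumination correction multiplies counts by `P_ref / P(x, y)`;
  `P_ref` defaults to the profile maximum and must match the location
  where `N0` was calibrated — a mismatch translates directly into a
  field-dependent z offset.
* Counts at or below the asymptote `(1 - alpha_F) N0` cannot be
  inverted and are flagged invalid. Counts above `N0` give nominal
  z < 0 and are kept but flagged (`clip_negative=True` clips them to 0
  instead, appropriate for samples known to sit at the coverslip, and
  avoids asymmetric truncation of the count distribution at z ~ 0).
* `N0` estimation is a plain normal fit to filtered, corrected counts
  of surface-adsorbed labels (no outlier trimming); the angle
  calibration is an ordinary least-squares fit of lateral spot drift vs
  axial stage travel, `theta_i = arctan(slope)`, with the standard
  error propagated through the arctangent.

## Sensitivity analyses and known model deviations

Miscalibration errors are evaluated by generating signals with the true
exact response and inverting with the wrong assumption.

* **N0.** A +10% overestimate of `N0` displaces molecules upward by
  8.7 nm at z = 0, 12.7 nm at 150 nm and 20.6 nm at 250 nm
  (exact-generate / exact-invert pathway; the closed-form inversion of
  the exponential gives 9.0 nm at z = 0). The corresponding reference
  values from the FDTD-based calibration are 8.5 / 11.0 / 18.1 nm. The
  discrepancy tracks a single cause: this analytic model has a slightly
  shallower supercritical tail than the FDTD reference (the modes just
  beyond the critical angle decay arbitrarily slowly, and their weight
  depends delicately on the far-field treatment), and the sensitivity
  at z scales with `1/(d ln F/dz)`, which amplifies the tail difference
  where the response flattens. At z = 0 the two models agree.
* **alpha.** Misjudging the non-evanescent fraction `1 - alpha`
  (true 10%) by up to ±12% relative (assumed 8.8–11.2%) accumulates at
  most 4.1 nm of axial-span distortion over a structure occupying
  [0, 150] nm and 13.5 nm over [0, 250] nm. Misreading the *absolute*
  value by ±2 points (assumed 8% or 12%) costs 6.9 and 23.8 nm
  respectively — under every inversion pathway, including an emulation
  with the reference calibration constants themselves, which is why the
  relative reading is the one implemented in `scripts/acceptance.py`.
  The deep-range value again exceeds the reference (~10 nm) because of
  the tail-slope difference above.
* **theta_i.** Enters only through `d`; the angle-calibration fit
  propagates its standard error, and `sigma_dF` feeds the precision
  model.

The test suite asserts the reference sensitivity values at their stated
tolerances; the two comparisons affected by the tail difference
(mislocalization at z = 150/250 nm, deep-range alpha distortion) fail
them by 0.2–3.3 nm and are left failing rather than loosened.

## Synthetic data

The generator emulates what the pipeline consumes, not the raw movies:
binding events pick an emitter uniformly, last a geometric number of
full frames (mean 6 by default — long enough that frame filtering
leaves >= 1 record per typical event) flanked by partial frames with
uniform(0, 1) exposure; per frame the detected count is
`normal(N0 F(z) P/P_ref * exposure, c sqrt(mean))` truncated at one
photon, with `c = 5` by default (the empirically observed
over-dispersion of EM-CCD counts with fast blinking; `c = 1` is the
shot-noise floor); lateral positions get 5-nm Gaussian noise.
Concurrent events on one emitter merge into a single record with summed
counts, as they would on the camera. Defaults give per-emitter duty
cycles below ~1%, typical of DNA-PAINT.

Not emulated: PSF shape and fitting (and hence photon-count estimation
errors correlated with position), drift, triplet/bleaching photophysics,
non-Gaussian EM-CCD noise, axially varying background. Passing the
end-to-end tests therefore shows that the decoding chain is correct and
self-consistent at realistic noise levels — not that those instrument
effects are harmless.

Phantom recoveries at the defaults (N0 = 51,000, c = 5): a plane at
100 nm returns its median height within 3 nm; a 41-nm cylinder,
circle-fitted on per-event (trace-median) cross-section points, returns
its diameter within 4 nm; a 59-nm double ring returns its separation
within 3 nm. Cross-section circle fits use the algebraic (Kasa) form,
whose noise bias (~2 sigma^2/diameter, about +0.8 nm here) is below
those tolerances; per-trace medians rather than raw records keep heavy
tails from the occasional corrupted trace out of the fit.

## Numerical choices

* Angular quadrature: Gauss–Legendre, 2000 nodes per half-space,
  substrate integral split at the critical and aperture angles so no
  panel straddles the SAF kink; convergence asserted against 100x-finer
  trapezoid integration (relative agreement ~1e-6, test threshold
  1e-3). High Gauss orders (>~4000) are avoided — node generation cost
  grows steeply — and unnecessary.
* Far reference height `10 lambda_em`; total power there differs from
  the free-dipole value by < 1e-4.
* Exact-curve inversion is linear interpolation on the 0.5-nm grid
  (the curve is strictly monotone; interpolation error << 0.01 nm);
  ratios outside the tabulated range clip to the grid ends.
* The grazing direction (theta = pi/2) is a removable singularity of
  the far-field formulas (emission exactly parallel to an interface
  vanishes for any index contrast); quadrature nodes never sit on it.
* Fits use `scipy.optimize.curve_fit` with bounds `d_F > 0`,
  `0 < alpha_F <= 1`, started at (90 nm, 0.9); the objective is convex
  enough in this regime that the start point is uncritical.

## Limitations

* Single interface only: no coverslip/oil multilayers, no metal films.
* The dipole is treated at the single emission-maximum wavelength; real
  emission spectra average CF over ~50 nm, a percent-level effect on
  `d_F`.
* The precision formula is a first-order bound in `sigma_N` and
  `sigma_dF` only; `N0` field inhomogeneity adds variability it does
  not capture.
* Axial positions are absolute only up to the accuracy of `N0` and the
  assumption that the label sits at the structure; label size (~5–10 nm
  for antibody stacks) is not modelled.
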