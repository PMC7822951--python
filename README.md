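# simpler-tirf

Photometric axial localization of single molecules in a total internal
reflection fluorescence (TIRF) microscope — a calibrated implementation of
the SIMPLER method (supercritical illumination microscopy photometric
z-localization with enhanced resolution), for researchers doing 3D
single-molecule localization microscopy (DNA-PAINT, dSTORM, PALM) on an
unmodified TIRF setup.

## The idea

Under TIR illumination the excitation field decays exponentially away from
the coverslip,

    I(z) = alpha * I0 * exp(-z / d) + (1 - alpha) * I0,
    d    = lambda0 / (4 pi sqrt(n_i^2 sin^2(theta_i) - n_s^2)),

where `alpha` is the evanescent fraction (the rest is scattered,
non-evanescent light) and `d` the penetration depth. Close to the
glass–water interface, the *emission* of a fluorophore is also modified:
near-field coupling into supercritical angles of the glass makes the
objective collect more light from molecules near the coverslip. This
package computes that collected fraction, CF_avg(z), with an analytic
angular-spectrum model of a dipole above a planar dielectric interface
(Fresnel coefficients, supercritical-angle fluorescence included, isotropic
average for a rotating fluorophore).

The detected signal is then

    F(z) = I(z)/I0 * CF_avg(z),   normalized so F(0) = 1,

which over the TIRF range is well approximated by another exponential with
a steeper decay `d_F < d` and a smaller floor `1 - alpha_F`. Inverting it
gives the z estimator from a single photon count N per frame,

    z_hat = d_F * ln( alpha_F / (N/N0 - (1 - alpha_F)) ),        (z estimator)

anchored by `N0`, the photon count of an emitter at z = 0. The propagated
precision is

    sigma_z = sqrt( (d_F / (N - (1-alpha_F) N0))^2 sigma_N^2
                    + ln^2(alpha_F N0 / (N - (1-alpha_F) N0)) sigma_dF^2 ).

Around these two equations the package provides the full pipeline:
trace linking (consecutive-frame chaining within 20 nm), frame filtering
(drop first/last frames of each emission event; ignore events shorter than
three frames), illumination correction for non-uniform excitation,
sensitivity analysis for miscalibrated `N0`, `alpha` and `theta_i`, a
synthetic-data generator with ground-truth phantom geometries (plane,
41-nm microtubule cylinder, 59-nm double ring, 190-nm periodic lattice),
table I/O (CSV and Picasso-style HDF5), and rendering/circle-fit helpers.

## Worked example

```python
import numpy as np
from simpler_tirf import (OpticalConfig, axial_response, CalibrationBundle,
                          make_scene, simulate_traces, AcquisitionParams,
                          localize_table, trace_z_statistics)

config = OpticalConfig()            # 642 nm @ 69.5 deg, NA 1.42, 670 nm emission
response = axial_response(config)   # dipole model + excitation profile + fit
print(f"d      = {config.penetration_depth_nm:.1f} nm")
print(f"d_F    = {response.d_f:.1f} nm")
print(f"alpha_F = {response.alpha_f:.3f}")

bundle = CalibrationBundle.from_response(response)      # N0 = 51,000
scene = make_scene("plane", 50, seed=1, z0=100.0)       # flat layer at 100 nm
acq = AcquisitionParams(sigma_n_factor=5.0)             # sigma_N = 5 sqrt(N)
table = simulate_traces(scene, response, acq, seed=2, n_events=1200)
locs3d, stats = localize_table(table, bundle)
valid = locs3d[locs3d["valid"]]
print(f"kept {stats.n_after_filter} of {stats.n_in} localizations")
print(f"median z_hat = {np.median(valid['z_nm']):.1f} nm (truth: 100 nm)")
print(f"median per-trace sigma_z = "
      f"{trace_z_statistics(valid)['sigma_z_emp_nm'].median():.1f} nm")
```

prints

```
d      = 102.1 nm
d_F    = 86.1 nm
alpha_F = 0.919
kept 6962 of 9591 localizations
median z_hat = 100.1 nm (truth: 100 nm)
median per-trace sigma_z = 3.9 nm
```

The penetration depth of the reference configuration is 102 nm; the fitted
exponential calibration decays with 86 nm and a 8.1% floor; a simulated
flat layer at 100 nm with five-fold over-dispersed photon noise comes back
at its true height with ~4 nm per-event axial precision.

The same steps are available from the shell:

```
simpler calibrate --out calib.yaml
simpler simulate --geometry cylinder --n-events 3000 --seed 1 --out mt.csv
simpler localize mt.csv --calibration calib.yaml --out mt3d.csv
simpler sensitivity --n0-error 0.1 --alpha-assumed 0.88
simpler cf-table --na 1.42 --lambda-em 670 --out cf.csv
```

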