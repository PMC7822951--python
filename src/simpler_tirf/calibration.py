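"""Axial calibration of the photometric TIRF response.

The detected single-molecule signal at height ``z`` above the coverslip
is ``F(z) = I(z) * CF_avg(z)``: the evanescent-plus-constant excitation
profile times the orientation-averaged collected fluorescence of a
dipole near the interface.  ``F`` is normalized to 1 at the interface
and is well approximated over the TIRF range by a two-parameter
exponential

    F(z) ~ alpha_F * exp(-z / d_F) + (1 - alpha_F),

whose inverse (the z estimator) needs only ``d_F``, ``alpha_F`` and the
photon count ``N0`` of an emitter at z = 0.  This module builds that
calibration, plus the two experimental calibrations that feed it: the
incidence angle from stage-displacement data and ``N0`` from
surface-adsorbed emitters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import optimize, stats

from .config import OpticalConfig
from .emission_model import DEFAULT_NODES, cf_avg_curve

__all__ = [
    "AxialResponse",
    "AngleCalibrationData",
    "CalibrationBundle",
    "penetration_depth",
    "excitation_profile",
    "axial_response",
    "fit_exponential_calibration",
    "calibrate_angle",
    "estimate_n0",
]


def penetration_depth(config: OpticalConfig) -> float:
    """Evanescent penetration depth d (nm); requires theta_i > theta_c."""
    return config.penetration_depth_nm


def excitation_profile(config: OpticalConfig, z) -> np.ndarray | float:
    """Relative excitation intensity I(z)/I0 = alpha e^(-z/d) + (1 - alpha).

    The non-evanescent (scattered) component is treated as constant on
    the TIRF scale.  ``z`` in nm, non-negative.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("z must be non-negative")
    d = config.penetration_depth_nm
    out = config.alpha * np.exp(-z_arr / d) + (1.0 - config.alpha)
    return float(out) if np.isscalar(z) else out


def _exp_model(z, d_f, alpha_f):
    return alpha_f * np.exp(-z / d_f) + (1.0 - alpha_f)


def fit_exponential_calibration(
    z_grid: np.ndarray,
    f_exact: np.ndarray,
    log_domain: bool = True,
) -> tuple[float, float]:
    """Fit alpha_F e^(-z/d_F) + (1 - alpha_F) to the exact response.

    The fit is performed on log F by default: the response spans about
    a decade over the TIRF range and the axial inversion error is
    governed by the *relative* residual, which the log-domain fit
    distributes uniformly.  Requires >= 10 points; warns if the input
    is not monotonically decreasing.

    Returns ``(d_f, alpha_f)``.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    f_exact = np.asarray(f_exact, dtype=float)
    if z_grid.size < 10:
        raise ValueError("need at least 10 grid points for the calibration fit")
    if np.any(np.diff(f_exact) > 0):
        warnings.warn("response is not monotonically decreasing; fit may be poor")
    p0 = (90.0, 0.9)
    bounds = ([1e-3, 1e-6], [np.inf, 1.0])
    if log_domain:
        popt, _ = optimize.curve_fit(
            lambda zz, df, af: np.log(_exp_model(zz, df, af)),
            z_grid, np.log(f_exact), p0=p0, bounds=bounds, maxfev=20000,
        )
    else:
        popt, _ = optimize.curve_fit(
            _exp_model, z_grid, f_exact, p0=p0, bounds=bounds, maxfev=20000
        )
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class AxialResponse:
    """Sampled exact axial response and its exponential calibration.

    ``z_nm`` / ``f_exact`` sample F(z) (normalized to F(0) = 1) on an
    extended grid reaching past the fit range so that exact inversions
    that overshoot the TIRF range stay on the sampled curve.  The fit
    of the two-parameter exponential is restricted to
    ``z <= fit_range_nm``.
    """

    z_nm: np.ndarray
    i_rel: np.ndarray
    cf_avg: np.ndarray
    f_exact: np.ndarray
    d_f: float
    alpha_f: float
    fit_range_nm: float
    config: OpticalConfig = field(repr=False)

    @property
    def d_nm(self) -> float:
        """Penetration depth of the excitation field (nm)."""
        return self.config.penetration_depth_nm

    def f_at(self, z) -> np.ndarray | float:
        """Exact relative signal F(z) by interpolation."""
        return np.interp(z, self.z_nm, self.f_exact)

    def f_approx(self, z) -> np.ndarray | float:
        """Exponential approximation alpha_F e^(-z/d_F) + (1 - alpha_F)."""
        return _exp_model(np.asarray(z, dtype=float), self.d_f, self.alpha_f)

    def invert_exact(self, ratio) -> np.ndarray | float:
        """Invert the exact response: z such that F(z) = ratio.

        Values above F(0) = 1 or below F(z_max) are clipped to the grid
        ends (the response is strictly decreasing on the grid).
        """
        r = np.asarray(ratio, dtype=float)
        out = np.interp(r, self.f_exact[::-1], self.z_nm[::-1])
        return float(out) if np.isscalar(ratio) else out

    def invert_approx(self, ratio) -> np.ndarray | float:
        """Invert the exponential approximation (closed form)."""
        r = np.asarray(ratio, dtype=float)
        arg = self.alpha_f / (r - (1.0 - self.alpha_f))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.d_f * np.log(arg)
        return float(out) if np.isscalar(ratio) else out

    def approximation_gap(self, z_max: float) -> float:
        """max |z_hat_approx(F_exact(z)) - z| over [0, z_max] (nm)."""
        m = self.z_nm <= z_max + 1e-9
        zhat = self.invert_approx(self.f_exact[m])
        return float(np.max(np.abs(zhat - self.z_nm[m])))


def axial_response(
    config: OpticalConfig,
    z_grid: np.ndarray | None = None,
    fit_range_nm: float = 250.0,
    n_nodes: int = DEFAULT_NODES,
    cf_avg: np.ndarray | None = None,
) -> AxialResponse:
    """Build the complete axial calibration for an optical configuration.

    The default grid spans [0, 350] nm at 0.5-nm spacing; the
    exponential is fitted on [0, ``fit_range_nm``].  ``cf_avg`` may be
    supplied to reuse a precomputed collection curve on the same grid
    (it depends only on the emission-side parameters, not on the
    excitation profile).
    """
    if z_grid is None:
        z_grid = np.arange(0.0, 350.0 + 0.25, 0.5)
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid[0] != 0.0 or z_grid[-1] < fit_range_nm:
        raise ValueError("z_grid must start at 0 and cover the fit range")

    if cf_avg is None:
        cf_avg = cf_avg_curve(config, z_grid, n_nodes).cf_avg
    i_rel = excitation_profile(config, z_grid)
    f = i_rel * cf_avg
    f = f / f[0]

    m = z_grid <= fit_range_nm + 1e-9
    d_f, alpha_f = fit_exponential_calibration(z_grid[m], f[m])
    return AxialResponse(
        z_nm=z_grid,
        i_rel=i_rel,
        cf_avg=np.asarray(cf_avg, dtype=float),
        f_exact=f,
        d_f=d_f,
        alpha_f=alpha_f,
        fit_range_nm=float(fit_range_nm),
        config=config,
    )


@dataclass(frozen=True)
class AngleCalibrationData:
    """Paired stage displacements for the incidence-angle calibration.

    ``dz_um``: axial stage translations (µm), strictly increasing;
    ``dy_um``: lateral displacement of the excitation-spot centre (µm).
    """

    dz_um: np.ndarray
    dy_um: np.ndarray

    def __post_init__(self):
        dz = np.asarray(self.dz_um, dtype=float)
        dy = np.asarray(self.dy_um, dtype=float)
        object.__setattr__(self, "dz_um", dz)
        object.__setattr__(self, "dy_um", dy)
        if dz.size != dy.size:
            raise ValueError("dz and dy must have the same length")
        if dz.size < 3:
            raise ValueError("need at least 3 displacement pairs")
        if np.any(np.diff(dz) <= 0):
            raise ValueError("dz must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AngleCalibrationData":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(dz_um=arr[:, 0], dy_um=arr[:, 1])


def calibrate_angle(data: AngleCalibrationData) -> tuple[float, float]:
    """Incidence angle from the lateral drift of the excitation spot.

    Under TIR illumination an axial stage translation dz displaces the
    excitation-spot centre laterally by dy = m dz + c with
    arctan(m) = theta_i.  Ordinary least squares on the pairs gives the
    slope; the angle standard error is propagated through the arctan.

    Returns ``(theta_i_deg, theta_i_stderr_deg)``.
    """
    res = stats.linregress(data.dz_um, data.dy_um)
    m, se = res.slope, res.stderr
    theta = math.degrees(math.atan(m))
    se_deg = math.degrees(se / (1.0 + m * m))
    if m <= 0:
        warnings.warn(
            "non-positive slope: no lateral drift, incidence is not beyond "
            "the critical angle"
        )
    return theta, se_deg


def estimate_n0(photons) -> tuple[float, float]:
    """Photon count at z = 0 from surface-adsorbed emitters.

    ``photons`` are per-frame counts after frame filtering and
    illumination correction, from labels deposited directly on the
    coverslip.  Returns the normal-fit mean and the standard deviation
    as a fraction of the mean.  Requires >= 50 values.
    """
    x = np.asarray(photons, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 photon counts to estimate N0")
    mu, sd = stats.norm.fit(x)
    return float(mu), float(sd / mu)


@dataclass(frozen=True)
class CalibrationBundle:
    """Everything the z estimator needs, in serializable form."""

    config: OpticalConfig
    d_f: float
    alpha_f: float
    n0: float
    n0_rel_std: float = 0.0

    @classmethod
    def from_response(
        cls,
        response: AxialResponse,
        n0: float | None = None,
        n0_rel_std: float = 0.0,
    ) -> "CalibrationBundle":
        return cls(
            config=response.config,
            d_f=response.d_f,
            alpha_f=response.alpha_f,
            n0=n0 if n0 is not None else response.config.n0,
            n0_rel_std=n0_rel_std,
        )

    def to_dict(self) -> dict:
        c = self.config
        return {
            "lambda0": c.lambda0_exc,
            "lambda_em": c.lambda_em,
            "na": c.na,
            "n_i": c.n_i,
            "n_s": c.n_s,
            "theta_i_deg": c.theta_i_deg,
            "alpha": c.alpha,
            "d_nm": c.penetration_depth_nm,
            "d_f_nm": self.d_f,
            "alpha_f": self.alpha_f,
            "n0": self.n0,
            "n0_rel_std": self.n0_rel_std,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationBundle":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = OpticalConfig(
            lambda0_exc=d["lambda0"],
            lambda_em=d["lambda_em"],
            na=d["na"],
            n_i=d["n_i"],
            n_s=d["n_s"],
            theta_i_deg=d["theta_i_deg"],
            alpha=d["alpha"],
            n0=d["n0"],
        )
        return cls(
            config=cfg,
            d_f=d["d_f_nm"],
            alpha_f=d["alpha_f"],
            n0=d["n0"],
            n0_rel_std=d.get("n0_rel_std", 0.0),
        )
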