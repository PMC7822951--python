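"""Dipole emission near a planar glass-water interface.

Angular-spectrum (plane-wave decomposition) model of the far-field
radiation of a point dipole located at height ``z`` in the sample medium
(index ``n_s``) above a semi-infinite dielectric substrate (index
``n_i > n_s``).  Fresnel transmission at the interface couples the
near-field (evanescent) components of the dipole field into propagating
substrate waves beyond the critical angle — supercritical-angle
fluorescence (SAF) — with the characteristic exponential height
dependence.  The fraction of the emitted power that a high-NA objective
collects through the substrate therefore depends strongly on the
emitter height, which is one of the two physical ingredients of the
photometric axial response (the other being the evanescent excitation).

Conventions
-----------
* The emitter sits at ``(0, 0, z)``, ``z >= 0``, in the sample medium;
  the substrate fills the half-space below the interface at ``z = 0``.
* Substrate-side angles ``theta`` are measured from the downward
  normal, sample-side angles from the upward normal.
* All powers are expressed in units of the total power radiated by the
  same dipole in a homogeneous sample medium (the "free dipole"), so
  the full-sphere integral of the free-space pattern is 1.
* ``orientation`` is ``"parallel"`` (dipole axis in the interface
  plane, azimuthally averaged) or ``"perpendicular"`` (axis along z).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import OpticalConfig

__all__ = [
    "AngularPattern",
    "CollectionCurve",
    "angular_emission_pattern",
    "collection_fraction",
    "cf_avg_curve",
    "tabulate_cf",
    "radiated_powers",
]

ORIENTATIONS = ("parallel", "perpendicular")

#: default number of polar quadrature nodes per half-space
DEFAULT_NODES = 2000

#: far reference height for CF normalization, in units of lambda_em
Z_REF_FACTOR = 10.0


def _check_orientation(orientation: str) -> str:
    if orientation not in ORIENTATIONS:
        raise ValueError(
            f"orientation must be one of {ORIENTATIONS}, got {orientation!r}"
        )
    return orientation


@lru_cache(maxsize=32)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def _gauss_nodes(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights on [a, b]."""
    x, w = _leggauss(n)
    half = 0.5 * (b - a)
    return a + half * (x + 1.0), half * w


def _fresnel(kz1: np.ndarray, kz2: np.ndarray, n1: float, n2: float):
    """Fresnel amplitude coefficients for a wave incident from medium 1.

    ``kz1``/``kz2`` are the (possibly complex) normal wavevector
    components in medium 1 and 2.  Conventions: at normal incidence
    ``r_p = (n2 - n1)/(n2 + n1)`` and ``t_s = t_p = 2 n1/(n1 + n2)``.
    """
    rs = (kz1 - kz2) / (kz1 + kz2)
    ts = 2.0 * kz1 / (kz1 + kz2)
    e1, e2 = n1 * n1, n2 * n2
    rp = (e2 * kz1 - e1 * kz2) / (e2 * kz1 + e1 * kz2)
    tp = 2.0 * n1 * n2 * kz1 / (e2 * kz1 + e1 * kz2)
    return rs, rp, ts, tp


def _substrate_density(
    config: OpticalConfig, orientation: str, z, theta2
) -> np.ndarray:
    """Azimuthally averaged power per solid angle in the substrate.

    ``theta2`` is the polar angle from the downward normal in the
    substrate.  Broadcasts ``z`` against ``theta2``; output is in units
    of the free-dipole total power (full-sphere integral of the free
    pattern = 1).
    """
    n1, n2 = config.n_s, config.n_i
    k0 = 2.0 * math.pi / config.lambda_em
    k1, k2 = n1 * k0, n2 * k0
    z = np.asarray(z, dtype=float)
    theta2 = np.asarray(theta2, dtype=float)

    krho = k2 * np.sin(theta2)
    # normal component in the sample medium; +i branch beyond k1 (SAF)
    kz1 = np.sqrt((k1**2 - krho**2).astype(complex))
    kz2 = k2 * np.cos(theta2)
    _, _, ts, tp = _fresnel(kz1, kz2 + 0j, n1, n2)

    decay = np.exp(-2.0 * np.imag(kz1) * z)  # exp(-2 kappa z) for SAF modes
    geom = (n2 / n1) * (kz2**2) / np.abs(kz1) ** 2

    if orientation == "perpendicular":
        mod = np.abs(tp) ** 2 * (krho / k1) ** 2
    else:
        mod = 0.5 * (np.abs(ts) ** 2 + np.abs(tp) ** 2 * np.abs(kz1) ** 2 / k1**2)
    return geom * decay * mod / (8.0 * math.pi / 3.0)


def _sample_density(
    config: OpticalConfig, orientation: str, z, theta1
) -> np.ndarray:
    """Azimuthally averaged power per solid angle in the sample medium.

    ``theta1`` is the polar angle from the upward normal; the pattern is
    the interference of the direct and interface-reflected waves.
    """
    n1, n2 = config.n_s, config.n_i
    k0 = 2.0 * math.pi / config.lambda_em
    k1, k2 = n1 * k0, n2 * k0
    z = np.asarray(z, dtype=float)
    theta1 = np.asarray(theta1, dtype=float)

    krho = k1 * np.sin(theta1)
    kz1 = k1 * np.cos(theta1)
    kz2 = np.sqrt((k2**2 - krho**2).astype(complex))
    rs, rp, _, _ = _fresnel(kz1 + 0j, kz2, n1, n2)

    phase = np.exp(2j * kz1 * z)
    if orientation == "perpendicular":
        mod = np.sin(theta1) ** 2 * np.abs(1.0 + rp * phase) ** 2
    else:
        mod = 0.5 * (
            np.abs(1.0 + rs * phase) ** 2
            + np.cos(theta1) ** 2 * np.abs(1.0 - rp * phase) ** 2
        )
    return mod / (8.0 * math.pi / 3.0)


def radiated_powers(
    config: OpticalConfig,
    orientation: str,
    z,
    n_nodes: int = DEFAULT_NODES,
) -> dict[str, np.ndarray]:
    """Quadrature of the far-field pattern over both half-spaces.

    Returns a dict with arrays (broadcast over ``z``), all in units of
    the free-dipole total power:

    ``sample``
        power radiated into the sample half-space,
    ``substrate``
        power radiated into the substrate half-space,
    ``collected``
        substrate power within the objective cone
        ``theta2 <= arcsin(na / n_i)``,
    ``supercritical``
        substrate power beyond the critical angle (SAF),
    ``total``
        ``sample + substrate``.
    """
    _check_orientation(orientation)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z < 0):
        raise ValueError("emitter height z must be non-negative")
    zc = z[:, None]

    theta_na = math.asin(min(config.na / config.n_i, 1.0))
    theta_c = math.asin(config.n_s / config.n_i)

    def _integrate(density, a, b):
        if b <= a:
            return np.zeros(z.shape)
        th, w = _gauss_nodes(a, b, n_nodes)
        vals = density(zc, th[None, :])
        return 2.0 * math.pi * np.sum(vals * np.sin(th)[None, :] * w[None, :], axis=1)

    sub = lambda zz, th: _substrate_density(config, orientation, zz, th)
    sam = lambda zz, th: _sample_density(config, orientation, zz, th)

    # split the substrate integral at the critical and aperture angles so
    # the quadrature never straddles the SAF kink
    splits = sorted({0.0, theta_c, theta_na, 0.5 * math.pi})
    seg = {}
    for a, b in zip(splits[:-1], splits[1:]):
        seg[(a, b)] = _integrate(sub, a, b)

    substrate = np.sum(list(seg.values()), axis=0)
    collected = np.sum(
        [v for (a, b), v in seg.items() if b <= theta_na + 1e-15], axis=0
    )
    supercritical = np.sum(
        [v for (a, b), v in seg.items() if a >= theta_c - 1e-15], axis=0
    )
    sample = _integrate(sam, 0.0, 0.5 * math.pi)

    return {
        "sample": sample,
        "substrate": substrate,
        "collected": np.atleast_1d(collected),
        "supercritical": np.atleast_1d(supercritical),
        "total": sample + substrate,
    }


@dataclass(frozen=True)
class AngularPattern:
    """Far-field angular emission pattern at a fixed height.

    ``theta`` runs over [0, pi]: angles below pi/2 are sample-side
    (measured from the upward normal), angles above pi/2 map to
    substrate-side directions (``pi - theta`` from the downward
    normal).  ``density`` is the azimuthally averaged radiated power
    per unit solid angle in units of the free-dipole total power.
    """

    theta: np.ndarray
    density: np.ndarray
    orientation: str
    z_nm: float
    config: OpticalConfig = field(repr=False)

    def total_power(self) -> float:
        """Full-sphere integral of the pattern (trapezoid on the grid)."""
        return float(
            2.0 * math.pi * np.trapezoid(self.density * np.sin(self.theta), self.theta)
        )

    def substrate_power(self, n_nodes: int = DEFAULT_NODES) -> float:
        return float(
            radiated_powers(self.config, self.orientation, self.z_nm, n_nodes)[
                "substrate"
            ][0]
        )

    def sample_power(self, n_nodes: int = DEFAULT_NODES) -> float:
        return float(
            radiated_powers(self.config, self.orientation, self.z_nm, n_nodes)[
                "sample"
            ][0]
        )

    def supercritical_power(self, n_nodes: int = DEFAULT_NODES) -> float:
        return float(
            radiated_powers(self.config, self.orientation, self.z_nm, n_nodes)[
                "supercritical"
            ][0]
        )


def angular_emission_pattern(
    config: OpticalConfig,
    orientation: str,
    z: float,
    n_theta: int = 2001,
) -> AngularPattern:
    """Angular emission pattern of a dipole at height ``z`` (nm).

    The sample half-space pattern includes the interference of direct
    and interface-reflected waves; the substrate half-space pattern
    includes the supercritical-angle contribution fed by the dipole
    near field, which decays exponentially with ``z``.
    """
    _check_orientation(orientation)
    if z < 0:
        raise ValueError("emitter height z must be non-negative")
    theta = np.linspace(0.0, math.pi, n_theta)
    upper = theta <= 0.5 * math.pi
    density = np.empty_like(theta)
    density[upper] = _sample_density(config, orientation, z, theta[upper])
    density[~upper] = _substrate_density(
        config, orientation, z, math.pi - theta[~upper]
    )
    return AngularPattern(
        theta=theta, density=density, orientation=orientation, z_nm=float(z),
        config=config,
    )


def _z_ref(config: OpticalConfig) -> float:
    return Z_REF_FACTOR * config.lambda_em


def collection_fraction(
    config: OpticalConfig,
    orientation: str,
    z,
    n_nodes: int = DEFAULT_NODES,
    normalized: bool = True,
    efficiency: bool = False,
) -> np.ndarray | float:
    """Collected-fluorescence CF(z) for a fixed dipole orientation.

    By default CF(z) is the power a dipole of fixed amplitude radiates
    into the objective cone (through the substrate) at height ``z`` —
    the quantity obtained by integrating the angular emission pattern
    over the collection solid angle, interface-modified total emission
    included.  With ``normalized=True`` (default) it is divided by its
    value at the far reference height ``10 * lambda_em``, where
    interface effects are negligible, so CF -> 1 far from the
    interface.

    ``efficiency=True`` instead returns the collection *efficiency*
    (collected / total radiated at the same height), normalized the
    same way; this alternative convention is kept for comparison and
    does not reproduce the photometric calibration of a TIRF
    measurement (see the package methods note).
    """
    _check_orientation(orientation)
    scalar = np.isscalar(z)
    p = radiated_powers(config, orientation, z, n_nodes)
    cf = p["collected"] / p["total"] if efficiency else p["collected"]
    if normalized:
        pr = radiated_powers(config, orientation, _z_ref(config), n_nodes)
        ref = pr["collected"][0] / pr["total"][0] if efficiency else pr["collected"][0]
        cf = cf / ref
    return float(cf[0]) if scalar else cf


@dataclass(frozen=True)
class CollectionCurve:
    """CF(z) for both dipole orientations and the isotropic average.

    Each curve is the collected power of a fixed-amplitude dipole,
    normalized to the same quantity for a molecule far from the
    interface.  ``cf_avg`` is the orientation-averaged collected power
    (weights 2 parallel : 1 perpendicular, a fast-rotating emitter),
    normalized the same way.
    """

    z_nm: np.ndarray
    cf_parallel: np.ndarray
    cf_perpendicular: np.ndarray
    cf_avg: np.ndarray

    def cf_avg_at(self, z) -> np.ndarray | float:
        return np.interp(z, self.z_nm, self.cf_avg)


def cf_avg_curve(
    config: OpticalConfig,
    z_grid: Sequence[float] | np.ndarray,
    n_nodes: int = DEFAULT_NODES,
) -> CollectionCurve:
    """Orientation-averaged collection curve on ``z_grid`` (nm).

    Raises on an empty or unsorted grid.
    """
    z = np.asarray(z_grid, dtype=float)
    if z.size == 0:
        raise ValueError("z_grid must not be empty")
    if np.any(np.diff(z) < 0) or np.any(z < 0):
        raise ValueError("z_grid must be sorted and non-negative")

    zr = _z_ref(config)
    z_ext = np.concatenate([z, [zr]])
    par = radiated_powers(config, "parallel", z_ext, n_nodes)
    per = radiated_powers(config, "perpendicular", z_ext, n_nodes)

    def _norm(p):
        cf = p["collected"]
        return cf[:-1] / cf[-1]

    coll = 2.0 * par["collected"] + per["collected"]
    avg = coll[:-1] / coll[-1]

    return CollectionCurve(
        z_nm=z,
        cf_parallel=_norm(par),
        cf_perpendicular=_norm(per),
        cf_avg=avg,
    )


def tabulate_cf(
    na_list: Iterable[float],
    lambda_em_list: Iterable[float],
    z_grid: Sequence[float] | np.ndarray,
    config: OpticalConfig | None = None,
    n_nodes: int = DEFAULT_NODES,
) -> pd.DataFrame:
    """Tabulate CF_avg(z) for a grid of (NA, lambda_em) configurations.

    Returns a DataFrame with a ``z_nm`` column and one column per
    (NA, lambda) pair named ``CF_NA<na>_lam<lambda>``.  The usual TIRF
    range is NA 1.40-1.49 and emission 500-720 nm; values outside it
    are still computed, with a warning.
    """
    base = config or OpticalConfig()
    na_list = list(na_list)
    lambda_em_list = list(lambda_em_list)
    out = pd.DataFrame({"z_nm": np.asarray(z_grid, dtype=float)})
    for na in na_list:
        if not 1.40 <= na <= 1.49:
            warnings.warn(f"NA={na} outside the usual TIRF range [1.40, 1.49]")
        for lam in lambda_em_list:
            if not 500.0 <= lam <= 720.0:
                warnings.warn(
                    f"lambda_em={lam} nm outside the usual range [500, 720] nm"
                )
            cfg = base.replace(na=na, lambda_em=lam)
            curve = cf_avg_curve(cfg, z_grid, n_nodes)
            out[f"CF_NA{na:.2f}_lam{lam:.0f}"] = curve.cf_avg
    return out
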