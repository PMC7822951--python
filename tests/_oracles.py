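"""Independent brute-force oracles for the emission model.

Two routes that share no code with the implementation:

* :func:`dissipation_power` — the classical mode-expansion integral for
  the total power radiated by a dipole above a lossless dielectric
  interface (adaptive 1-D quadrature over the in-plane wavevector).
  For lossless media every dissipated photon is radiated, so this must
  equal the far-field quadrature over both half-spaces.
* :func:`collected_power_bruteforce` — direct trapezoid integration of
  the same Fresnel far-field integrands on a very fine angular grid,
  used to cross-check the fixed-order Gauss quadrature.
"""

import math

import numpy as np
from scipy.integrate import quad

from simpler_tirf.emission_model import _substrate_density, _sample_density


def dissipation_power(config, orientation: str, z: float) -> float:
    """Total radiated power in units of the free-dipole power."""
    n1, n2 = config.n_s, config.n_i
    k1 = 2.0 * math.pi * n1 / config.lambda_em
    e1, e2 = n1 * n1, n2 * n2

    def coeffs(s):
        sz = np.sqrt(complex(1.0 - s * s))
        if sz.imag < 0:
            sz = -sz
        kz2 = np.sqrt(complex((n2 / n1) ** 2 - s * s))
        if kz2.imag < 0:
            kz2 = -kz2
        rs = (sz - kz2) / (sz + kz2)
        rp = (e2 * sz - e1 * kz2) / (e2 * sz + e1 * kz2)
        return rs, rp, sz

    def f_propagating(t):  # s = sin t over [0, pi/2]
        s = math.sin(t)
        rs, rp, sz = coeffs(s)
        ph = np.exp(2j * k1 * sz * z)
        if orientation == "perpendicular":
            return (s**3 * rp * ph).real
        return (s * (rs - sz * sz * rp) * ph).real

    def f_evanescent(t):  # sz = i t, s = sqrt(1 + t^2)
        s = math.sqrt(1.0 + t * t)
        rs, rp, _ = coeffs(s)
        ph = math.exp(-2.0 * k1 * t * z)
        if orientation == "perpendicular":
            return ((s * s) * rp * ph / 1j).real
        return ((rs + t * t * rp) * ph / 1j).real

    t_evan = math.sqrt((n2 / n1) ** 2 - 1.0)
    if z > 0:
        t_evan += min(40.0, 20.0 / (2.0 * k1 * z))
    i1, _ = quad(f_propagating, 0.0, math.pi / 2, limit=500)
    i2, _ = quad(f_evanescent, 0.0, t_evan, limit=500)
    if orientation == "perpendicular":
        return 1.0 + 1.5 * (i1 + i2)
    return 1.0 + 0.75 * (i1 + i2)


def collected_power_bruteforce(
    config, orientation: str, z: float, n_theta: int = 200001
) -> float:
    """Substrate-cone power by fine trapezoid integration of the integrand."""
    theta_na = math.asin(config.na / config.n_i)
    th = np.linspace(0.0, theta_na, n_theta)
    dens = _substrate_density(config, orientation, z, th)
    return float(2.0 * math.pi * np.trapezoid(dens * np.sin(th), th))


def total_power_bruteforce(
    config, orientation: str, z: float, n_theta: int = 200001
) -> float:
    """Both-half-space power by fine trapezoid integration."""
    th_sub = np.linspace(0.0, 0.5 * math.pi, n_theta)
    th_sam = np.linspace(0.0, 0.5 * math.pi, n_theta)
    p_sub = 2.0 * math.pi * np.trapezoid(
        _substrate_density(config, orientation, z, th_sub) * np.sin(th_sub), th_sub
    )
    p_sam = 2.0 * math.pi * np.trapezoid(
        _sample_density(config, orientation, z, th_sam) * np.sin(th_sam), th_sam
    )
    return float(p_sub + p_sam)
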