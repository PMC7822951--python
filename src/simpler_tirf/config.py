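"""Optical configuration for a TIRF single-molecule experiment.

All lengths are in nanometres and angles in degrees at the API surface;
internal computations use radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and photometric parameters of a TIRF measurement.

    Parameters
    ----------
    lambda0_exc:
        Excitation vacuum wavelength (nm).
    lambda_em:
        Emission wavelength at the emission maximum (nm); the dipole
        emission model is evaluated at this single wavelength.
    na:
        Numerical aperture of the collection objective.
    n_i:
        Refractive index of the substrate / immersion medium (glass).
    n_s:
        Refractive index of the sample medium (e.g. 1.33 for water).
    theta_i_deg:
        Incidence angle of the excitation beam (degrees); must exceed
        the critical angle for total internal reflection.
    alpha:
        Evanescent fraction of the excitation intensity at the
        interface; ``1 - alpha`` is the non-evanescent (scattering)
        contribution, constant on the TIRF scale.
    n0:
        Detected photons per frame for an emitter at z = 0 under the
        calibration illumination (photometric anchor of the z scale).
    """

    lambda0_exc: float = 642.0
    lambda_em: float = 670.0
    na: float = 1.42
    n_i: float = 1.517
    n_s: float = 1.33
    theta_i_deg: float = 69.5
    alpha: float = 0.9
    n0: float = 51000.0

    def __post_init__(self) -> None:
        if self.n_s >= self.n_i:
            raise ValueError(
                f"total internal reflection requires n_s < n_i "
                f"(got n_s={self.n_s}, n_i={self.n_i})"
            )
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.na > self.n_i:
            raise ValueError(
                f"collection cone cannot exceed the substrate index "
                f"(na={self.na} > n_i={self.n_i})"
            )
        if self.lambda0_exc <= 0 or self.lambda_em <= 0:
            raise ValueError("wavelengths must be positive")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    @property
    def theta_c_deg(self) -> float:
        """Critical angle arcsin(n_s / n_i), degrees."""
        return math.degrees(math.asin(self.n_s / self.n_i))

    @property
    def theta_i_rad(self) -> float:
        return math.radians(self.theta_i_deg)

    @property
    def penetration_depth_nm(self) -> float:
        """Evanescent-field penetration depth d (nm).

        d = lambda0 / (4 pi sqrt(n_i^2 sin^2(theta_i) - n_s^2)); only
        defined for incidence beyond the critical angle.
        """
        arg = (self.n_i * math.sin(self.theta_i_rad)) ** 2 - self.n_s**2
        if arg <= 0.0:
            raise ValueError(
                f"no total internal reflection: theta_i={self.theta_i_deg} deg "
                f"is not beyond the critical angle {self.theta_c_deg:.3f} deg"
            )
        return self.lambda0_exc / (4.0 * math.pi * math.sqrt(arg))

    def replace(self, **kwargs) -> "OpticalConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})
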