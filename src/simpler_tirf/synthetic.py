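"""Synthetic DNA-PAINT / dSTORM acquisitions with known ground truth.

Emulates the statistical structure the decoding pipeline assumes:
multi-frame single-molecule emission events with partial first/last
frames, over-dispersed photon noise (sigma_N = c sqrt(N), with c ~ 5
for EM-CCD detection of fast-blinking emitters), lateral localization
noise, and a flat or Gaussian illumination profile, over ground-truth
geometries inspired by standard reference structures: a plane, a
microtubule-like cylinder, a nuclear-pore-like double ring, and a
spectrin-like periodic ring lattice.

It does not render camera images (localizations are generated
directly) and has no photophysics state model (on-times are
memoryless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import AxialResponse
from .io_render import IlluminationProfile

__all__ = [
    "SyntheticScene",
    "AcquisitionParams",
    "make_scene",
    "simulate_traces",
    "gaussian_illumination",
    "flat_illumination",
]

GEOMETRIES = ("plane", "cylinder", "double_ring", "periodic_rings")


@dataclass(frozen=True)
class SyntheticScene:
    """Ground-truth emitter positions (nm) for a phantom geometry."""

    positions: np.ndarray  # (n, 3) array of x, y, z in nm
    geometry: str
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_emitters(self) -> int:
        return self.positions.shape[0]


def make_scene(geometry: str, n_emitters: int, seed: int, **params) -> SyntheticScene:
    """Sample emitter positions from a phantom geometry.

    Geometries and their parameters (nm):

    ``plane``
        ``z0`` (height, default 0), ``extent`` (square side, 2000).
    ``cylinder``
        horizontal cylinder along x: ``radius`` (20.5, a 41-nm
        microtubule), ``axis_z`` (height of the axis, default
        radius + 50), ``length`` (2000).
    ``double_ring``
        two coaxial rings in xy: ``diameter`` (107, nuclear-pore
        scale), ``separation`` (59, axial ring spacing), ``z0``
        (height of the lower ring, 50).
    ``periodic_rings``
        rings in the yz plane repeating along x: ``period`` (190,
        spectrin lattice), ``radius`` (100), ``n_rings`` (5).

    Deterministic for a fixed seed.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; choose from {GEOMETRIES}")
    if n_emitters <= 0:
        raise ValueError("n_emitters must be positive")
    rng = np.random.default_rng(seed)

    if geometry == "plane":
        z0 = float(params.setdefault("z0", 0.0))
        extent = float(params.setdefault("extent", 2000.0))
        if z0 < 0:
            raise ValueError("plane height must be non-negative")
        xy = rng.uniform(-extent / 2, extent / 2, size=(n_emitters, 2))
        pos = np.column_stack([xy, np.full(n_emitters, z0)])
    elif geometry == "cylinder":
        radius = float(params.setdefault("radius", 20.5))
        axis_z = float(params.setdefault("axis_z", radius + 50.0))
        length = float(params.setdefault("length", 2000.0))
        if radius <= 0 or axis_z < radius:
            raise ValueError("need radius > 0 and axis_z >= radius (z >= 0)")
        x = rng.uniform(-length / 2, length / 2, n_emitters)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_emitters)
        pos = np.column_stack(
            [x, radius * np.sin(phi), axis_z + radius * np.cos(phi)]
        )
    elif geometry == "double_ring":
        diameter = float(params.setdefault("diameter", 107.0))
        separation = float(params.setdefault("separation", 59.0))
        z0 = float(params.setdefault("z0", 50.0))
        if diameter <= 0 or separation <= 0 or z0 < 0:
            raise ValueError("geometry parameters must be positive (z0 >= 0)")
        phi = rng.uniform(0.0, 2.0 * math.pi, n_emitters)
        ring = rng.integers(0, 2, n_emitters)
        r = diameter / 2.0
        pos = np.column_stack(
            [r * np.cos(phi), r * np.sin(phi), z0 + ring * separation]
        )
    else:  # periodic_rings
        period = float(params.setdefault("period", 190.0))
        radius = float(params.setdefault("radius", 100.0))
        n_rings = int(params.setdefault("n_rings", 5))
        if period <= 0 or radius <= 0 or n_rings < 1:
            raise ValueError("geometry parameters must be positive")
        ring = rng.integers(0, n_rings, n_emitters)
        phi = rng.uniform(0.0, 2.0 * math.pi, n_emitters)
        pos = np.column_stack(
            [ring * period, radius * np.sin(phi), radius * (1.0 + np.cos(phi))]
        )

    return SyntheticScene(positions=pos, geometry=geometry, params=dict(params), seed=seed)


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and noise settings for a simulated measurement.

    ``mean_on_frames`` is the mean number of *full* frames per binding
    event (geometric, memoryless); a partial first and last frame with
    uniform(0, 1) fractional exposure are added around them, so the
    frame filter has something to remove.  ``sigma_n_factor`` is c in
    sigma_N = c sqrt(N) (c = 5 matches EM-CCD DNA-PAINT data; 1 is the
    shot-noise floor).  ``sigma_xy_nm`` is the lateral localization
    noise.
    """

    n_frames: int = 20000
    mean_on_frames: float = 6.0
    events_per_frame: float = 0.05
    sigma_n_factor: float = 5.0
    sigma_xy_nm: float = 5.0
    pixel_size_nm: float = 133.0
    partial_frames: bool = True

    def __post_init__(self):
        if self.mean_on_frames < 1.0:
            raise ValueError("mean_on_frames must be >= 1")
        if self.sigma_n_factor < 0:
            raise ValueError("sigma_n_factor must be non-negative")


def gaussian_illumination(
    sigma_nm: float, centre: tuple[float, float] = (0.0, 0.0)
) -> IlluminationProfile:
    """Gaussian excitation profile with max 1 at the beam centre."""
    return IlluminationProfile(kind="gaussian", sigma_nm=sigma_nm, centre=centre)


def flat_illumination() -> IlluminationProfile:
    """Uniform excitation profile, P = 1 everywhere."""
    return IlluminationProfile(kind="flat")


def simulate_traces(
    scene: SyntheticScene,
    response: AxialResponse,
    acq: AcquisitionParams,
    seed: int,
    n_events: int | None = None,
    profile: IlluminationProfile | None = None,
    n0: float | None = None,
    merge_collisions: bool = True,
) -> pd.DataFrame:
    """Simulate a localization table from a ground-truth scene.

    For each binding event an emitter is chosen uniformly; the event
    lasts a geometric number of full frames (mean ``mean_on_frames``)
    plus partial first/last frames with uniform fractional exposure.
    Per frame the expected count is ``N0 * F(z) * P(x, y)/P_ref *
    exposure`` and the detected count is drawn from a normal with
    standard deviation ``c sqrt(mean)``, truncated at 1 photon.
    Lateral coordinates get isotropic Gaussian noise per localization.
    Concurrent events on the same emitter are merged into one record
    with summed photons (one spot on the camera); pass
    ``merge_collisions=False`` to keep per-event records instead.

    Output columns: ``frame, x_nm, y_nm, photons, bg`` plus ground
    truth ``true_z_nm, emitter_id, event_id``.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n0 = float(n0 if n0 is not None else response.config.n0)
    if n_events is None:
        n_events = max(1, int(round(acq.events_per_frame * acq.n_frames)))
    prof = profile if profile is not None else flat_illumination()

    emitter = rng.integers(0, scene.n_emitters, n_events)
    start = rng.integers(0, acq.n_frames, n_events)
    # number of full frames: geometric with mean mean_on_frames, support >= 1
    n_full = rng.geometric(1.0 / acq.mean_on_frames, n_events)

    rows_frame, rows_x, rows_y, rows_n, rows_bg = [], [], [], [], []
    rows_z, rows_em, rows_ev = [], [], []
    for ev in range(n_events):
        e = emitter[ev]
        x, y, z = scene.positions[e]
        rel = prof(x, y) / prof.p_ref
        mean_full = n0 * float(response.f_at(z)) * float(rel)
        exposures = [1.0] * int(n_full[ev])
        f0 = int(start[ev])
        if acq.partial_frames:
            exposures = [float(rng.uniform())] + exposures + [float(rng.uniform())]
            f0 -= 1
        for k, expo in enumerate(exposures):
            fr = f0 + k
            if fr < 0 or fr >= acq.n_frames:
                continue
            mu = max(mean_full * expo, 1e-9)
            n_det = rng.normal(mu, acq.sigma_n_factor * math.sqrt(mu))
            rows_frame.append(fr)
            rows_x.append(x + rng.normal(0.0, acq.sigma_xy_nm))
            rows_y.append(y + rng.normal(0.0, acq.sigma_xy_nm))
            rows_n.append(max(n_det, 1.0))
            rows_bg.append(100.0 * float(rel))
            rows_z.append(z)
            rows_em.append(e)
            rows_ev.append(ev)

    df = pd.DataFrame({
        "frame": np.asarray(rows_frame, dtype=np.int64),
        "x_nm": rows_x,
        "y_nm": rows_y,
        "photons": rows_n,
        "bg": rows_bg,
        "true_z_nm": rows_z,
        "emitter_id": np.asarray(rows_em, dtype=np.int64),
        "event_id": np.asarray(rows_ev, dtype=np.int64),
    })
    # concurrent events on the same emitter appear as one spot on the
    # camera: merge them, summing the photon counts
    if merge_collisions:
        df = (
            df.groupby(["emitter_id", "frame"], as_index=False)
            .agg({
                "x_nm": "mean", "y_nm": "mean", "photons": "sum", "bg": "first",
                "true_z_nm": "first", "event_id": "min",
            })
        )
    return (
        df[["frame", "x_nm", "y_nm", "photons", "bg", "true_z_nm",
            "emitter_id", "event_id"]]
        .sort_values(["frame", "emitter_id"], kind="stable")
        .reset_index(drop=True)
    )
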