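"""Localization-table I/O, illumination profiles, and rendering utilities.

Two table dialects are supported:

* CSV with named columns ``frame, x_nm, y_nm, photons[, bg, ...]`` —
  coordinates in nanometres, frames 0-based.  A CSV with pixel-unit
  ``x, y`` columns can be read by passing ``pixel_size_nm``.
* HDF5 with a ``locs`` record dataset using Picasso-style field names
  (``frame, x, y, photons, bg``), x/y in pixels, with a
  ``pixel_size_nm`` attribute on the dataset.

Unknown extra columns are preserved on read and write.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "IlluminationProfile",
    "read_localizations",
    "write_localizations",
    "render_z_histogram",
    "RenderResult",
    "fit_circle",
    "CircleFit",
    "density_filter",
]

MANDATORY_COLUMNS = ("frame", "x_nm", "y_nm", "photons")


class IlluminationProfile:
    """Excitation-intensity profile P(x, y) over the field of view.

    Either analytic (``flat`` or a 2-D isotropic ``gaussian``) or a
    gridded image with a pixel size.  ``p_ref`` is the reference value
    used for photon-count correction; it defaults to the profile
    maximum and must correspond to the region where N0 was calibrated.
    """

    def __init__(
        self,
        kind: str = "flat",
        sigma_nm: float | None = None,
        centre: tuple[float, float] = (0.0, 0.0),
        image: np.ndarray | None = None,
        pixel_size_nm: float | None = None,
        origin: tuple[float, float] = (0.0, 0.0),
        p_ref: float | None = None,
    ):
        if kind not in ("flat", "gaussian", "image"):
            raise ValueError(f"unknown profile kind {kind!r}")
        self.kind = kind
        self.centre = centre
        self.origin = origin
        self.pixel_size_nm = pixel_size_nm
        if kind == "gaussian":
            if sigma_nm is None or sigma_nm <= 0:
                raise ValueError("gaussian profile needs a positive sigma_nm")
            self.sigma_nm = float(sigma_nm)
        if kind == "image":
            if image is None or pixel_size_nm is None:
                raise ValueError("image profile needs an image and pixel size")
            self.image = np.asarray(image, dtype=float)
            if np.any(self.image < 0):
                raise ValueError("illumination image must be non-negative")
        if p_ref is None:
            p_ref = 1.0 if kind in ("flat", "gaussian") else float(self.image.max())
        if p_ref <= 0:
            raise ValueError("p_ref must be positive")
        self.p_ref = float(p_ref)

    @classmethod
    def from_image(
        cls,
        image: np.ndarray,
        pixel_size_nm: float,
        origin: tuple[float, float] = (0.0, 0.0),
        smooth_sigma_px: float = 2.0,
        p_ref: float | None = None,
    ) -> "IlluminationProfile":
        """Profile from a measured beam image, smoothed before use."""
        img = np.asarray(image, dtype=float)
        if smooth_sigma_px > 0:
            img = ndimage.gaussian_filter(img, smooth_sigma_px)
        return cls(
            kind="image", image=img, pixel_size_nm=pixel_size_nm,
            origin=origin, p_ref=p_ref,
        )

    def __call__(self, x_nm, y_nm) -> np.ndarray:
        x = np.asarray(x_nm, dtype=float)
        y = np.asarray(y_nm, dtype=float)
        if self.kind == "flat":
            return np.ones(np.broadcast(x, y).shape)
        if self.kind == "gaussian":
            r2 = (x - self.centre[0]) ** 2 + (y - self.centre[1]) ** 2
            return np.exp(-0.5 * r2 / self.sigma_nm**2)
        col = (x - self.origin[0]) / self.pixel_size_nm
        row = (y - self.origin[1]) / self.pixel_size_nm
        return ndimage.map_coordinates(
            self.image, [row, col], order=1, mode="nearest"
        )


def _resolve_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def read_localizations(
    path: str | Path,
    dialect: str | None = None,
    pixel_size_nm: float | None = None,
) -> pd.DataFrame:
    """Read a localization table into the nm / 0-based-frame convention.

    Raises ``ValueError`` naming the first missing mandatory column.
    """
    dialect = _resolve_dialect(path, dialect)
    if dialect == "csv":
        df = pd.read_csv(path)
        if "x_nm" not in df.columns and "x" in df.columns:
            if pixel_size_nm is None:
                raise ValueError(
                    "CSV has pixel-unit columns 'x'/'y'; pixel_size_nm is required"
                )
            df = df.rename(columns={"x": "x_nm", "y": "y_nm"})
            df["x_nm"] = df["x_nm"] * pixel_size_nm
            df["y_nm"] = df["y_nm"] * pixel_size_nm
    elif dialect == "hdf5":
        with h5py.File(path, "r") as fh:
            ds = fh["locs"]
            rec = ds[()]
            px = ds.attrs.get("pixel_size_nm", pixel_size_nm)
        if px is None:
            raise ValueError(
                "HDF5 table lacks a pixel_size_nm attribute; pass pixel_size_nm"
            )
        df = pd.DataFrame.from_records(rec)
        for col in ("frame", "x", "y", "photons"):
            if col not in df.columns:
                raise ValueError(f"missing mandatory column: {col}")
        df = df.rename(columns={"x": "x_nm", "y": "y_nm"})
        df["x_nm"] = df["x_nm"] * float(px)
        df["y_nm"] = df["y_nm"] * float(px)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    bad = ~np.isfinite(df[list(MANDATORY_COLUMNS)]).all(axis=1)
    if bad.any():
        raise ValueError(
            f"malformed row {int(np.flatnonzero(bad)[0])}: non-finite value "
            f"in a mandatory column"
        )
    df["frame"] = df["frame"].astype(np.int64)
    return df


def write_localizations(
    df: pd.DataFrame,
    path: str | Path,
    dialect: str | None = None,
    pixel_size_nm: float = 133.0,
) -> None:
    """Write a localization table; the inverse of :func:`read_localizations`.

    The HDF5 dialect stores x/y in pixels with a ``pixel_size_nm``
    attribute and Picasso-style field names.  Output is byte-stable for
    a fixed table and configuration.
    """
    dialect = _resolve_dialect(path, dialect)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if dialect == "csv":
        df.to_csv(path, index=False)
        return
    out = df.copy()
    out["x_nm"] = out["x_nm"] / pixel_size_nm
    out["y_nm"] = out["y_nm"] / pixel_size_nm
    out = out.rename(columns={"x_nm": "x", "y_nm": "y"})
    rec = out.to_records(index=False)
    with h5py.File(path, "w", track_order=True) as fh:
        ds = fh.create_dataset("locs", data=rec, track_times=False)
        ds.attrs["pixel_size_nm"] = float(pixel_size_nm)


@dataclass(frozen=True)
class RenderResult:
    """A rendered 2-D histogram plus the colour-by-z map for top views."""

    image: np.ndarray
    extent: tuple[float, float, float, float]
    projection: str
    pixel_size_nm: float
    z_map: np.ndarray | None = None

    @property
    def total_weight(self) -> float:
        return float(self.image.sum())


_PROJ_COLUMNS = {"xy": ("x_nm", "y_nm"), "xz": ("x_nm", "z_nm"), "yz": ("y_nm", "z_nm")}


def render_z_histogram(
    df: pd.DataFrame,
    pixel_size_nm: float = 5.0,
    projection: str = "xy",
    sigma_nm: float | None = None,
    colour_by_z: bool = False,
) -> RenderResult:
    """Render localizations as a smoothed 2-D histogram.

    ``projection`` selects top (``xy``) or side (``xz``/``yz``) views;
    side views require a ``z_nm`` column.  The histogram is smoothed
    with a Gaussian of ``sigma_nm``; by default 0.5 times the median
    axial localization precision (``sigma_z_nm`` column) when present,
    otherwise one rendering pixel.  With ``colour_by_z`` the result
    also carries the mean z per pixel for colour-coded top views.
    Integrated weight equals the number of rendered localizations.
    """
    if projection not in _PROJ_COLUMNS:
        raise ValueError(f"projection must be one of {sorted(_PROJ_COLUMNS)}")
    cx, cy = _PROJ_COLUMNS[projection]
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    if cx not in df.columns or cy not in df.columns:
        raise ValueError(f"table lacks column {cx!r} or {cy!r}")
    if len(df) == 0:
        warnings.warn("no valid localizations to render")
        empty = np.zeros((1, 1))
        return RenderResult(empty, (0, 0, 0, 0), projection, pixel_size_nm)

    if sigma_nm is None:
        if "sigma_z_nm" in df.columns and np.isfinite(df["sigma_z_nm"]).any():
            sigma_nm = 0.5 * float(np.nanmedian(df["sigma_z_nm"]))
        else:
            sigma_nm = pixel_size_nm

    x = df[cx].to_numpy(float)
    y = df[cy].to_numpy(float)
    pad = 3.0 * sigma_nm + pixel_size_nm
    xe = np.arange(x.min() - pad, x.max() + pad + pixel_size_nm, pixel_size_nm)
    ye = np.arange(y.min() - pad, y.max() + pad + pixel_size_nm, pixel_size_nm)
    hist, _, _ = np.histogram2d(y, x, bins=(ye, xe))
    img = ndimage.gaussian_filter(hist, sigma_nm / pixel_size_nm, mode="constant")

    z_map = None
    if colour_by_z and "z_nm" in df.columns:
        zsum, _, _ = np.histogram2d(y, x, bins=(ye, xe), weights=df["z_nm"])
        counts, _, _ = np.histogram2d(y, x, bins=(ye, xe))
        with np.errstate(invalid="ignore"):
            z_map = np.where(counts > 0, zsum / np.maximum(counts, 1), np.nan)

    extent = (xe[0], xe[-1], ye[0], ye[-1])
    return RenderResult(img, extent, projection, pixel_size_nm, z_map)


@dataclass(frozen=True)
class CircleFit:
    cx: float
    cy: float
    radius: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def fit_circle(u: Sequence[float], v: Sequence[float]) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through points (u, v).

    Solves the linear system for u^2 + v^2 = 2 a u + 2 b v + c; fast
    and adequate at the noise level of labelled-structure
    cross-sections.  Raises on fewer than 3 points or (near-)collinear
    input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size < 3:
        raise ValueError("need at least 3 points to fit a circle")
    A = np.column_stack([2.0 * u, 2.0 * v, np.ones_like(u)])
    b = u**2 + v**2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("degenerate circle fit: points are collinear")
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if r2 <= 0 or not np.isfinite(r2):
        raise ValueError("degenerate circle fit: points are collinear")
    return CircleFit(cx=float(a), cy=float(bb), radius=float(math.sqrt(r2)))


def density_filter(
    df: pd.DataFrame,
    radius_nm: float = 67.0,
    min_neighbours: int = 100,
) -> pd.DataFrame:
    """Keep localizations with enough lateral neighbours.

    Counts neighbours (excluding the point itself) within ``radius_nm``
    in the xy plane; suppresses sparse non-specific background before
    rendering.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be positive")
    if min_neighbours <= 0 or len(df) == 0:
        return df.copy()
    pts = df[["x_nm", "y_nm"]].to_numpy(float)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius_nm, return_length=True) - 1
    return df[counts >= min_neighbours].copy()
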