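"""Photometric z-estimation pipeline for 2-D SMLM localization tables.

The decoder turns per-frame photon counts of single molecules under
TIRF illumination into axial positions:

1. photon counts are corrected for the local excitation intensity so a
   single N0 applies across the field of view;
2. localizations are linked into traces — runs of detections of the
   same molecule in strictly consecutive frames within a small lateral
   radius;
3. the first and last frame of every trace are dropped (the molecule
   may have switched on or off mid-exposure, biasing the count low and
   the apparent z high), and traces shorter than three frames are
   discarded entirely;
4. surviving counts are inverted through the exponential calibration,

       z_hat = d_F * ln( alpha_F / (N/N0 - (1 - alpha_F)) ),

   with the propagated precision

       sigma_z = sqrt( (d_F / (N - (1-alpha_F) N0))^2 sigma_N^2
                       + (ln(alpha_F N0 / (N - (1-alpha_F) N0)))^2 sigma_dF^2 ).

Records whose count sits at or below the background asymptote
``(1 - alpha_F) N0`` cannot be inverted and are flagged invalid;
counts above N0 give a nominally negative z and are flagged but kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calibration import AxialResponse, CalibrationBundle
from .config import OpticalConfig
from .io_render import IlluminationProfile

__all__ = [
    "TraceSet",
    "link_traces",
    "frame_filter",
    "correct_illumination",
    "z_estimate",
    "z_precision",
    "localize_table",
    "mislocalization_n0",
    "distortion_alpha",
    "trace_z_statistics",
]

logger = logging.getLogger(__name__)

DEFAULT_LINK_RADIUS_NM = 20.0


@dataclass
class TraceSet:
    """Localizations annotated with trace membership.

    ``table`` carries a ``trace_id`` column; every trace is a run of
    records in strictly consecutive frames whose consecutive lateral
    distances satisfy the linking criterion.  Single detections form
    traces of length 1.
    """

    table: pd.DataFrame
    radius_nm: float = DEFAULT_LINK_RADIUS_NM

    def __len__(self) -> int:
        return int(self.table["trace_id"].nunique())

    def trace(self, trace_id: int) -> pd.DataFrame:
        return self.table[self.table["trace_id"] == trace_id]

    def lengths(self) -> pd.Series:
        return self.table.groupby("trace_id").size()

    def validate(self) -> None:
        """Check the consecutive-frame and linking-distance invariants."""
        for tid, grp in self.table.groupby("trace_id"):
            frames = grp["frame"].to_numpy()
            if not np.all(np.diff(frames) == 1):
                raise AssertionError(f"trace {tid} has non-consecutive frames")
            dx = np.diff(grp["x_nm"].to_numpy())
            dy = np.diff(grp["y_nm"].to_numpy())
            if np.any(dx * dx + dy * dy >= self.radius_nm**2):
                raise AssertionError(f"trace {tid} violates the linking radius")


def link_traces(
    table: pd.DataFrame,
    radius_nm: float = DEFAULT_LINK_RADIUS_NM,
) -> TraceSet:
    """Chain localizations of the same molecule across consecutive frames.

    A record in frame n continues a trace ending in frame n-1 if their
    lateral distance is below ``radius_nm`` (default 20 nm, a few times
    the lateral localization precision).  No gap frames are allowed.
    When several candidates compete, the nearest pair wins
    (deterministic tie-break by distance, then table order); leftover
    records start new traces.
    """
    df = table.sort_values(["frame"], kind="stable").reset_index(drop=False)
    n = len(df)
    trace_id = np.full(n, -1, dtype=np.int64)
    next_id = 0
    r2 = radius_nm * radius_nm

    frames = df["frame"].to_numpy()
    xy = df[["x_nm", "y_nm"]].to_numpy(float)
    # row indices per frame, in sorted order
    frame_groups = {f: idx for f, idx in pd.Series(np.arange(n)).groupby(frames)}

    prev_frame = None
    prev_rows: np.ndarray = np.empty(0, dtype=np.int64)
    for f in sorted(frame_groups):
        rows = frame_groups[f].to_numpy()
        if prev_frame is not None and f == prev_frame + 1 and len(prev_rows):
            tree = cKDTree(xy[prev_rows])
            pairs = tree.query_ball_point(xy[rows], r=radius_nm)
            cand = [
                (float(np.sum((xy[rows[i]] - xy[prev_rows[j]]) ** 2)), i, j)
                for i, js in enumerate(pairs)
                for j in js
            ]
            cand.sort()
            used_prev: set[int] = set()
            used_cur: set[int] = set()
            for d2, i, j in cand:
                if d2 >= r2 or i in used_cur or j in used_prev:
                    continue
                trace_id[rows[i]] = trace_id[prev_rows[j]]
                used_cur.add(i)
                used_prev.add(j)
        for row in rows:
            if trace_id[row] < 0:
                trace_id[row] = next_id
                next_id += 1
        prev_frame, prev_rows = f, rows

    out = df.set_index("index")
    out.index.name = table.index.name
    out = out.loc[table.index]
    out["trace_id"] = pd.Series(trace_id, index=df["index"]).loc[table.index]
    return TraceSet(table=out, radius_nm=radius_nm)


def frame_filter(traces: TraceSet) -> pd.DataFrame:
    """Drop first/last frames of each trace; ignore traces shorter than 3.

    The first and last frame of an emission event may cover only part
    of the exposure, so their photon counts underestimate the true rate
    and would bias z high.  Returns the surviving records (with
    ``trace_id``); kept/total counts are logged.
    """
    df = traces.table
    order = df.sort_values(["trace_id", "frame"], kind="stable")
    grp = order.groupby("trace_id")
    size = grp["frame"].transform("size")
    pos = grp.cumcount()
    keep = (size >= 3) & (pos > 0) & (pos < size - 1)
    kept = order[keep]
    kept = kept.loc[kept.index.intersection(df.index)]
    kept = kept.reindex(index=[i for i in df.index if i in set(kept.index)])
    logger.info(
        "frame filter: kept %d of %d localizations (%d of %d traces)",
        len(kept), len(df), kept["trace_id"].nunique(), df["trace_id"].nunique(),
    )
    return kept


def correct_illumination(
    table: pd.DataFrame,
    profile: IlluminationProfile,
    p_ref: float | None = None,
) -> pd.DataFrame:
    """Rescale photon counts to the reference excitation intensity.

    ``photons_corrected = photons * P_ref / P(x, y)``.  P_ref must be
    the profile value where N0 was calibrated (default: the profile
    maximum).  Records falling where the profile is non-positive are
    flagged invalid.
    """
    p_ref = profile.p_ref if p_ref is None else p_ref
    out = table.copy()
    p = np.asarray(profile(out["x_nm"].to_numpy(), out["y_nm"].to_numpy()))
    ok = p > 0
    out["photons_raw"] = out["photons"]
    out["photons"] = np.where(ok, out["photons"] * p_ref / np.where(ok, p, 1.0), np.nan)
    if "valid" in out.columns:
        out["valid"] = out["valid"].to_numpy(bool) & ok
    else:
        out["valid"] = ok
    return out


def z_estimate(n_photons, n0: float, d_f: float, alpha_f: float) -> np.ndarray | float:
    """Photometric axial position from a photon count.

    ``z_hat = d_F ln(alpha_F / (N/N0 - (1 - alpha_F)))``; NaN where the
    count is at or below the background asymptote ``(1 - alpha_F) N0``.
    Counts above N0 yield negative values (caller decides flagging).
    """
    n_arr = np.asarray(n_photons, dtype=float)
    ratio = n_arr / n0 - (1.0 - alpha_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ratio > 0, d_f * np.log(alpha_f / np.where(ratio > 0, ratio, 1.0)), np.nan)
    return float(out) if np.isscalar(n_photons) else out


def z_precision(
    n_photons,
    n0: float,
    d_f: float,
    alpha_f: float,
    sigma_n,
    sigma_df: float = 0.0,
) -> np.ndarray | float:
    """Lower bound on the axial localization precision.

    First-order propagation of the photon-count uncertainty
    ``sigma_n`` and the calibration-decay uncertainty ``sigma_df``
    through the z estimator.  NaN where the estimator is undefined.
    """
    n_arr = np.asarray(n_photons, dtype=float)
    sn = np.asarray(sigma_n, dtype=float)
    denom = n_arr - (1.0 - alpha_f) * n0
    with np.errstate(invalid="ignore", divide="ignore"):
        term_n = (d_f / denom) ** 2 * sn**2
        term_d = np.log(alpha_f * n0 / denom) ** 2 * sigma_df**2
        out = np.where(denom > 0, np.sqrt(term_n + term_d), np.nan)
    return float(out) if np.isscalar(n_photons) else out


@dataclass
class LocalizeStats:
    """Bookkeeping of the localization pipeline."""

    n_in: int = 0
    n_after_filter: int = 0
    n_valid: int = 0
    n_below_asymptote: int = 0
    n_negative_z: int = 0
    n_traces: int = 0
    n_traces_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def localize_table(
    table: pd.DataFrame,
    calibration: CalibrationBundle,
    profile: IlluminationProfile | None = None,
    radius_nm: float = DEFAULT_LINK_RADIUS_NM,
    sigma_n: str | float = "sqrt",
    sigma_df_nm: float = 0.0,
    clip_negative: bool = False,
) -> tuple[pd.DataFrame, LocalizeStats]:
    """End-to-end z decoding of a 2-D localization table.

    Steps: illumination correction (if a profile is given), trace
    linking, frame filtering, z estimation and precision.  ``sigma_n``
    is either the string ``"sqrt"`` (shot-noise floor, sigma_N =
    sqrt(N)) or a multiplier c in sigma_N = c * sqrt(N).

    Returns the surviving records with ``z_nm``, ``sigma_z_nm``,
    ``trace_id`` and ``valid`` columns, plus pipeline statistics.
    """
    stats = LocalizeStats(n_in=len(table))
    df = table.copy()
    if profile is not None:
        df = correct_illumination(df, profile)
    traces = link_traces(df, radius_nm=radius_nm)
    stats.n_traces = len(traces)
    kept = frame_filter(traces)
    stats.n_after_filter = len(kept)
    stats.n_traces_kept = int(kept["trace_id"].nunique()) if len(kept) else 0
    if len(kept) == 0:
        out = kept.assign(z_nm=np.nan, sigma_z_nm=np.nan, valid=False)
        return out, stats

    n = kept["photons"].to_numpy(float)
    c = 1.0 if sigma_n == "sqrt" else float(sigma_n)
    z = z_estimate(n, calibration.n0, calibration.d_f, calibration.alpha_f)
    sz = z_precision(
        n, calibration.n0, calibration.d_f, calibration.alpha_f,
        c * np.sqrt(n), sigma_df_nm,
    )
    below = np.isnan(z)
    negative = ~below & (z < 0)
    stats.n_below_asymptote = int(below.sum())
    stats.n_negative_z = int(negative.sum())

    out = kept.copy()
    out["z_nm"] = np.clip(z, 0.0, None) if clip_negative else z
    out["sigma_z_nm"] = sz
    valid = out.get("valid", pd.Series(True, index=out.index)).to_numpy(bool)
    valid &= ~below
    if not clip_negative:
        valid &= ~negative
    out["valid"] = valid
    stats.n_valid = int(valid.sum())
    logger.info(
        "localized %d records: %d valid, %d below background asymptote, "
        "%d negative z", len(out), stats.n_valid, stats.n_below_asymptote,
        stats.n_negative_z,
    )
    return out, stats


def mislocalization_n0(
    z_true,
    n0_error_fraction: float,
    response: AxialResponse,
    pathway: str = "exact",
) -> np.ndarray | float:
    """Axial error from decoding with a miscalibrated N0.

    Photon counts are generated from the exact response at ``z_true``
    (N = N0 F(z)) and inverted assuming ``N0 (1 + n0_error_fraction)``.
    ``pathway`` selects the inversion: ``"exact"`` (numerical inversion
    of the exact response; reproduces the reference sensitivity values)
    or ``"approx"`` (closed-form inversion of the exponential
    calibration).  Returns ``z_hat - z_true``.
    """
    z_arr = np.asarray(z_true, dtype=float)
    ratio = response.f_at(z_arr) / (1.0 + n0_error_fraction)
    if pathway == "exact":
        z_hat = response.invert_exact(ratio)
    elif pathway == "approx":
        z_hat = response.invert_approx(ratio)
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    out = z_hat - z_arr
    return float(out) if np.isscalar(z_true) else out


@dataclass(frozen=True)
class AlphaDistortion:
    """Axial distortion curve under a miscalibrated evanescent fraction."""

    z_true: np.ndarray
    z_hat: np.ndarray
    accumulated_nm: float
    alpha_true: float
    alpha_assumed: float


def distortion_alpha(
    z_max: float,
    alpha_true: float,
    alpha_assumed: float,
    config: OpticalConfig,
    response_true: AxialResponse | None = None,
    cf_avg: np.ndarray | None = None,
    pathway: str = "exact",
    n_grid: int = 201,
) -> AlphaDistortion:
    """Accumulated axial distortion from a wrong evanescent fraction.

    Signals for z in [0, z_max] are generated with the calibration
    built at ``alpha_true`` and inverted with the one built at
    ``alpha_assumed``.  The accumulated distortion is the error in the
    imaged axial span of a structure occupying [0, z_max]:
    ``|(z_hat(z_max) - z_hat(0)) - z_max|``.  The collection curve does
    not depend on alpha and is computed once (or reused via
    ``cf_avg`` / ``response_true``).
    """
    from .calibration import axial_response  # local import to avoid cycle

    for a in (alpha_true, alpha_assumed):
        if not 0.0 < a <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {a}")
    if response_true is None:
        response_true = axial_response(config.replace(alpha=alpha_true), cf_avg=cf_avg)
    response_assumed = axial_response(
        config.replace(alpha=alpha_assumed), cf_avg=response_true.cf_avg,
        z_grid=response_true.z_nm, fit_range_nm=response_true.fit_range_nm,
    )
    z = np.linspace(0.0, z_max, n_grid)
    ratio = response_true.f_at(z)
    if pathway == "exact":
        z_hat = response_assumed.invert_exact(ratio)
    elif pathway == "approx":
        z_hat = response_assumed.invert_approx(ratio)
    else:
        raise ValueError(f"unknown pathway {pathway!r}")
    accumulated = abs((z_hat[-1] - z_hat[0]) - z_max)
    return AlphaDistortion(
        z_true=z, z_hat=z_hat, accumulated_nm=float(accumulated),
        alpha_true=alpha_true, alpha_assumed=alpha_assumed,
    )


def trace_z_statistics(
    table: pd.DataFrame,
    min_records: int = 3,
    z_bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-trace empirical axial precision and photon-count spread.

    Operates on frame-filtered, localized records: traces with at least
    ``min_records`` surviving frames (raw length >= min_records + 2)
    contribute a sample standard deviation of their z estimates
    (``sigma_z_emp_nm``) and of their photon counts expressed in units
    of sqrt(mean N) (``sigma_n_sqrtn``).  With ``z_bins``, a per-bin
    summary (median of per-trace medians and precisions) is attached as
    ``df.attrs["binned"]``.
    """
    need = {"trace_id", "z_nm", "photons"}
    if not need <= set(table.columns):
        raise ValueError(f"table lacks columns {sorted(need - set(table.columns))}")
    df = table
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    rows = []
    for tid, grp in df.groupby("trace_id"):
        if len(grp) < min_records:
            continue
        n = grp["photons"].to_numpy(float)
        rows.append({
            "trace_id": tid,
            "n_records": len(grp),
            "z_median_nm": float(np.median(grp["z_nm"])),
            "sigma_z_emp_nm": float(np.std(grp["z_nm"], ddof=1)),
            "sigma_n_sqrtn": float(np.std(n, ddof=1) / np.sqrt(np.mean(n))),
        })
    out = pd.DataFrame(
        rows, columns=[
            "trace_id", "n_records", "z_median_nm", "sigma_z_emp_nm",
            "sigma_n_sqrtn",
        ]
    )
    if z_bins is not None and len(out):
        cut = pd.cut(out["z_median_nm"], z_bins)
        binned = out.groupby(cut, observed=False).agg(
            n_traces=("trace_id", "size"),
            z_median_nm=("z_median_nm", "median"),
            sigma_z_median_nm=("sigma_z_emp_nm", "median"),
            sigma_n_median=("sigma_n_sqrtn", "median"),
        )
        out.attrs["binned"] = binned
    return out
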