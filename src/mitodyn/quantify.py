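"""Fluorescence-front migration quantification.

Given a two-channel time series with a declared photoactivation ROI,
extract directional intensity profiles of the tracer channel, locate
the migration front (farthest crossing of a fractional threshold of the
same-frame ROI plateau) and express cumulative migration in m-steps
(one m-step = one average sarcomere length, 2.2 um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .netsim.experiment import ImageSeries

__all__ = [
    "DIRECTIONS",
    "MSTEP_UM",
    "DirectionalProfile",
    "MigrationCurve",
    "estimate_background",
    "profile_along",
    "front_distance",
    "migration_curve",
]

DIRECTIONS = ("long+", "long-", "trans+", "trans-")

#: one migration step, the average sarcomere length in micrometres
MSTEP_UM = 2.2

#: default front criterion: fraction of the same-frame ROI plateau
DEFAULT_THRESHOLD = 0.10

#: band pixels brighter than this multiple of the plateau are treated
#: as puncta/artifacts and excluded from profile averaging
OUTLIER_FACTOR = 3.0


@dataclass
class DirectionalProfile:
    """Background-subtracted, plateau-normalized outward profile."""

    direction: str
    distance: np.ndarray    # um from the ROI edge, strictly increasing
    intensity: np.ndarray   # >= 0, 1.0 ~ ROI plateau
    time: float             # minutes


@dataclass
class MigrationCurve:
    """Cumulative migration in m-steps, per direction and aggregated."""

    times: np.ndarray
    steps_by_direction: dict[str, np.ndarray]
    steps: np.ndarray
    msteps_unit: float = MSTEP_UM

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d, s in self.steps_by_direction.items():
            for t, v in zip(self.times, s):
                rows.append({"time_min": t, "dir": d, "steps": v})
        for t, v in zip(self.times, self.steps):
            rows.append({"time_min": t, "dir": "mean", "steps": v})
        df = pd.DataFrame(rows)
        mean = df[df["dir"] == "mean"].set_index("time_min")["steps"]
        df["steps_mean"] = df["time_min"].map(mean)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MigrationCurve":
        times = np.sort(df["time_min"].unique()).astype(float)
        by_dir = {}
        for d, g in df[df["dir"] != "mean"].groupby("dir"):
            by_dir[str(d)] = g.sort_values("time_min")["steps"].to_numpy(float)
        mean = (df[df["dir"] == "mean"].sort_values("time_min")["steps"]
                .to_numpy(float))
        if mean.size == 0 and by_dir:
            mean = np.mean(list(by_dir.values()), axis=0)
        return cls(times=times, steps_by_direction=by_dir, steps=mean)


def estimate_background(frame: np.ndarray, background_mask: np.ndarray) -> float:
    """Median intensity of the declared background region."""
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixels")
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != frame.shape:
        raise ValueError("background mask shape does not match frame")
    if not background_mask.any():
        raise ValueError("background region is empty")
    return float(np.median(frame[background_mask]))


def _roi_px(series: "ImageSeries") -> tuple[int, int, int, int]:
    """ROI (x0, y0, x1, y1) as pixel indices (half-open)."""
    px = series.geometry.pixel_size
    ox, oy = series.origin
    x0, y0, x1, y1 = series.roi_um
    return (int(round((x0 - ox) / px)), int(round((y0 - oy) / px)),
            int(round((x1 - ox) / px)), int(round((y1 - oy) / px)))


def _fiber_px(series: "ImageSeries") -> tuple[int, int, int, int]:
    px = series.geometry.pixel_size
    ox, oy = series.origin
    g = series.geometry
    return (int(round(-ox / px)), int(round(-oy / px)),
            int(round((g.length_um - ox) / px)),
            int(round((g.width_um - oy) / px)))


def background_mask(series: "ImageSeries", guard_um: float = 2.0) -> np.ndarray:
    """Pixels outside the fiber extent plus a guard band (PSF spill)."""
    shape = series.frames[0].tracer.shape
    px = series.geometry.pixel_size
    fx0, fy0, fx1, fy1 = _fiber_px(series)
    guard = int(round(guard_um / px))
    mask = np.ones(shape, dtype=bool)
    mask[max(fy0 - guard, 0):fy1 + guard, max(fx0 - guard, 0):fx1 + guard] = False
    return mask


def profile_along(series: "ImageSeries", direction: str,
                  outlier_factor: float = OUTLIER_FACTOR,
                  smooth_um: float = 0.8) -> list[DirectionalProfile]:
    """One outward profile per frame, in the given direction.

    Intensity is averaged over the band of pixels spanning the ROI in
    the perpendicular axis, background-subtracted and normalized to the
    same-frame ROI plateau (mean over ROI pixels after excluding bright
    outliers).  The 1-D profile is lightly smoothed (``smooth_um``) so
    that single-column noise excursions cannot masquerade as a front.
    Returns an empty list, with a warning, when the ROI is flush with
    the fiber border so no outward pixels exist.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")

    rx0, ry0, rx1, ry1 = _roi_px(series)
    fx0, fy0, fx1, fy1 = _fiber_px(series)
    px = series.geometry.pixel_size
    bg_mask = background_mask(series)

    # outward pixel index range along the scan axis, and the band slice
    if direction == "long+":
        lo, hi = rx1, fx1
    elif direction == "long-":
        lo, hi = fx0, rx0
    elif direction == "trans+":
        lo, hi = ry1, fy1
    else:
        lo, hi = fy0, ry0
    if hi <= lo:
        warnings.warn(
            f"direction {direction!r} dropped: ROI flush with fiber border",
            stacklevel=2)
        return []

    roi_edge_um = {"long+": series.roi_um[2], "long-": series.roi_um[0],
                   "trans+": series.roi_um[3], "trans-": series.roi_um[1]}[direction]
    origin = series.origin[0] if direction.startswith("long") else series.origin[1]
    centers_um = origin + (np.arange(lo, hi) + 0.5) * px
    if direction.endswith("+"):
        dist = centers_um - roi_edge_um
    else:
        dist = (roi_edge_um - centers_um)[::-1]

    profiles = []
    for frame in series.frames:
        img = np.asarray(frame.tracer, dtype=float)
        bg = estimate_background(img, bg_mask)
        # do NOT clip per pixel here: zeroing negative noise excursions
        # before averaging biases the dim far-field upward
        img = img - bg

        roi_vals = img[ry0:ry1, rx0:rx1].ravel()
        if roi_vals.size == 0:
            raise ValueError("ROI contains no pixels")
        # upper-quartile reference: the ROI median can land on the dim
        # gaps between compartment footprints in sharp renders
        cap = outlier_factor * max(float(np.percentile(roi_vals, 75)), 1e-12)
        plateau = float(roi_vals[roi_vals <= cap].mean()) if \
            (roi_vals <= cap).any() else float(roi_vals.mean())

        if direction.startswith("long"):
            band = img[ry0:ry1, lo:hi]
            axis = 0
        else:
            band = img[lo:hi, rx0:rx1]
            axis = 1
        keep = band <= cap
        with np.errstate(invalid="ignore"):
            vals = np.where(keep, band, np.nan)
            mean = np.nanmean(vals, axis=axis)
        mean = np.where(np.isfinite(mean), mean, 0.0)
        if direction.endswith("-"):
            mean = mean[::-1]
        if smooth_um > 0:
            from scipy.ndimage import gaussian_filter1d
            mean = gaussian_filter1d(mean, smooth_um / px, mode="nearest")
        inten = np.clip(mean / plateau if plateau > 0 else mean * 0.0, 0.0, None)
        profiles.append(DirectionalProfile(
            direction=direction, distance=dist.copy(), intensity=inten,
            time=float(frame.time_min)))
    return profiles


def front_distance(profile: "DirectionalProfile | tuple[np.ndarray, np.ndarray]",
                   threshold_frac: float = DEFAULT_THRESHOLD) -> float:
    """Farthest distance at which intensity still reaches the threshold.

    Linear interpolation between the last sample at/above threshold and
    the next sample below it; 0 when the profile never reaches the
    threshold.
    """
    if not (0 < threshold_frac < 1):
        raise ValueError("threshold_frac must be in (0, 1)")
    if isinstance(profile, DirectionalProfile):
        d, v = profile.distance, profile.intensity
    else:
        d, v = profile
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    idx = np.flatnonzero(v >= threshold_frac)
    if idx.size == 0:
        return 0.0
    k = int(idx[-1])
    if k == d.size - 1:
        return float(d[k])
    # interpolate the crossing between samples k and k+1
    dv = v[k] - v[k + 1]
    frac = (v[k] - threshold_frac) / dv if dv > 0 else 0.0
    return float(d[k] + frac * (d[k + 1] - d[k]))


def migration_curve(series: "ImageSeries",
                    threshold_frac: float = DEFAULT_THRESHOLD,
                    directions: Iterable[str] = DIRECTIONS,
                    smooth_um: float = 0.8) -> MigrationCurve:
    """Migration curve in m-steps, aggregated over available directions.

    A running maximum is applied per direction: a cumulative migration
    front cannot physically retreat, so apparent decreases are noise.
    """
    if len(series.frames) < 2:
        raise ValueError("need at least 2 frames")
    times = np.asarray([f.time_min for f in series.frames], dtype=float)

    by_dir: dict[str, np.ndarray] = {}
    for direction in directions:
        profiles = profile_along(series, direction, smooth_um=smooth_um)
        if not profiles:
            continue
        fronts = np.array([front_distance(p, threshold_frac) for p in profiles])
        by_dir[direction] = np.maximum.accumulate(fronts) / MSTEP_UM
    if not by_dir:
        raise ValueError("all directions were dropped; cannot build a curve")

    steps = np.mean(np.stack(list(by_dir.values())), axis=0)
    return MigrationCurve(times=times, steps_by_direction=by_dir, steps=steps)
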