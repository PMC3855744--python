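"""End-to-end synthetic experiments: simulate, render, keep ground truth.

`simulate_experiment` reproduces the acquisition protocol of the assay:
photoactivate a ~10x10 um region, record two-channel frames on a fixed
time grid starting 2 min after activation, and attach the ground-truth
migration curve computed from the noise-free tracer field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .. import quantify
from .model import (FiberGeometry, MitoNetworkState, SimParams,
                    build_lattice, evolve, photoactivate)
from .presets import ConditionPreset, get_preset
from .render import RenderOptics, image_origin, render

__all__ = [
    "Frame",
    "ImageSeries",
    "SimTruth",
    "DEFAULT_GEOMETRY",
    "default_frame_times",
    "default_roi",
    "simulate_experiment",
    "truth_migration_curve",
]

DEFAULT_GEOMETRY = FiberGeometry(n_long=56, n_trans=32)

DEFAULT_ROI_SIZE_UM = (10.0, 10.0)


@dataclass
class Frame:
    time_min: float
    tracer: np.ndarray
    tmre: np.ndarray


@dataclass
class SimTruth:
    """Ground truth attached to synthetic series."""

    curve: "quantify.MigrationCurve"
    params: SimParams
    preset_name: str | None = None
    n_aggregates: int = 0


@dataclass
class ImageSeries:
    """Timestamped two-channel frames plus acquisition metadata.

    ``origin`` is the physical (x, y) in micrometres of the corner of
    pixel (0, 0); the fiber occupies [0, length] x [0, width].
    """

    frames: list[Frame]
    roi_um: tuple[float, float, float, float]
    geometry: FiberGeometry
    origin: tuple[float, float] = (0.0, 0.0)
    truth: SimTruth | None = None
    preset_name: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        times = self.times
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.tracer.shape != f.tmre.shape:
                raise ValueError("tracer and tmre channels differ in shape")
            if f.tracer.shape != self.frames[0].tracer.shape:
                raise ValueError("frames differ in shape")
            if np.min(f.tracer) < 0 or np.min(f.tmre) < 0:
                raise ValueError("pixel values must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time_min for f in self.frames], dtype=float)


def default_frame_times() -> np.ndarray:
    """2, 4, ..., 20 minutes post-activation."""
    return np.arange(2.0, 20.0 + 1e-9, 2.0)


def default_roi(geometry: FiberGeometry,
                size_um: tuple[float, float] = DEFAULT_ROI_SIZE_UM
                ) -> tuple[float, float, float, float]:
    """Photoactivation rectangle centered on the fiber."""
    cx, cy = geometry.length_um / 2.0, geometry.width_um / 2.0
    w, h = size_um
    return (cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)


def _truth_profiles(state: MitoNetworkState,
                    roi: tuple[float, float, float, float]
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Outward tracer profiles computed directly on the node field.

    Band = rows (columns) whose centers lie inside the ROI; values are
    normalized to the mean tracer of the activated block.  The distance
    assigned to a compartment is the distance from the ROI edge to the
    compartment's far edge, which is where the rendered front of a
    filled compartment sits.
    """
    g = state.geometry
    L = g.sarcomere_length
    a = state.tracer.reshape(g.n_trans, g.n_long)
    x0, y0, x1, y1 = roi
    col_c = (np.arange(g.n_long) + 0.5) * L
    row_c = (np.arange(g.n_trans) + 0.5) * L
    band_rows = (row_c >= y0) & (row_c <= y1)
    band_cols = (col_c >= x0) & (col_c <= x1)
    plateau = float(a[np.ix_(band_rows, band_cols)].mean())

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for direction in quantify.DIRECTIONS:
        if direction == "long+":
            sel = col_c > x1
            dist = (np.arange(g.n_long) + 1.0)[sel] * L - x1
            vals = a[band_rows][:, sel].mean(axis=0)
        elif direction == "long-":
            sel = col_c < x0
            dist = (x0 - np.arange(g.n_long)[sel] * L)[::-1]
            vals = a[band_rows][:, sel].mean(axis=0)[::-1]
        elif direction == "trans+":
            sel = row_c > y1
            dist = (np.arange(g.n_trans) + 1.0)[sel] * L - y1
            vals = a[sel][:, band_cols].mean(axis=1)
        else:
            sel = row_c < y0
            dist = (y0 - np.arange(g.n_trans)[sel] * L)[::-1]
            vals = a[sel][:, band_cols].mean(axis=1)[::-1]
        if dist.size == 0:
            continue
        rel = vals / plateau if plateau > 0 else vals * 0.0
        out[direction] = (dist, rel)
    return out


def truth_migration_curve(states: list[MitoNetworkState],
                          roi: tuple[float, float, float, float],
                          threshold_frac: float = quantify.DEFAULT_THRESHOLD
                          ) -> "quantify.MigrationCurve":
    """Ground-truth migration curve from noise-free tracer fields."""
    times = np.asarray([s.time for s in states], dtype=float)
    fronts: dict[str, list[float]] = {}
    for s in states:
        for direction, (dist, rel) in _truth_profiles(s, roi).items():
            fronts.setdefault(direction, []).append(
                quantify.front_distance((dist, rel), threshold_frac))
    by_dir = {d: np.maximum.accumulate(np.asarray(v)) / quantify.MSTEP_UM
              for d, v in fronts.items()}
    steps = np.mean(np.stack(list(by_dir.values())), axis=0)
    return quantify.MigrationCurve(times=times, steps_by_direction=by_dir,
                                   steps=steps)


def simulate_experiment(preset: ConditionPreset | str,
                        geometry: FiberGeometry | None = None,
                        frame_times: np.ndarray | None = None,
                        seed: int = 0,
                        optics: RenderOptics | None = None,
                        roi: tuple[float, float, float, float] | None = None,
                        render_frames: bool = True,
                        method: str = "auto") -> ImageSeries:
    """Simulate one fiber and return its rendered time series.

    The returned series carries the ground-truth migration curve
    (computed from the noise-free tracer field at each frame time) and
    the parameter bundle used.  Fully deterministic given
    (preset, geometry, frame_times, seed).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    geometry = geometry or DEFAULT_GEOMETRY
    optics = optics or RenderOptics()
    if frame_times is None:
        frame_times = default_frame_times()
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size < 1 or np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be non-empty and strictly increasing")
    if frame_times[0] < 2.0:
        warnings.warn("first frame earlier than the 2-min acquisition delay",
                      stacklevel=2)
    if roi is None:
        roi = default_roi(geometry)

    ss = np.random.SeedSequence(seed)
    s_build, s_dyn, s_noise = ss.spawn(3)
    params = replace(preset.params, seed=int(s_build.generate_state(1)[0]))

    state = build_lattice(geometry, params)
    n_agg = int(state.aggregate_nodes.size)
    state = photoactivate(state, roi)
    rng_dyn = np.random.default_rng(s_dyn)
    noise_seeds = s_noise.spawn(frame_times.size)

    frames: list[Frame] = []
    snapshots: list[MitoNetworkState] = []
    for t, ns in zip(frame_times, noise_seeds):
        state = evolve(state, params, float(t), rng_dyn, method=method)
        snapshots.append(state)
        if render_frames:
            tr, tm = render(state, geometry, optics, np.random.default_rng(ns))
            frames.append(Frame(time_min=float(t), tracer=tr, tmre=tm))

    truth = SimTruth(curve=truth_migration_curve(snapshots, roi),
                     params=params, preset_name=preset.name,
                     n_aggregates=n_agg)
    return ImageSeries(frames=frames, roi_um=roi, geometry=geometry,
                       origin=image_origin(optics), truth=truth,
                       preset_name=preset.name, seed=seed)
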