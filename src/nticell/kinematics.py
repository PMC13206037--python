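"""Kinetic-energy series: construction, transforms, phases and mean-fields.

The motility observable is the kinetic-energy proxy KE(t) = v(t)^2 / 2 (unit
mass) computed from frame-to-frame displacements.  Analyses run on
log-transformed, stride-resampled KE; a cell's life is split into three
equal terciles (early / middle / last) and distribution estimation uses a
central window centred on the lifetime midpoint.  The collective context of
a focal cell is the sibling mean-field: the frame-wise mean KE of all
contemporaneous cells excluding the focal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CellSeries",
    "ContextSeries",
    "PhaseSegmentation",
    "kinetic_energy",
    "log_resample",
    "segment_phases",
    "mean_field",
    "coarse_grain",
]

DEFAULT_DT = 0.1          # seconds per raw frame
DEFAULT_STRIDE = 5        # resampling stride of the analysis protocol
CENTRAL_WINDOW_SAMPLES = 3000   # stride-5 samples in the central 25-min window
EPSILON_FACTOR = 1e-6     # log offset, relative to the cell's median positive KE


@dataclass
class CellSeries:
    """One cell's KE (or log-KE) series on a uniform frame grid."""

    cell_id: int
    frames: np.ndarray
    values: np.ndarray
    dt: float = DEFAULT_DT
    stride: int = 1
    transformed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.frames.shape != self.values.shape:
            raise ValueError("frames and values must have equal shape")
        if self.frames.size > 1:
            steps = np.diff(self.frames)
            if not np.all(steps == steps[0]) or steps[0] <= 0:
                raise ValueError("frames must be strictly increasing with constant step")
        if not self.transformed and self.frames.size and np.min(self.values) < 0:
            raise ValueError("untransformed KE values must be >= 0")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def frame_step(self) -> int:
        return int(self.frames[1] - self.frames[0]) if len(self) > 1 else 1

    def slice_frames(self, start: int, stop: int) -> "CellSeries":
        """Sub-series on frames in [start, stop)."""
        m = (self.frames >= start) & (self.frames < stop)
        return replace(self, frames=self.frames[m], values=self.values[m])


@dataclass
class ContextSeries:
    """Sibling mean-field aligned to a focal cell's series."""

    focal_id: int
    frames: np.ndarray
    values: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class PhaseSegmentation:
    """Early / middle / last terciles plus the central window, all half-open."""

    early: tuple[int, int]
    middle: tuple[int, int]
    last: tuple[int, int]
    central_window: tuple[int, int]
    clipped: bool = False

    def phase(self, name: str) -> tuple[int, int]:
        try:
            return {"early": self.early, "middle": self.middle, "last": self.last}[name]
        except KeyError:
            raise ValueError(f"unknown phase {name!r}") from None


def kinetic_energy(track, dt: float = DEFAULT_DT, cell_id: int = 0) -> CellSeries:
    """KE series from a 2-D trajectory.

    ``track`` is a sequence of (frame, x, y) rows with uniform frame spacing.
    KE(t) = |displacement(t -> t+1)| ** 2 / (2 dt^2) with unit mass, assigned
    to the earlier frame, so the output is one sample shorter than the input.
    """
    arr = np.asarray(track, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("track must be rows of (frame, x, y)")
    if arr.shape[0] < 2:
        raise ValueError("track needs at least 2 points")
    frames = arr[:, 0].astype(int)
    steps = np.diff(frames)
    if not np.all(steps == steps[0]):
        bad = int(np.flatnonzero(steps != steps[0])[0])
        raise ValueError(
            f"non-uniform frame spacing: first gap after frame {frames[bad]}"
        )
    disp = np.diff(arr[:, 1:3], axis=0)
    speed2 = (disp**2).sum(axis=1) / (dt * steps[0]) ** 2
    return CellSeries(
        cell_id=cell_id, frames=frames[:-1], values=0.5 * speed2, dt=dt, stride=1
    )


def log_resample(
    series: CellSeries,
    stride: int = DEFAULT_STRIDE,
    epsilon_factor: float = EPSILON_FACTOR,
) -> CellSeries:
    """Keep every stride-th sample, then take log(KE + eps).

    eps is ``epsilon_factor`` times the cell's median positive KE, which keeps
    the offset scale-free and finite even for exact-zero samples; an all-zero
    series falls back to eps = epsilon_factor.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if len(series) == 0:
        raise ValueError("cannot resample an empty series")
    if series.transformed:
        raise ValueError("series already log-transformed")
    frames = series.frames[::stride]
    vals = series.values[::stride]
    positive = series.values[series.values > 0]
    eps = epsilon_factor * (np.median(positive) if positive.size else 1.0)
    return CellSeries(
        cell_id=series.cell_id,
        frames=frames,
        values=np.log(vals + eps),
        dt=series.dt,
        stride=series.stride * stride,
        transformed=True,
    )


def segment_phases(
    series_or_length,
    lifetime: tuple[int, int] | None = None,
    window_samples: int = CENTRAL_WINDOW_SAMPLES,
) -> PhaseSegmentation:
    """Split a lifetime into equal terciles and a centred window.

    The three phases are equal-length terciles of the half-open lifetime (the
    remainder of a non-divisible length goes to the last tercile).  The
    central window holds ``window_samples`` frames centred on the lifetime
    midpoint; if the lifetime is shorter it is clipped (with a warning) and
    flagged in the output.

    Accepts either a :class:`CellSeries` (whose frame span is used) or an
    explicit ``lifetime`` interval.
    """
    if lifetime is None:
        if not isinstance(series_or_length, CellSeries):
            raise TypeError("pass a CellSeries or an explicit lifetime interval")
        s = series_or_length
        step = s.frame_step
        lifetime = (int(s.frames[0]), int(s.frames[-1]) + step)
    else:
        step = 1
        if isinstance(series_or_length, CellSeries):
            step = series_or_length.frame_step
    start, stop = int(lifetime[0]), int(lifetime[1])
    n = (stop - start) // step
    if n < 3:
        raise ValueError(f"lifetime must hold at least 3 samples, got {n}")
    third = n // 3
    b1 = start + third * step
    b2 = start + 2 * third * step
    mid = start + (n // 2) * step
    half = window_samples // 2
    w0 = mid - half * step
    w1 = w0 + window_samples * step
    clipped = False
    if w0 < start or w1 > stop:
        warnings.warn(
            f"central window of {window_samples} samples clipped to lifetime "
            f"[{start}, {stop})",
            stacklevel=2,
        )
        w0, w1 = max(w0, start), min(w1, stop)
        clipped = True
    return PhaseSegmentation(
        early=(start, b1),
        middle=(b1, b2),
        last=(b2, stop),
        central_window=(w0, w1),
        clipped=clipped,
    )


def mean_field(series_map: dict[int, CellSeries], focal_id: int) -> ContextSeries:
    """Sibling mean-field of a focal cell.

    ``series_map`` maps cell id to series on a common frame grid (all in the
    same transform state).  For every frame of the focal series where at
    least one other cell is present, the context value is the mean of all
    contemporaneous non-focal values.  Frames with no contemporary are
    dropped; if none exist at all (a lone founder) an error is raised.
    """
    if focal_id not in series_map:
        raise KeyError(f"no series for focal cell {focal_id}")
    focal = series_map[focal_id]
    others = [s for cid, s in series_map.items() if cid != focal_id]
    states = {s.transformed for s in series_map.values()}
    if len(states) > 1:
        raise ValueError("all series must share the same transform state")
    total = np.zeros(len(focal))
    count = np.zeros(len(focal), dtype=int)
    for s in others:
        idx = np.searchsorted(focal.frames, s.frames)
        ok = (idx < len(focal)) & (s.frames == focal.frames[np.minimum(idx, len(focal) - 1)])
        np.add.at(total, idx[ok], s.values[ok])
        np.add.at(count, idx[ok], 1)
    present = count > 0
    if not present.any():
        raise ValueError(
            f"cell {focal_id} has no contemporaneous sibling on any frame"
        )
    return ContextSeries(
        focal_id=focal_id,
        frames=focal.frames[present],
        values=total[present] / count[present],
        transformed=focal.transformed,
    )


def coarse_grain(series: CellSeries, block: int) -> CellSeries:
    """Average non-overlapping blocks of ``block`` samples.

    The trailing partial block is dropped; the frame of each block is the
    frame of its first sample, the grid step and dt scale by ``block``.
    """
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    if block == 1:
        return replace(series)
    n = len(series)
    if block > n:
        raise ValueError(f"block {block} exceeds series length {n}")
    m = n // block
    vals = series.values[: m * block].reshape(m, block).mean(axis=1)
    frames = series.frames[: m * block : block]
    return CellSeries(
        cell_id=series.cell_id,
        frames=frames,
        values=vals,
        dt=series.dt * block,
        stride=series.stride * block,
        transformed=series.transformed,
    )


def coarse_grain_context(context: ContextSeries, block: int) -> ContextSeries:
    """Block-average a context series (mean-fields commute with blocking)."""
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    if block == 1:
        return ContextSeries(context.focal_id, context.frames, context.values,
                             context.transformed)
    n = len(context)
    if block > n:
        raise ValueError(f"block {block} exceeds context length {n}")
    m = n // block
    vals = context.values[: m * block].reshape(m, block).mean(axis=1)
    frames = context.frames[: m * block : block]
    return ContextSeries(context.focal_id, frames, vals, context.transformed)


# -- CSV interfaces -----------------------------------------------------


def read_ke_csv(path: str | Path, dt: float = DEFAULT_DT) -> dict[int, CellSeries]:
    """Long-form KE table (cell_id, frame, ke) -> series per cell."""
    df = pd.read_csv(path)
    need = {"cell_id", "frame", "ke"}
    if not need.issubset(df.columns):
        raise ValueError(f"KE csv must have columns {sorted(need)}")
    out = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        out[int(cid)] = CellSeries(
            cell_id=int(cid),
            frames=grp["frame"].to_numpy(),
            values=grp["ke"].to_numpy(),
            dt=dt,
        )
    return out


def write_ke_csv(series_map: dict[int, CellSeries], path: str | Path) -> None:
    parts = [
        pd.DataFrame(
            {"cell_id": s.cell_id, "frame": s.frames, "ke": s.values}
        )
        for s in series_map.values()
    ]
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)


def read_track_csv(path: str | Path, dt: float = DEFAULT_DT) -> dict[int, CellSeries]:
    """Trajectory table (frame, cell_id, x, y) -> KE series per cell."""
    df = pd.read_csv(path)
    need = {"frame", "cell_id", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"track csv must have columns {sorted(need)}")
    out = {}
    for cid, grp in df.groupby("cell_id"):
        grp = grp.sort_values("frame")
        out[int(cid)] = kinetic_energy(
            grp[["frame", "x", "y"]].to_numpy(), dt=dt, cell_id=int(cid)
        )
    return out
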