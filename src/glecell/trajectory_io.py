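"""Trajectory ingest, validation, smoothing, and differentiation.

Conventions used throughout the package:

* time in seconds, positions in micrometers;
* positions are indexed 0..N (N+1 samples at a uniform step ``dt``);
* velocities live on half steps i+1/2 and are indexed 0..N-1,
  ``v[i] = (x[i+1] - x[i]) / dt``.

Gaps (NaN rows) and non-uniform sampling are hard errors at ingest: every
downstream estimator assumes a complete, uniformly sampled series and silent
interpolation would bias the short-lag correlations this package lives on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GapError, LengthError, ParameterError, SamplingError

#: relative tolerance on |t[i+1]-t[i]-dt| / dt
UNIFORMITY_RTOL = 1e-6

#: default minimum number of position samples
DEFAULT_MIN_LENGTH = 500

DEFAULT_COLUMNS = {"time": "time", "x": "x", "y": "y"}


@dataclass
class Trajectory:
    """Uniformly sampled 2-D cell-center trajectory.

    Attributes
    ----------
    cell_id : str
        Identifier of the cell the trajectory belongs to.
    times : ndarray, shape (N+1,)
        Sample times in seconds, strictly increasing, uniform step.
    x, y : ndarray, shape (N+1,)
        Positions in micrometers.
    dt : float
        Time step in seconds.
    meta : dict
        Provenance (smoothing window, units, source file, ...).
    """

    cell_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) < 2:
            raise LengthError(f"{self.cell_id}: trajectory needs at least 2 samples")
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise LengthError(
                f"{self.cell_id}: times/x/y lengths differ "
                f"({len(self.times)}/{len(self.x)}/{len(self.y)})"
            )
        for name, arr in (("times", self.times), ("x", self.x), ("y", self.y)):
            if np.isnan(arr).any():
                raise GapError(f"{self.cell_id}: NaN values in column '{name}'")
        if len(self.times) >= 2:
            diffs = np.diff(self.times)
            if np.max(np.abs(diffs - self.dt)) > UNIFORMITY_RTOL * self.dt:
                raise SamplingError(
                    f"{self.cell_id}: non-uniform sampling "
                    f"(max deviation {np.max(np.abs(diffs - self.dt)):.3g} s)"
                )

    @property
    def n_steps(self) -> int:
        """Number of steps N (positions are N+1)."""
        return len(self.times) - 1

    def positions(self) -> np.ndarray:
        """Positions as a (2, N+1) array (row 0 = x, row 1 = y)."""
        return np.vstack([self.x, self.y])


@dataclass
class VelocitySeries:
    """Half-step finite-difference velocities of one cell.

    ``v`` has shape (n_components, N); component c, entry i is
    v_{i+1/2} of spatial component c, in μm/s.
    """

    cell_id: str
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if not np.isfinite(self.v).all():
            raise GapError(f"{self.cell_id}: non-finite velocities")

    @property
    def n(self) -> int:
        return self.v.shape[1]

    @property
    def n_components(self) -> int:
        return self.v.shape[0]


def read_trajectory(
    path: str | Path,
    column_map: dict | None = None,
    *,
    cell_id: str | None = None,
    time_unit: float = 1.0,
    length_unit: float = 1.0,
    min_length: int = DEFAULT_MIN_LENGTH,
    delimiter: str | None = None,
) -> Trajectory:
    """Read one cell's trajectory from a delimited text file.

    Parameters
    ----------
    path : path
        CSV/TSV file with a header row.
    column_map : dict, optional
        Maps canonical names ``time``/``x``/``y`` to file column names.
    time_unit, length_unit : float
        Multipliers converting file units to seconds / micrometers.
    min_length : int
        Minimum number of position samples; set to 0 to disable.

    Raises
    ------
    SamplingError, GapError, LengthError, ParameterError
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [c for c in (cols["time"], cols["x"], cols["y"]) if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    t = df[cols["time"]].to_numpy(dtype=float) * time_unit
    x = df[cols["x"]].to_numpy(dtype=float) * length_unit
    y = df[cols["y"]].to_numpy(dtype=float) * length_unit
    if np.isnan(t).any() or np.isnan(x).any() or np.isnan(y).any():
        raise GapError(f"{path}: file contains missing/NaN entries")
    if len(t) < max(min_length, 2):
        raise LengthError(f"{path}: {len(t)} samples < required minimum {max(min_length, 2)}")
    diffs = np.diff(t)
    if np.any(diffs <= 0):
        raise SamplingError(f"{path}: time column not strictly increasing")
    dt = float(np.median(diffs))
    if np.max(np.abs(diffs - dt)) > UNIFORMITY_RTOL * dt:
        raise SamplingError(
            f"{path}: non-uniform time step (median {dt:.6g} s, "
            f"max deviation {np.max(np.abs(diffs - dt)):.3g} s)"
        )
    cid = cell_id if cell_id is not None else path.stem
    meta = {"source": str(path), "time_unit": time_unit, "length_unit": length_unit}
    return Trajectory(cell_id=cid, times=t, x=x, y=y, dt=dt, meta=meta)


def write_trajectory(traj: Trajectory, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a trajectory as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time": traj.times, "x": traj.x, "y": traj.y})
    df.to_csv(path, index=False, float_format=float_format)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(traj.meta, cell_id=traj.cell_id, dt=traj.dt, units={"time": "s", "length": "um"})
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def smooth_positions(traj: Trajectory, window: int) -> Trajectory:
    """Running mean over ``window`` consecutive positions.

    Reduces localization noise before differentiation; window=1 is the
    identity. Output has N+2-window samples; dt is unchanged.
    """
    n = len(traj.times)
    if window < 1 or window >= n:
        raise ParameterError(f"smoothing window {window} invalid for length {n}")
    if window == 1:
        out = Trajectory(traj.cell_id, traj.times.copy(), traj.x.copy(), traj.y.copy(),
                         traj.dt, dict(traj.meta))
        out.meta["smoothing_window"] = 1
        return out
    kernel = np.full(window, 1.0 / window)
    xs = np.convolve(traj.x, kernel, mode="valid")
    ys = np.convolve(traj.y, kernel, mode="valid")
    ts = traj.times[: len(xs)] + 0.5 * (window - 1) * traj.dt
    meta = dict(traj.meta, smoothing_window=window)
    return Trajectory(traj.cell_id, ts, xs, ys, traj.dt, meta)


def velocities(traj: Trajectory) -> VelocitySeries:
    """Half-step finite-difference velocities v_{i+1/2} = (x_{i+1}-x_i)/dt."""
    v = np.diff(traj.positions(), axis=1) / traj.dt
    return VelocitySeries(cell_id=traj.cell_id, v=v, dt=traj.dt)


def integrate_velocities(vel: VelocitySeries, x0: np.ndarray | float = 0.0) -> np.ndarray:
    """Inverse of :func:`velocities`: cumulative sum of v*dt from x0.

    Returns a (n_components, N+1) position array.
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.size == 1:
        x0 = np.full(vel.n_components, x0.item())
    steps = np.cumsum(vel.v * vel.dt, axis=1)
    return np.hstack([x0[:, None], x0[:, None] + steps])
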