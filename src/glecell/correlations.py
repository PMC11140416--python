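"""VACF / MSD estimation and Gaussian-process diagnostics.

The velocity autocorrelation function (VACF) C_vv(iΔ) and the mean-squared
displacement (MSD) are estimated as time averages over all overlapping pairs
of a stationary series, per spatial component, then averaged over the two
components (x and y are statistically independent in the model, so averaging
the correlation estimates is the unbiased combination).

Because the process is assumed Gaussian and stationary, the whole two-point
statistics follow from the VACF alone: the conditional distribution of
v(t+lag) given v(t)=v1 is Gaussian with mean v1*C(lag)/C(0) and variance
C(0) - C(lag)^2/C(0). The diagnostics here check exactly that on data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ParameterError
from .trajectory_io import Trajectory, VelocitySeries


class CorrKind(str, Enum):
    VACF = "VACF"
    MSD = "MSD"


@dataclass
class CorrelationFunction:
    """Lag-indexed correlation estimate.

    ``lags`` are times iΔ in seconds starting at 0; ``values`` are μm²/s²
    (VACF) or μm² (MSD); ``counts`` is the number of averaged pairs per lag
    per component.
    """

    kind: CorrKind
    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    n_components: int = 1
    dt: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.dt is None:
            self.dt = float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.lags)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"# kind: {self.kind.value}\n"
            f"# dt_s: {self.dt!r}\n"
            f"# n_components: {self.n_components}\n"
            "lag_s,value,count\n"
        )
        rows = "\n".join(
            f"{l:.10g},{v:.10g},{c}" for l, v, c in zip(self.lags, self.values, self.counts)
        )
        path.write_text(header + rows + "\n")


@dataclass
class GaussianConditional:
    """Parameters of p(v2, t1+lag | v1, t1) for a stationary Gaussian process."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ParameterError(f"negative conditional variance {self.variance}")


def _acf_fft(v: np.ndarray, max_lag: int) -> np.ndarray:
    """Unnormalized autocovariance sums S_i = sum_j v_j v_{j+i} via FFT."""
    n = len(v)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    f = np.fft.rfft(v, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov


def vacf(vel: VelocitySeries, max_lag: int | None = None) -> CorrelationFunction:
    """Time-averaged VACF, per component then averaged over components.

    C_i = (1/(n_v - i)) * sum_{j} v_{j+1/2} v_{j+i+1/2}, with n_v - i
    overlapping pairs at lag i.
    """
    n = vel.n
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag < n:
        raise ParameterError(f"max_lag {max_lag} must be in [0, {n - 1}]")
    counts = n - np.arange(max_lag + 1)
    vals = np.zeros(max_lag + 1)
    for comp in vel.v:
        vals += _acf_fft(comp, max_lag) / counts
    vals /= vel.n_components
    lags = np.arange(max_lag + 1) * vel.dt
    return CorrelationFunction(CorrKind.VACF, lags, vals, counts,
                               n_components=vel.n_components, dt=vel.dt)


def msd(traj: Trajectory, max_lag: int | None = None) -> CorrelationFunction:
    """Time-averaged MSD over all overlapping start points, component-averaged."""
    pos = traj.positions()
    n = pos.shape[1]
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag < n:
        raise ParameterError(f"max_lag {max_lag} must be in [0, {n - 1}]")
    vals = np.zeros(max_lag + 1)
    counts = n - np.arange(max_lag + 1)
    for comp in pos:
        for i in range(1, max_lag + 1):
            d = comp[i:] - comp[:-i]
            vals[i] += np.mean(d * d)
    vals /= pos.shape[0]
    lags = np.arange(max_lag + 1) * traj.dt
    return CorrelationFunction(CorrKind.MSD, lags, vals, counts,
                               n_components=pos.shape[0], dt=traj.dt)


def second_difference_stencil(msd_values: np.ndarray, dt: float) -> np.ndarray:
    """VACF from an MSD series via C(iΔ) = (M_{i+1} - 2 M_i + M_{i-1}) / (2Δ²).

    At i=0 the even extension M_{-1} = M_1 is used (the MSD of a stationary
    process is even in the lag). Output has len(msd_values) - 1 entries.
    """
    m = np.asarray(msd_values, dtype=float)
    if len(m) < 2:
        raise ParameterError("need at least 2 MSD values")
    out = np.empty(len(m) - 1)
    out[0] = (m[1] - 2.0 * m[0] + m[1]) / (2.0 * dt * dt)
    if len(m) > 2:
        out[1:] = (m[2:] - 2.0 * m[1:-1] + m[:-2]) / (2.0 * dt * dt)
    return out


def msd_vacf_consistency(msd_cf: CorrelationFunction, vacf_cf: CorrelationFunction) -> dict:
    """Sanity check: the discrete curvature of the MSD should reproduce the VACF.

    Returns a report with the per-lag residuals and their max absolute value
    over the shared lag range (reported, not thresholded).
    """
    if abs(msd_cf.dt - vacf_cf.dt) > 1e-12 * max(msd_cf.dt, vacf_cf.dt):
        raise ParameterError(f"dt mismatch: {msd_cf.dt} vs {vacf_cf.dt}")
    stencil = second_difference_stencil(msd_cf.values, msd_cf.dt)
    n = min(len(stencil), len(vacf_cf.values))
    residuals = stencil[:n] - vacf_cf.values[:n]
    return {
        "lags": vacf_cf.lags[:n],
        "residuals": residuals,
        "max_abs_residual": float(np.max(np.abs(residuals))) if n else 0.0,
    }


def rescale_velocities(
    vels: Iterable[VelocitySeries], mode: str = "per_cell"
) -> dict:
    """Standardize pooled component velocities per cell or over the ensemble.

    ``per_cell`` subtracts each cell's own mean and divides by its own std
    (the rescaling under which Gaussian single-cell distributions collapse
    onto the standard normal); ``ensemble`` uses the pooled mean/std of all
    cells, which does NOT collapse a heterogeneous population.
    """
    if mode not in ("per_cell", "ensemble"):
        raise ParameterError(f"unknown mode {mode!r}")
    vels = list(vels)
    per_cell_stats = {}
    pooled_raw = []
    for vel in vels:
        sample = vel.v.ravel()
        mu, sd = float(np.mean(sample)), float(np.std(sample))
        if sd == 0.0:
            raise DegenerateInputError(f"{vel.cell_id}: zero velocity std")
        per_cell_stats[vel.cell_id] = {"mean": mu, "std": sd}
        pooled_raw.append(sample)
    if mode == "per_cell":
        samples = np.concatenate(
            [(s - per_cell_stats[v.cell_id]["mean"]) / per_cell_stats[v.cell_id]["std"]
             for v, s in zip(vels, pooled_raw)]
        )
    else:
        allv = np.concatenate(pooled_raw)
        mu, sd = float(np.mean(allv)), float(np.std(allv))
        if sd == 0.0:
            raise DegenerateInputError("zero pooled velocity std")
        samples = (allv - mu) / sd
    return {"samples": samples, "per_cell": per_cell_stats, "mode": mode}


def conditional_velocity(
    vacf_cf: CorrelationFunction, v1: float, lag: int
) -> GaussianConditional:
    """Conditional law of v(t+lag·Δ) given v(t) = v1, from the VACF alone."""
    if not 0 <= lag < len(vacf_cf):
        raise ParameterError(f"lag {lag} outside VACF range [0, {len(vacf_cf) - 1}]")
    c0 = vacf_cf.values[0]
    cl = vacf_cf.values[lag]
    if c0 <= 0:
        raise DegenerateInputError("Cvv(0) must be positive")
    if abs(cl) > c0:
        raise ParameterError(
            f"|Cvv(lag)| = {abs(cl):.6g} > Cvv(0) = {c0:.6g}: covariance not PSD; "
            "truncate noisy long lags before conditioning"
        )
    return GaussianConditional(mean=v1 * cl / c0, variance=c0 - cl * cl / c0)


def binned_conditional(
    vel: VelocitySeries, lag: int, bin_edges: Sequence[float]
) -> dict:
    """Empirical conditional mean/variance of v(t+lag) binned on v(t).

    Pools both spatial components. Used to validate the Gaussian two-point
    law against :func:`conditional_velocity`.
    """
    if lag < 1 or lag >= vel.n:
        raise ParameterError(f"lag {lag} out of range")
    v1 = np.concatenate([c[:-lag] for c in vel.v])
    v2 = np.concatenate([c[lag:] for c in vel.v])
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(v1, edges) - 1
    nb = len(edges) - 1
    centers = np.empty(nb)
    means = np.full(nb, np.nan)
    variances = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        counts[b] = int(sel.sum())
        centers[b] = float(np.mean(v1[sel])) if counts[b] else 0.5 * (edges[b] + edges[b + 1])
        if counts[b] >= 2:
            means[b] = float(np.mean(v2[sel]))
            variances[b] = float(np.var(v2[sel]))
    return {"centers": centers, "means": means, "variances": variances, "counts": counts}


def moment_report(samples: np.ndarray) -> dict:
    """Mean / std / excess kurtosis with CLT-scale reference bounds.

    Surrogate for the visual 'collapse onto the normal curve' check: for
    standardized Gaussian samples |mean| and |std-1| are O(1/sqrt(n)) and
    the excess kurtosis is ~0; a bimodal mixture drives kurtosis negative.
    """
    s = np.asarray(samples, dtype=float)
    n = len(s)
    m2 = np.mean((s - s.mean()) ** 2)
    m4 = np.mean((s - s.mean()) ** 4)
    return {
        "n": n,
        "mean": float(np.mean(s)),
        "std": float(np.std(s)),
        "excess_kurtosis": float(m4 / m2**2 - 3.0),
        "clt_bound": 4.0 / np.sqrt(n),
    }
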