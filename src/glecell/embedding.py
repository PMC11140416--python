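"""Markovian-embedding simulator: synthetic trajectories with known kernels.

A non-Markovian GLE with the oscillatory kernel

    Γ(t) = 2a δ(t) + b e^{−t/τ} [cos(Ωt) + (1/(τΩ)) sin(Ωt)]

is exactly equivalent to a Markovian system of two harmonically coupled
degrees of freedom: the observed coordinate x (mass m, friction γ_x) and a
hidden coordinate y (mass m_y, friction γ_y), coupled with spring constant
K and driven by independent white noises obeying the fluctuation-dissipation
relation at temperature k_BT.  The parameter map is

    a = γ_x / m,   b = K / m,   τ = 2 m_y / γ_y,   Ω = sqrt(K/m_y − 1/τ²),

valid while the hidden mode is underdamped (K/m_y > 1/τ²).  When τΩ is
large the sin correction 1/(τΩ) is negligible and the kernel reduces to the
pure-cosine fitting model.

The coupled system is a 4-dimensional linear SDE per spatial component, so
its transition over any step h is exactly Gaussian: z_{n+1} = E z_n + ξ_n
with E = e^{Mh} and cov(ξ) = ∫₀ʰ e^{Ms} Q e^{Mᵀs} ds (computed by the
Van Loan block-exponential).  The simulator therefore has no time-step
discretization error; sampling starts from the stationary (equilibrium)
distribution so every output is a stationary Gaussian process from step 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.signal import lfilter

from .errors import ConfigError, DomainError, ResolutionError
from .kernel_model import KernelParams, OMEGA_BOUNDS, TAU_BOUNDS
from .trajectory_io import Trajectory

#: internal substep must satisfy h * max_rate < this
RATE_RESOLUTION = 0.1

#: sin-correction coefficients at or above this are flagged as non-negligible
SIN_COEFF_FLAG = 0.1

_MAX_SUBSTEPS = 1000


@dataclass
class EmbeddingParams:
    """Parameters of the coupled two-coordinate Langevin system."""

    m: float
    m_y: float
    gamma_x: float
    gamma_y: float
    K: float
    kT: float

    def __post_init__(self) -> None:
        for name in ("m", "m_y", "gamma_x", "gamma_y", "K", "kT"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")

    @property
    def max_rate(self) -> float:
        """Fastest dynamical rate (largest drift-eigenvalue magnitude plus
        the bare frictions); valid for oscillatory and overdamped regimes."""
        M, _ = _drift_diffusion(self)
        return float(
            max(
                np.max(np.abs(np.linalg.eigvals(M))),
                self.gamma_x / self.m,
                self.gamma_y / self.m_y,
            )
        )


def embedding_to_kernel(e: EmbeddingParams) -> tuple[KernelParams, float]:
    """Effective-kernel parameters (a, b, τ, Ω) and the sin coefficient 1/(τΩ).

    Raises :class:`DomainError` when the hidden mode is overdamped, reporting
    the critical coupling below which no oscillatory kernel exists.
    """
    tau = 2.0 * e.m_y / e.gamma_y
    disc = e.K / e.m_y - 1.0 / tau**2
    if disc <= 0:
        k_crit = e.m_y / tau**2
        raise DomainError(
            f"overdamped hidden mode: K/m_y = {e.K / e.m_y:.6g} <= 1/tau^2 = "
            f"{1.0 / tau**2:.6g}; need K > {k_crit:.6g}"
        )
    omega = math.sqrt(disc)
    p = KernelParams(a=e.gamma_x / e.m, b=e.K / e.m, tau=tau, omega=omega)
    return p, 1.0 / (tau * omega)


def kernel_to_embedding(p: KernelParams, B: float) -> EmbeddingParams:
    """Invert the parameter map with the gauge m := 1 (only ratios are
    identifiable from trajectories); round-trips exactly."""
    m = 1.0
    K = p.b * m
    m_y = K / (p.omega**2 + 1.0 / p.tau**2)
    gamma_y = 2.0 * m_y / p.tau
    return EmbeddingParams(m=m, m_y=m_y, gamma_x=p.a * m, gamma_y=gamma_y, K=K, kT=B * m)


def _drift_diffusion(e: EmbeddingParams) -> tuple[np.ndarray, np.ndarray]:
    """Drift matrix M and noise covariance rate Q for state z = (x, v, y, v_y)."""
    M = np.array(
        [
            [0.0, 1.0, 0.0, 0.0],
            [-e.K / e.m, -e.gamma_x / e.m, e.K / e.m, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [e.K / e.m_y, 0.0, -e.K / e.m_y, -e.gamma_y / e.m_y],
        ]
    )
    Q = np.zeros((4, 4))
    Q[1, 1] = 2.0 * e.gamma_x * e.kT / e.m**2
    Q[3, 3] = 2.0 * e.gamma_y * e.kT / e.m_y**2
    return M, Q


def _discrete_update(M: np.ndarray, Q: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-step propagator E and noise covariance S over step h
    (Van Loan block-exponential)."""
    n = M.shape[0]
    H = np.zeros((2 * n, 2 * n))
    H[:n, :n] = M
    H[:n, n:] = Q
    H[n:, n:] = -M.T
    Phi = expm(H * h)
    E = Phi[:n, :n]
    S = Phi[:n, n:] @ E.T
    return E, 0.5 * (S + S.T)


def _cov_sqrt(S: np.ndarray) -> np.ndarray:
    lam, U = np.linalg.eigh(S)
    return U * np.sqrt(np.clip(lam, 0.0, None))


def _run_component(E: np.ndarray, L: np.ndarray, z0: np.ndarray,
                   n_total: int, rng: np.random.Generator) -> np.ndarray:
    """States z_0..z_{n_total} of z_{n+1} = E z_n + L η_n, via the eigenbasis
    of E so each mode reduces to a scalar AR(1) filtered with lfilter."""
    d, V = np.linalg.eig(E)
    eta = rng.standard_normal((n_total, E.shape[0]))
    xi = eta @ L.T
    Vinv = np.linalg.inv(V)
    inp = np.empty((n_total + 1, E.shape[0]), dtype=complex)
    inp[0] = Vinv @ z0
    inp[1:] = xi @ Vinv.T
    w = np.empty_like(inp)
    for j in range(E.shape[0]):
        w[:, j] = lfilter([1.0], [1.0, -d[j]], inp[:, j])
    return np.real(w @ V.T)


def simulate(
    e: EmbeddingParams,
    n_steps: int,
    dt: float,
    seed: int,
    *,
    cell_id: str = "sim",
    return_velocities: bool = False,
) -> Trajectory | tuple[Trajectory, np.ndarray]:
    """Simulate a 2-D trajectory (two independent 1-D embedding processes).

    The internal substep is chosen so that h * max_rate < 0.1 and the output
    is decimated to ``dt``; the update itself is exact at any step, so the
    substepping only enforces the stated resolution contract.  With
    ``return_velocities`` the true (state) velocities at the output times are
    returned as well, shape (2, n_steps+1).
    """
    n_sub = max(1, math.ceil(dt * e.max_rate / RATE_RESOLUTION))
    if n_sub > _MAX_SUBSTEPS:
        raise ResolutionError(
            f"dt = {dt} needs {n_sub} substeps (> {_MAX_SUBSTEPS}); reduce dt"
        )
    h = dt / n_sub
    M, Q = _drift_diffusion(e)
    E, S = _discrete_update(M, Q, h)
    L = _cov_sqrt(S)
    rng = np.random.default_rng(seed)
    n_total = n_steps * n_sub
    pos = np.empty((2, n_steps + 1))
    vel = np.empty((2, n_steps + 1))
    for comp in range(2):
        # stationary (Gibbs) start: v, v_y, and r = x - y independent Gaussians
        v0 = rng.normal(0.0, math.sqrt(e.kT / e.m))
        vy0 = rng.normal(0.0, math.sqrt(e.kT / e.m_y))
        r0 = rng.normal(0.0, math.sqrt(e.kT / e.K))
        z0 = np.array([0.0, v0, -r0, vy0])
        z = _run_component(E, L, z0, n_total, rng)[::n_sub]
        pos[comp] = z[:, 0]
        vel[comp] = z[:, 1]
    times = np.arange(n_steps + 1) * dt
    traj = Trajectory(
        cell_id=cell_id, times=times, x=pos[0], y=pos[1], dt=dt,
        meta={"simulator": "markovian_embedding", "seed": seed, "n_substeps": n_sub},
    )
    return (traj, vel) if return_velocities else traj


def add_localization_noise(traj: Trajectory, sigma_loc: float, seed: int) -> Trajectory:
    """Add i.i.d. Gaussian position noise of width σ_loc to every sample."""
    if sigma_loc < 0:
        raise ConfigError("sigma_loc must be >= 0")
    if sigma_loc == 0:
        return traj
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma_loc, size=(2, len(traj.times)))
    meta = dict(traj.meta, sigma_loc=sigma_loc, noise_seed=seed)
    return Trajectory(traj.cell_id, traj.times.copy(), traj.x + noise[0],
                      traj.y + noise[1], traj.dt, meta)


@dataclass
class PopulationSpec:
    """Specification of one synthetic cell population.

    ``center`` holds the population-median kernel parameters and B;
    ``spread`` is the log-normal sigma of each parameter's multiplicative
    scatter (a scalar applies to all five parameters).  Defaults mirror the
    experimental regime: Δ = 0.002 s, trajectories of 10³–10⁴ steps or more,
    localization noise ~0.02 μm.
    """

    name: str
    n_cells: int
    center: KernelParams
    B: float
    spread: float | dict = 0.15
    sigma_loc: float = 0.0
    n_steps: int = 10_000
    dt: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        spreads = self.spread.values() if isinstance(self.spread, dict) else [self.spread]
        if any(s < 0 for s in spreads):
            raise ConfigError("spread must be >= 0")


_PARAM_NAMES = ("a", "b", "tau", "omega", "B")
_MAX_REDRAWS = 200


def _draw_cell_params(spec: PopulationSpec, rng: np.random.Generator) -> tuple[KernelParams, float]:
    center = {
        "a": spec.center.a, "b": spec.center.b, "tau": spec.center.tau,
        "omega": spec.center.omega, "B": spec.B,
    }
    spread = (
        {k: spec.spread.get(k, 0.0) for k in _PARAM_NAMES}
        if isinstance(spec.spread, dict)
        else {k: spec.spread for k in _PARAM_NAMES}
    )
    center_in_box = (
        TAU_BOUNDS[0] <= center["tau"] <= TAU_BOUNDS[1]
        and OMEGA_BOUNDS[0] <= center["omega"] <= OMEGA_BOUNDS[1]
    )
    for _ in range(_MAX_REDRAWS):
        vals = {k: center[k] * math.exp(spread[k] * rng.standard_normal())
                for k in _PARAM_NAMES}
        if center_in_box and not (
            TAU_BOUNDS[0] <= vals["tau"] <= TAU_BOUNDS[1]
            and OMEGA_BOUNDS[0] <= vals["omega"] <= OMEGA_BOUNDS[1]
        ):
            continue  # keep drawn cells inside the identifiable fit box
        return KernelParams(vals["a"], vals["b"], vals["tau"], vals["omega"]), vals["B"]
    raise ConfigError(f"population {spec.name!r}: redraw limit hit; spread too large")


def draw_population_params(spec: PopulationSpec) -> pd.DataFrame:
    """Ground-truth parameter table of a population without simulating.

    Used when only the parameter clouds are needed (e.g. clustering studies);
    :func:`generate_population` uses the same draws for its trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_cells):
        p, B = _draw_cell_params(spec, rng)
        rows.append({
            "cell_id": f"{spec.name}_{i:03d}", "population": spec.name,
            "a": p.a, "b": p.b, "tau": p.tau, "omega": p.omega, "B": B,
            "sigma_loc": spec.sigma_loc,
            "sim_seed": int(rng.integers(2**31)),
        })
    return pd.DataFrame(rows)


def generate_population(spec: PopulationSpec) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate every cell of a population; returns trajectories + truth table."""
    truth = draw_population_params(spec)
    trajectories = []
    for row in truth.itertuples():
        p = KernelParams(row.a, row.b, row.tau, row.omega)
        e = kernel_to_embedding(p, row.B)
        traj = simulate(e, spec.n_steps, spec.dt, int(row.sim_seed), cell_id=row.cell_id)
        if spec.sigma_loc > 0:
            traj = add_localization_noise(traj, spec.sigma_loc, int(row.sim_seed) + 1)
        trajectories.append(traj)
    return trajectories, truth
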