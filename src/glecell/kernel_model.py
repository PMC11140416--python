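"""Parametric memory kernel, exact forward model, and kernel/VACF fits.

Model
-----
The effective memory kernel of one cell is

    Γ(t) = 2 a δ(t) + b e^{−t/τ} [cos(Ωt) + c sin(Ωt)]

with δ-peak amplitude a (1/s), oscillation amplitude b (1/s²), decay time τ
(s), frequency Ω (1/s), and an optional sin-correction coefficient c (the
Markovian-embedding kernel has c = 1/(τΩ); the fitting model uses c = 0).
On a grid with step Δ the δ-peak contributes only to the initial value,
Γ(0) = 2a/Δ + b.

The VACF C(t) with C(0) = B obeys the linear Volterra equation

    C'(t) = −a C(t) − b ∫₀ᵗ e^{−(t−s)/τ}[cos + c sin](Ω(t−s)) C(s) ds,

which is solved exactly by two independent routes that serve as mutual
oracles: (i) augmenting the convolution with two auxiliary states gives a
3-variable linear ODE, propagated exactly by the matrix exponential; (ii)
the Laplace transform has a cubic denominator whose roots give the closed
form C(t) = Σ R_k e^{r_k t}.  The MSD follows as 2∫₀ᵗ(t−s)C(s)ds, again in
closed form.  Finite sampling and localization noise enter through the
second-difference stencil of the noisy MSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import qmc

from .correlations import CorrelationFunction, CorrKind, second_difference_stencil
from .errors import (
    DegenerateInputError,
    FitError,
    ParameterError,
    ResolutionError,
)
from .memory_extraction import MemoryKernel, extract_kernel

#: default fit window in seconds (short-time part of kernel / VACF)
DEFAULT_FIT_WINDOW = 0.2

#: hard fit constraints on decay time and frequency
TAU_BOUNDS = (0.05, 3.0)
OMEGA_BOUNDS = (20.0, 250.0)

#: a and b contributions each constrained to this fraction range of Γ0
AB_FRACTION_BOUNDS = (1e-3, 0.999)

SIGMA_LOC_BOUNDS = (0.0, 1.0)


@dataclass
class KernelParams:
    """Parameters (a, b, τ, Ω) of the oscillatory memory kernel."""

    a: float
    b: float
    tau: float
    omega: float

    def gamma0(self, dt: float) -> float:
        return 2.0 * self.a / dt + self.b

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.tau, self.omega])


@dataclass
class CellParams:
    """Per-cell fit result: kernel parameters plus B and optional σ_loc."""

    kernel: KernelParams
    B: float
    sigma_loc: float | None = None
    fit_errors: dict = field(default_factory=dict)
    cell_id: str = ""
    flags: list = field(default_factory=list)
    cost: float = float("nan")

    def as_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "a": self.kernel.a,
            "b": self.kernel.b,
            "tau": self.kernel.tau,
            "omega": self.kernel.omega,
            "B": self.B,
            "sigma_loc": self.sigma_loc,
            "cost": self.cost,
            "flags": ";".join(self.flags),
        }
        for k, v in self.fit_errors.items():
            d[f"err_{k}"] = v
        return d


def kernel_eval(
    p: KernelParams, t: np.ndarray, dt: float, sin_coeff: float = 0.0
) -> np.ndarray:
    """Kernel on a uniform grid starting at 0; the δ-peak folds into Γ(0)."""
    t = np.asarray(t, dtype=float)
    osc = np.cos(p.omega * t)
    if sin_coeff:
        osc = osc + sin_coeff * np.sin(p.omega * t)
    vals = p.b * np.exp(-t / p.tau) * osc
    if t[0] == 0.0:
        vals[0] = 2.0 * p.a / dt + p.b
    return vals


def kernel_integral(p: KernelParams, t: np.ndarray) -> np.ndarray:
    """Closed-form G(t) = a + ∫₀ᵗ b e^{−s/τ} cos(Ωs) ds for the c=0 kernel.

    The δ-peak contributes its full weight a for any t > 0.
    """
    t = np.asarray(t, dtype=float)
    u = 1.0 / p.tau
    w = p.omega
    integral = (u - np.exp(-u * t) * (u * np.cos(w * t) - w * np.sin(w * t))) / (u * u + w * w)
    return p.a + p.b * integral


def _cubic_roots_residues(
    p: KernelParams, B: float, sin_coeff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Roots r_k of the characteristic cubic and residues R_k of Ĉ(s).

    Ĉ(s) = B ((s+u)² + Ω²) / D(s),
    D(s) = (s+a)((s+u)² + Ω²) + b (s + u + cΩ),  u = 1/τ.
    """
    u = 1.0 / p.tau
    w = p.omega
    coeffs = np.array(
        [
            1.0,
            p.a + 2.0 * u,
            u * u + w * w + 2.0 * p.a * u + p.b,
            p.a * (u * u + w * w) + p.b * (u + sin_coeff * w),
        ]
    )
    roots = np.roots(coeffs)
    dcoeffs = np.polyder(coeffs)
    residues = B * ((roots + u) ** 2 + w * w) / np.polyval(dcoeffs, roots)
    return roots, residues


def _check_resolution(p: KernelParams, dt: float) -> None:
    if dt * p.omega >= 0.5:
        raise ResolutionError(
            f"dt*omega = {dt * p.omega:.3g} >= 0.5: grid cannot resolve the oscillation"
        )


def forward_vacf(
    p: KernelParams,
    B: float,
    t_max: float,
    dt: float,
    method: str = "roots",
    sin_coeff: float = 0.0,
) -> CorrelationFunction:
    """Model VACF on the grid 0, Δ, ..., ≤ t_max; exact for both routes.

    ``method='roots'`` uses the characteristic-cubic closed form;
    ``method='ode'`` propagates the augmented 3-state linear ODE with the
    matrix exponential.  The two agree to ~1e-12 and cross-validate each
    other in the test suite.
    """
    _check_resolution(p, dt)
    n = int(math.floor(t_max / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    if p.b == 0.0:
        vals = B * np.exp(-p.a * t)
    elif method == "roots":
        roots, res = _cubic_roots_residues(p, B, sin_coeff)
        vals = np.real(np.exp(np.outer(t, roots)) @ res)
    elif method == "ode":
        u = 1.0 / p.tau
        A = np.array(
            [
                [-p.a, -p.b, -p.b * sin_coeff],
                [1.0, -u, -p.omega],
                [0.0, p.omega, -u],
            ]
        )
        P = expm(A * dt)
        y = np.array([B, 0.0, 0.0])
        vals = np.empty(n)
        for i in range(n):
            vals[i] = y[0]
            y = P @ y
    else:
        raise ParameterError(f"unknown method {method!r}")
    counts = np.zeros(n, dtype=int)
    return CorrelationFunction(CorrKind.VACF, t, vals, counts, n_components=1, dt=dt)


def forward_msd(
    p: KernelParams,
    B: float,
    t_max: float,
    dt: float,
    method: str = "roots",
    sin_coeff: float = 0.0,
) -> CorrelationFunction:
    """Model MSD 2∫₀ᵗ(t−s)C(s)ds on the grid; MSD(0)=0, short-time limit Bt²."""
    _check_resolution(p, dt)
    n = int(math.floor(t_max / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    if p.b == 0.0:
        a = p.a
        vals = 2.0 * B * (t / a - (1.0 - np.exp(-a * t)) / (a * a))
    elif method == "roots":
        roots, res = _cubic_roots_residues(p, B, sin_coeff)
        terms = (np.exp(np.outer(t, roots)) - 1.0 - np.outer(t, roots)) / roots**2
        vals = 2.0 * np.real(terms @ res)
    elif method == "ode":
        u = 1.0 / p.tau
        # states (C, Ic, Is, D=∫C, M=2∫(t−s)C ds): D' = C, M' = 2D
        A = np.zeros((5, 5))
        A[0, :3] = [-p.a, -p.b, -p.b * sin_coeff]
        A[1, :3] = [1.0, -u, -p.omega]
        A[2, :3] = [0.0, p.omega, -u]
        A[3, 0] = 1.0
        A[4, 3] = 2.0
        P = expm(A * dt)
        y = np.array([B, 0.0, 0.0, 0.0, 0.0])
        vals = np.empty(n)
        for i in range(n):
            vals[i] = y[4]
            y = P @ y
    else:
        raise ParameterError(f"unknown method {method!r}")
    vals[0] = 0.0
    counts = np.zeros(n, dtype=int)
    return CorrelationFunction(CorrKind.MSD, t, vals, counts, n_components=1, dt=dt)


def discretized_noisy_vacf(
    p: KernelParams,
    B: float,
    sigma_loc: float,
    n_lags: int,
    dt: float,
    sin_coeff: float = 0.0,
) -> CorrelationFunction:
    """Finite-Δ VACF including localization noise.

    Builds the noisy MSD  M_noise(iΔ) = M_theo(iΔ) + 2σ² (1−δ_{i0})  and
    applies the second-difference stencil (even extension at i=0).  The
    noise signature is the pair (+2σ²/Δ², −σ²/Δ²) at lags 0 and 1.
    """
    if n_lags < 1:
        raise ParameterError("n_lags must be >= 1")
    m = forward_msd(p, B, (n_lags + 1) * dt, dt, sin_coeff=sin_coeff).values.copy()
    if sigma_loc:
        m[1:] += 2.0 * sigma_loc**2
    vals = second_difference_stencil(m, dt)[: n_lags + 1]
    t = np.arange(n_lags + 1) * dt
    return CorrelationFunction(CorrKind.VACF, t, vals, np.zeros(n_lags + 1, dtype=int),
                               n_components=1, dt=dt)


# ---------------------------------------------------------------------------
# fitting


def _ab_bounds(gamma0: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Bounds on (a, b): each additive contribution to Γ0 = 2a/Δ + b is
    constrained to [0.1%, 99.9%] of the measured Γ0."""
    flo, fhi = AB_FRACTION_BOUNDS
    lo = np.array([flo * gamma0 * dt / 2.0, flo * gamma0])
    hi = np.array([fhi * gamma0 * dt / 2.0, fhi * gamma0])
    return lo, hi


def _multistart_draws(lo: np.ndarray, hi: np.ndarray, n: int, seed: int) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    return qmc.scale(sampler.random(n), lo, hi)


def _active_bound_flags(x: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                        names: list[str]) -> list[str]:
    flags = []
    for xi, l, h, nm in zip(x, lo, hi, names):
        span = max(h - l, 1e-300)
        if xi - l < 1e-3 * span or h - xi < 1e-3 * span:
            flags.append(f"bound_active:{nm}")
    return flags


def _fit_errors_from_jac(res, n_params: int) -> tuple[np.ndarray, list[str]]:
    """Parameter standard deviations from the Jacobian at the optimum."""
    flags: list[str] = []
    J = res.jac
    dof = max(J.shape[0] - n_params, 1)
    s2 = 2.0 * res.cost / dof
    JTJ = J.T @ J
    try:
        cond = np.linalg.cond(JTJ)
        if not np.isfinite(cond) or cond > 1e12:
            flags.append("ill_conditioned_covariance")
        cov = s2 * np.linalg.pinv(JTJ)
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        flags.append("covariance_failed")
        errs = np.full(n_params, np.nan)
    return errs, flags


def fit_kernel(
    kernel: MemoryKernel,
    window: float = DEFAULT_FIT_WINDOW,
    *,
    B: float | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> CellParams:
    """Least-squares fit of the parametric kernel to an extracted Γ(t).

    Fits (a, b, τ, Ω) to the first ``window`` seconds of the kernel,
    Γ(0) = 2a/Δ + b included.  Bounds follow the extraction's measured Γ0;
    Ω-multimodality is handled by multi-start from Latin-hypercube draws
    plus a heuristic start at the kernel's first minimum.
    """
    if kernel.gamma is None:
        raise ParameterError("kernel has no gamma values; run gamma_from_G first")
    dt = kernel.dt
    t = kernel.times
    sel = t <= window + 0.5 * dt
    t_fit, g_fit = t[sel], kernel.gamma[sel]
    if len(t_fit) < 5:
        raise ParameterError(f"window {window} s leaves only {len(t_fit)} kernel points")
    gamma0 = g_fit[0]
    if gamma0 <= 0:
        raise DegenerateInputError("non-positive Γ0; kernel carries no friction signal")
    ab_lo, ab_hi = _ab_bounds(gamma0, dt)
    lo = np.array([ab_lo[0], ab_lo[1], TAU_BOUNDS[0], OMEGA_BOUNDS[0]])
    hi = np.array([ab_hi[0], ab_hi[1], TAU_BOUNDS[1], OMEGA_BOUNDS[1]])

    def resid(x):
        return kernel_eval(KernelParams(*x), t_fit, dt) - g_fit

    starts = [_heuristic_kernel_start(t_fit, g_fit, dt, lo, hi)]
    if n_restarts > 0:
        starts.extend(_multistart_draws(lo, hi, n_restarts, seed))
    best = None
    for x0 in starts:
        try:
            r = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), x_scale="jac")
        except Exception:
            continue
        if r.success and (best is None or r.cost < best.cost):
            best = r
    if best is None:
        raise FitError("kernel fit failed to converge from all starts")
    names = ["a", "b", "tau", "omega"]
    errs, flags = _fit_errors_from_jac(best, 4)
    flags += _active_bound_flags(best.x, lo, hi, names)
    p = KernelParams(*best.x)
    return CellParams(
        kernel=p,
        B=float("nan") if B is None else float(B),
        fit_errors=dict(zip(names, errs)),
        cell_id=kernel.cell_id,
        flags=flags,
        cost=float(best.cost),
    )


def _heuristic_kernel_start(t, g, dt, lo, hi):
    """Data-driven initial guess: b from Γ(Δ), Ω from the first kernel minimum."""
    b0 = np.clip(g[1] if len(g) > 1 and g[1] > 0 else 0.3 * g[0], lo[1], hi[1])
    a0 = np.clip((g[0] - b0) * dt / 2.0, lo[0], hi[0])
    imin = int(np.argmin(g[1:])) + 1
    omega0 = np.clip(np.pi / (imin * dt), lo[3], hi[3])
    tau0 = np.clip(0.5 * t[-1], lo[2], hi[2])
    return np.array([a0, b0, tau0, omega0])


def fit_noisy_vacf(
    vacf_exp: CorrelationFunction,
    window: float = DEFAULT_FIT_WINDOW,
    *,
    n_restarts: int = 8,
    seed: int = 0,
) -> CellParams:
    """Fit the discretized noisy-VACF model to an experimental VACF.

    Optimizes (a, b, τ, Ω, B, σ_loc) so that the stencil of the noisy model
    MSD matches the measured VACF up to ``window`` seconds.  Used as a
    validation tool; the classification pipeline clusters the direct-kernel
    fit parameters.
    """
    dt = vacf_exp.dt
    n_lags = int(round(window / dt))
    if len(vacf_exp) < n_lags + 1:
        raise ParameterError(f"VACF covers {len(vacf_exp)} lags, window needs {n_lags + 1}")
    c_exp = vacf_exp.values[: n_lags + 1]
    c0 = c_exp[0]
    if c0 <= 0 or np.ptp(c_exp) <= 1e-12 * abs(c0):
        raise DegenerateInputError("flat or non-positive VACF")
    # Γ0 scale for the (a, b) bounds via a short preliminary Volterra extraction
    pre = extract_kernel(vacf_exp, n_steps=min(n_lags, len(vacf_exp) - 1))
    gamma0 = max(pre.gamma[0], 1e-300)
    ab_lo, ab_hi = _ab_bounds(gamma0, dt)
    lo = np.array([ab_lo[0], ab_lo[1], TAU_BOUNDS[0], OMEGA_BOUNDS[0],
                   1e-3 * c0, SIGMA_LOC_BOUNDS[0]])
    hi = np.array([ab_hi[0], ab_hi[1], TAU_BOUNDS[1], OMEGA_BOUNDS[1],
                   10.0 * c0, SIGMA_LOC_BOUNDS[1]])

    def resid(x):
        p = KernelParams(*x[:4])
        model = discretized_noisy_vacf(p, x[4], x[5], n_lags, dt)
        return model.values - c_exp

    warm = fit_kernel(gamma_filled(pre), window, n_restarts=2, seed=seed)
    x_warm = np.clip(
        np.array([warm.kernel.a, warm.kernel.b, warm.kernel.tau, warm.kernel.omega,
                  c0, 0.01]),
        lo, hi,
    )
    starts = [x_warm]
    if n_restarts > 0:
        draws = _multistart_draws(lo, hi, n_restarts, seed)
        draws[:, 4] = c0  # anchor B at its estimator; other params explore
        starts.extend(draws)
    best = None
    for x0 in starts:
        try:
            r = least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi), x_scale="jac")
        except Exception:
            continue
        if r.success and (best is None or r.cost < best.cost):
            best = r
    if best is None:
        raise FitError("noisy-VACF fit failed to converge from all starts")
    names = ["a", "b", "tau", "omega", "B", "sigma_loc"]
    errs, flags = _fit_errors_from_jac(best, 6)
    flags += _active_bound_flags(best.x, lo, hi, names)
    if len(c_exp) < 3 * 6:
        flags.append("underdetermined:window_too_short")
    return CellParams(
        kernel=KernelParams(*best.x[:4]),
        B=float(best.x[4]),
        sigma_loc=float(best.x[5]),
        fit_errors=dict(zip(names, errs)),
        flags=flags,
        cost=float(best.cost),
    )


def gamma_filled(kernel: MemoryKernel) -> MemoryKernel:
    """Ensure the kernel carries Γ values (no-op if already filled)."""
    if kernel.gamma is not None:
        return kernel
    from .memory_extraction import gamma_from_G

    return gamma_from_G(kernel)
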