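"""The deterministic Bayesian-mechanics dynamical system.

Treating the free-energy of a synaptic path as a classical action turns
free-energy minimization into Hamilton's principle, and the resulting
Hamiltonian equations of motion for Psi = (mu, w, p_mu, p_w) are

    mu_dot  = p_mu/m_mu + f(mu, w; s)
    w_dot   = p_w/m_w  + h(w, mu; s)
    p_mu_dot = -(p_mu df/dmu + p_w dh/dmu)
    p_w_dot  = -(p_mu df/dw  + p_w dh/dw)

Because the drifts are linear in the state, the system is affine,
Psi_dot = R(t) Psi + I, with a traceless block-triangular 4x4 matrix R and
a constant inhomogeneity I.  This module builds R and I, integrates the
equations (fixed-step RK4 or an adaptive wrapper around scipy), realizes
the closed-form matrix-exponential propagator for static input, and solves
and classifies the fixed point R Psi + I = 0.

The momentum equations are homogeneous in (p_mu, p_w): the zero-momentum
manifold is invariant, and on it the mechanics reduces exactly to the drift
ODE mu_dot = f, w_dot = h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import DegenerateSystemError, DivergenceError
from .model import ModelParams, PhaseState, Trajectory, hamiltonian
from .signals import PresynapticSignal

__all__ = [
    "LinearSystem",
    "FixedPointReport",
    "bm_rhs",
    "drift_jacobian",
    "build_linear_system",
    "integrate",
    "propagate_static",
    "fixed_point",
    "closed_form_fixed_point",
    "spectrum",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class LinearSystem:
    """The affine form Psi_dot = R Psi + I at one input value s."""

    R: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        I = np.asarray(self.I, dtype=float)
        if R.shape != (4, 4) or I.shape != (4,):
            raise ValueError("R must be 4x4 and I a 4-vector")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "I", I)

    @property
    def trace_residual(self) -> float:
        return float(np.trace(self.R))


@dataclass(frozen=True)
class FixedPointReport:
    """Equilibrium state of the affine system with its spectrum.

    ``stability`` classifies the dynamics of the state block (the
    zero-momentum manifold); the full spectrum is symmetric under negation,
    so the 4-D flow always has expanding directions in the momenta.
    """

    state: PhaseState
    eigenvalues: tuple
    stability: str
    momentum_components_zero: bool
    trace_residual: float

    def to_dict(self) -> dict:
        return {
            "state": {"mu": self.state.mu, "w": self.state.w,
                      "p_mu": self.state.p_mu, "p_w": self.state.p_w},
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "stability": self.stability,
            "momentum_components_zero": self.momentum_components_zero,
            "trace_residual": self.trace_residual,
        }


def drift_jacobian(s: float, params: ModelParams) -> np.ndarray:
    """Jacobian of the drift field (f, h) with respect to (mu, w)."""
    gw = params.effective_gamma_w(s)
    return np.array([[-params.gamma_mu, s],
                     [params.hebbian_sign * s, -gw]], dtype=float)


def _rhs(t: float, psi, signal: PresynapticSignal, params: ModelParams):
    """Right-hand side of Hamilton's equations as a plain 4-array.

    The momentum block is -J(s)^T p with J the analytic drift Jacobian, so
    any drift variant stays consistent automatically.
    """
    mu, w, p_mu, p_w = psi
    s = signal.evaluate(t)
    gw = params.effective_gamma_w(s)
    f = -params.gamma_mu * (mu - params.mu_d) + w * s
    h = -gw * (w - params.w_d) + params.hebbian_sign * s * mu
    sign_s = params.hebbian_sign * s
    return np.array([
        p_mu / params.m_mu + f,
        p_w / params.m_w + h,
        params.gamma_mu * p_mu - sign_s * p_w,
        gw * p_w - s * p_mu,
    ])


def bm_rhs(t: float, state, signal: PresynapticSignal,
           params: ModelParams) -> np.ndarray:
    """Evaluate Hamilton's equations at time t.

    ``state`` may be a :class:`PhaseState` or a length-4 sequence.  With
    Hebbian sign +1 this is the canonical form (p_mu_dot = gamma_mu p_mu -
    s p_w, p_w_dot = gamma_w p_w - s p_mu); the momentum terms are derived
    from the analytic drift Jacobian, not hard-coded.
    """
    psi = state.as_array() if isinstance(state, PhaseState) else np.asarray(state, dtype=float)
    if psi.shape != (4,):
        raise ValueError(f"state must be a 4-vector, got shape {psi.shape}")
    return _rhs(t, psi, signal, params)


def build_linear_system(s: float, params: ModelParams) -> LinearSystem:
    """Assemble R and I of the affine form Psi_dot = R Psi + I.

    R is traceless by construction (the +/-gamma and +/-s entries are
    placed antisymmetrically between the state and momentum blocks) and
    block upper-triangular: the momenta never feed back into themselves
    through the state.
    """
    g_mu, sign = params.gamma_mu, params.hebbian_sign
    gw = params.effective_gamma_w(s)
    R = np.array([
        [-g_mu, s, 1.0 / params.m_mu, 0.0],
        [sign * s, -gw, 0.0, 1.0 / params.m_w],
        [0.0, 0.0, g_mu, -sign * s],
        [0.0, 0.0, -s, gw],
    ])
    I = np.array([params.gamma_mu * params.mu_d, gw * params.w_d, 0.0, 0.0])
    return LinearSystem(R=R, I=I)


def _energies(traj_psi: np.ndarray, s_values: np.ndarray, params: ModelParams):
    """Per-point Lagrangian and Hamiltonian along an integrated path.

    Along a solution the rate residuals equal p/m, so the on-path
    Lagrangian is the kinetic form p_mu^2/2m_mu + p_w^2/2m_w.
    """
    mu, w, p_mu, p_w = traj_psi.T
    L = p_mu ** 2 / (2 * params.m_mu) + p_w ** 2 / (2 * params.m_w)
    H = hamiltonian((mu, w, p_mu, p_w), s_values, params)
    return L, np.asarray(H, dtype=float)


def integrate(initial: PhaseState, signal: PresynapticSignal,
              params: ModelParams, t_end: float, dt: float,
              method: str = "rk4") -> Trajectory:
    """Integrate the Bayesian mechanics on a uniform grid [0, t_end].

    ``method="rk4"`` is a classical fixed-step fourth-order scheme evaluated
    directly on the grid; ``method="adaptive"`` delegates to scipy's RK45
    (rtol 1e-8, atol 1e-10) and samples the dense output back onto the
    grid.  Per-point Lagrangian and Hamiltonian values and the accumulated
    (trapezoid) action are attached to the returned trajectory.

    Raises
    ------
    DivergenceError
        If the state leaves the finite domain; saddle configurations with
        generic momenta are expected to do this.
    """
    if not (t_end > 0 and dt > 0 and dt <= t_end):
        raise ValueError("need 0 < dt <= t_end")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    if not isinstance(initial, PhaseState):
        initial = PhaseState.from_array(initial)
    psi0 = initial.as_array()

    if method == "rk4":
        out = np.empty((n + 1, 4))
        out[0] = psi0
        psi = psi0
        with np.errstate(over="ignore", invalid="ignore"):
            for i in range(n):
                t = times[i]
                k1 = _rhs(t, psi, signal, params)
                k2 = _rhs(t + 0.5 * dt, psi + 0.5 * dt * k1, signal, params)
                k3 = _rhs(t + 0.5 * dt, psi + 0.5 * dt * k2, signal, params)
                k4 = _rhs(t + dt, psi + dt * k3, signal, params)
                psi = psi + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                if not np.all(np.isfinite(psi)):
                    raise DivergenceError(
                        f"trajectory diverged near t={times[i + 1]:.6g}",
                        time=float(times[i + 1]), step=i + 1)
                out[i + 1] = psi
    elif method == "adaptive":
        sol = solve_ivp(lambda t, y: _rhs(t, y, signal, params),
                        (0.0, float(times[-1])), psi0, method="RK45",
                        t_eval=times, rtol=1e-8, atol=1e-10)
        if not sol.success or sol.y.shape[1] != len(times):
            t_fail = sol.t[-1] if sol.t.size else 0.0
            raise DivergenceError(
                f"adaptive integration failed near t={t_fail:.6g}: {sol.message}",
                time=float(t_fail))
        out = sol.y.T
        if not np.all(np.isfinite(out)):
            raise DivergenceError("adaptive integration produced non-finite states")
    else:
        raise ValueError(f"unknown method {method!r}; use 'rk4' or 'adaptive'")

    s_values = signal.values(times)
    L, H = _energies(out, s_values, params)
    action = float(np.trapezoid(L, times))
    return Trajectory(times=times, psi=out, signal_values=s_values,
                      lagrangian_values=L, hamiltonian_values=H,
                      cumulative_action=action)


def propagate_static(initial: PhaseState, s_const: float,
                     params: ModelParams, t: float) -> PhaseState:
    """Closed-form propagation under a constant input.

    For static s the affine system has the exact solution
    Psi(t) = e^{Rt} Psi(0) + (integral of e^{R(t-t')} dt') I, evaluated here
    through the exponential of the augmented matrix [[R, I], [0, 0]], which
    is valid even when R is singular (resonant input strength).
    """
    if not t >= 0:
        raise ValueError("t must be nonnegative")
    system = build_linear_system(s_const, params)
    M = np.zeros((5, 5))
    M[:4, :4] = system.R
    M[:4, 4] = system.I
    phi = expm(M * t)
    if not isinstance(initial, PhaseState):
        initial = PhaseState.from_array(initial)
    psi = phi[:4, :4] @ initial.as_array() + phi[:4, 4]
    return PhaseState.from_array(psi)


def closed_form_fixed_point(s_inf: float, params: ModelParams) -> tuple[float, float]:
    """Analytic (mu_eq, w_eq) of the stationary drift field.

    mu_eq = (mu_d + s w_d / gamma_mu) / D,
    w_eq  = (w_d + sign * s mu_d / gamma_w) / D,
    D = 1 - sign * s^2 / (gamma_mu gamma_w);

    with sign=+1 this is the textbook Hebbian closed form.  Raises
    :class:`DegenerateSystemError` at the resonance D = 0.
    """
    denom = 1.0 - params.hebbian_sign * s_inf ** 2 / (params.gamma_mu * params.gamma_w)
    if abs(denom) < 1e-14:
        raise DegenerateSystemError(
            f"resonant input strength s^2 = {s_inf ** 2:g}: no fixed point")
    mu_eq = (params.mu_d + s_inf * params.w_d / params.gamma_mu) / denom
    w_eq = (params.w_d + params.hebbian_sign * s_inf * params.mu_d / params.gamma_w) / denom
    return float(mu_eq), float(w_eq)


def _sorted_eigs(matrix: np.ndarray) -> np.ndarray:
    eigs = np.linalg.eigvals(matrix)
    order = np.lexsort((eigs.imag, eigs.real))
    return eigs[order]


def _classify(eigs: np.ndarray) -> str:
    """Stability label from the state-block eigenvalues."""
    scale = max(1.0, float(np.max(np.abs(eigs))))
    tol = 1e-9 * scale
    re, im = eigs.real, eigs.imag
    if np.all(re < -tol):
        return "stable-spiral" if np.any(np.abs(im) > tol) else "stable-node"
    if np.all(re > tol):
        return "unstable"
    if np.any(re < -tol) and np.any(re > tol):
        return "saddle"
    if np.all(np.abs(re) <= tol) and np.any(np.abs(im) > tol):
        return "center"
    return "degenerate"


def spectrum(s: float, params: ModelParams):
    """Eigenvalues of R (sorted by real then imaginary part) and the
    stability label of the state block.

    The spectrum is symmetric under negation and sums to zero (R is
    traceless), so "stability" refers to the zero-momentum manifold.
    """
    system = build_linear_system(s, params)
    eigs = _sorted_eigs(system.R)
    label = _classify(_sorted_eigs(drift_jacobian(s, params)))
    return eigs, label


def fixed_point(s_inf: float, params: ModelParams) -> FixedPointReport:
    """Solve the stationarity system R Psi + I = 0 and classify it.

    The momentum block is homogeneous, so whenever it is nonsingular the
    equilibrium momenta vanish and (mu_eq, w_eq) solve the stationary drift
    field.  Raises :class:`DegenerateSystemError` for resonant input
    strengths where the system is singular.
    """
    system = build_linear_system(s_inf, params)
    cond = np.linalg.cond(system.R)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise DegenerateSystemError(
            f"stationarity system is singular (cond={cond:.3g}); "
            f"resonant input strength s={s_inf!r}")
    psi_eq = np.linalg.solve(system.R, -system.I)
    eigs = _sorted_eigs(system.R)
    label = _classify(_sorted_eigs(drift_jacobian(s_inf, params)))
    p_norm = float(np.max(np.abs(psi_eq[2:])))
    return FixedPointReport(
        state=PhaseState.from_array(psi_eq),
        eigenvalues=tuple(complex(z) for z in eigs),
        stability=label,
        momentum_components_zero=p_norm <= 1e-9 * (1.0 + float(np.max(np.abs(psi_eq)))),
        trace_residual=system.trace_residual,
    )
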