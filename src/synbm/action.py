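"""Free-energy action along trajectories and numerical least-action checks.

The free energy of a path is the time integral of the Onsager-Machlup
Lagrangian, F = Int L(mu, w, mu_dot, w_dot; s) dt.  A trajectory produced
by the Hamiltonian equations makes F stationary among paths sharing its
endpoints; because L is a positive quadratic form in the rate residuals,
the stationary path is in fact the global minimum.  This module evaluates
F by quadrature, measures Euler-Lagrange residuals, and verifies
stationarity directly: endpoint-vanishing perturbations of amplitude eps
must raise the action by c * eps^2 (vanishing first variation, quadratic
second variation).

Rates are reconstructed from sampled paths by centered finite differences
(second-order one-sided at the endpoints); the quadrature is trapezoidal,
matching the differencing order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, Trajectory, lagrangian
from .signals import PresynapticSignal

__all__ = [
    "PerturbationSpec",
    "ELResidual",
    "action",
    "euler_lagrange_residual",
    "stationarity_test",
]

_SHAPES = ("half-sine", "sine-squared", "custom")


@dataclass(frozen=True)
class PerturbationSpec:
    """An endpoint-vanishing variation of one path component.

    ``shape`` is ``"half-sine"`` (default), ``"sine-squared"``, or
    ``"custom"`` with an explicit ``custom_values`` array on the
    trajectory grid.  The bump must vanish at both ends of the time
    window, as Hamilton's principle compares paths with fixed endpoints.
    """

    component: str = "mu"
    shape: str = "half-sine"
    amplitude: float = 0.01
    custom_values: np.ndarray | None = None

    def __post_init__(self):
        if self.component not in ("mu", "w"):
            raise ValueError(f"component must be 'mu' or 'w', got {self.component!r}")
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}")
        if self.shape == "custom" and self.custom_values is None:
            raise ValueError("shape='custom' requires custom_values")

    def bump(self, times: np.ndarray) -> np.ndarray:
        """Unit-amplitude bump profile on the given grid."""
        t0, t1 = times[0], times[-1]
        x = (times - t0) / (t1 - t0)
        if self.shape == "half-sine":
            values = np.sin(np.pi * x)
        elif self.shape == "sine-squared":
            values = np.sin(np.pi * x) ** 2
        else:
            values = np.asarray(self.custom_values, dtype=float)
            if values.shape != times.shape:
                raise ValueError("custom_values must match the trajectory grid")
        if abs(values[0]) > 1e-12 or abs(values[-1]) > 1e-12:
            raise ValueError("perturbation must vanish at both endpoints")
        return values


class ELResidual(NamedTuple):
    """Max-norm and per-point Euler-Lagrange residuals (interior grid)."""

    max_residual: float
    table: pd.DataFrame


def _rates(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.gradient(values, times, edge_order=2)


def _path_signal(trajectory: Trajectory, signal: PresynapticSignal | None) -> np.ndarray:
    # the stored grid samples are the realization the path actually saw
    if trajectory.signal_values is not None:
        return trajectory.signal_values
    return signal.values(trajectory.times)


def action(trajectory: Trajectory, signal: PresynapticSignal | None,
           params: ModelParams) -> float:
    """Free-energy action of a sampled path by trapezoid quadrature.

    Rates come from centered finite differences, so a drift-following path
    evaluates to zero only up to O(dt^2) differencing residue.  Requires at
    least 3 grid points.
    """
    if len(trajectory.times) < 3:
        raise ValueError("action needs at least 3 grid points")
    t = trajectory.times
    s = _path_signal(trajectory, signal)
    mu_dot = _rates(t, trajectory.mu)
    w_dot = _rates(t, trajectory.w)
    L = lagrangian(mu_dot, w_dot, trajectory.mu, trajectory.w, s, params)
    return float(np.trapezoid(L, t))


def euler_lagrange_residual(trajectory: Trajectory,
                            signal: PresynapticSignal | None,
                            params: ModelParams) -> ELResidual:
    """Pointwise Euler-Lagrange residual d/dt(dL/dq_dot) - dL/dq.

    In terms of the finite-differenced momenta p = m (q_dot - drift), the
    residual for each component is dp/dt + (J^T p), with J the drift
    Jacobian.  Evaluated on the interior of the grid, excluding the two
    points nearest each endpoint where the one-sided rate stencils leak a
    first-order error; on the remaining interior a true least-action path
    drives the residual to zero at the differencing order O(dt^2).
    """
    t = trajectory.times
    if len(t) < 5:
        raise ValueError("residual evaluation needs at least 5 grid points")
    s = _path_signal(trajectory, signal)
    mu, w = trajectory.mu, trajectory.w
    mu_dot, w_dot = _rates(t, mu), _rates(t, w)
    gw = np.array([params.effective_gamma_w(si) for si in s])
    f = -params.gamma_mu * (mu - params.mu_d) + w * s
    h = -gw * (w - params.w_d) + params.hebbian_sign * s * mu
    p_mu = params.m_mu * (mu_dot - f)
    p_w = params.m_w * (w_dot - h)
    dp_mu, dp_w = _rates(t, p_mu), _rates(t, p_w)
    # J^T p, with J = [[df/dmu, df/dw], [dh/dmu, dh/dw]]
    res_mu = dp_mu + (-params.gamma_mu) * p_mu + params.hebbian_sign * s * p_w
    res_w = dp_w + s * p_mu + (-gw) * p_w
    interior = slice(2, -2)
    table = pd.DataFrame({"t": t[interior], "residual_mu": res_mu[interior],
                          "residual_w": res_w[interior]})
    max_res = float(max(np.max(np.abs(res_mu[interior])),
                        np.max(np.abs(res_w[interior]))))
    return ELResidual(max_residual=max_res, table=table)


def stationarity_test(base: Trajectory, perturbation: PerturbationSpec,
                      amplitudes: Sequence[float],
                      signal: PresynapticSignal | None,
                      params: ModelParams) -> pd.DataFrame:
    """Action change under endpoint-vanishing perturbations of a solution.

    For each amplitude eps the chosen component of the base path gains
    eps * bump(t) and the action difference DeltaF = F(perturbed) - F(base)
    is recorded.  On a true least-action path DeltaF(eps) >= 0 and scales
    as eps^2 (DeltaF(2 eps) / DeltaF(eps) -> 4): the first variation
    vanishes and the convex quadratic action has its global minimum there.

    Returns a DataFrame with columns ``epsilon`` and ``delta_F``.
    """
    bump = perturbation.bump(base.times)
    column = 0 if perturbation.component == "mu" else 1
    base_action = action(base, signal, params)
    rows = []
    for eps in amplitudes:
        psi = base.psi.copy()
        psi[:, column] = psi[:, column] + eps * bump
        perturbed = replace(base, psi=psi, lagrangian_values=None,
                            hamiltonian_values=None, cumulative_action=None)
        rows.append((float(eps), action(perturbed, signal, params) - base_action))
    return pd.DataFrame(rows, columns=["epsilon", "delta_F"])
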