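"""Self-check suite: the structural invariants of the mechanics.

Each check exercises an exact property of the model -- tracelessness and
spectral symmetry of R, conservation of the Hamiltonian under static
input, invariance of the zero-momentum manifold, agreement between the
integrator and the closed-form propagator, the analytic fixed points, and
the quadratic scaling of the action under perturbations.  ``run_all``
returns a list of named results; the CLI ``validate`` command prints them
and fails if any check fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dynamics
from .action import PerturbationSpec, stationarity_test
from .model import ModelParams, PhaseState, preset
from .signals import PresynapticSignal

__all__ = ["CheckResult", "run_all"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str


def _random_params(rng: np.random.Generator) -> ModelParams:
    return ModelParams(
        gamma_mu=float(rng.uniform(0.05, 5.0)),
        gamma_w=float(rng.uniform(0.05, 5.0)),
        m_mu=float(rng.uniform(0.1, 10.0)),
        m_w=float(rng.uniform(0.1, 10.0)),
        mu_d=float(rng.uniform(-10, 10)),
        w_d=float(rng.uniform(-10, 10)),
        hebbian_sign=int(rng.choice([-1, 1])),
    )


def run_all(seed: int = 0) -> list[CheckResult]:
    rng = np.random.default_rng(seed)
    results: list[CheckResult] = []

    def record(name: str, passed: bool, detail: str) -> None:
        results.append(CheckResult(name=name, passed=bool(passed), detail=detail))

    # tracelessness, eigenvalue sum, spectral negation symmetry
    worst_trace = worst_sum = worst_sym = 0.0
    for _ in range(50):
        params = _random_params(rng)
        s = float(rng.uniform(-10, 10))
        system = dynamics.build_linear_system(s, params)
        eigs, _ = dynamics.spectrum(s, params)
        worst_trace = max(worst_trace, abs(system.trace_residual))
        worst_sum = max(worst_sum, abs(np.sum(eigs)))
        for z in eigs:
            worst_sym = max(worst_sym, float(np.min(np.abs(eigs + z))))
    record("trace(R) = 0", worst_trace <= 1e-12, f"max |Tr R| = {worst_trace:.3g}")
    record("eigenvalue sum = 0", worst_sum <= 1e-9, f"max |sum| = {worst_sum:.3g}")
    record("spectrum symmetric under negation", worst_sym <= 1e-9,
           f"max defect = {worst_sym:.3g}")

    # rhs == R Psi + I
    worst = 0.0
    for _ in range(200):
        params = _random_params(rng)
        s = float(rng.uniform(-10, 10))
        psi = rng.uniform(-10, 10, size=4)
        system = dynamics.build_linear_system(s, params)
        rhs = dynamics.bm_rhs(0.0, psi, PresynapticSignal.static(s), params)
        worst = max(worst, float(np.max(np.abs(rhs - (system.R @ psi + system.I)))))
    record("Hamilton rhs == R Psi + I", worst <= 1e-12, f"max |diff| = {worst:.3g}")

    solid = preset("table1_solid")
    static5 = PresynapticSignal.static(5.0)

    # integrator vs matrix-exponential propagator
    initial = PhaseState(mu=0.0, w=0.0, p_mu=0.1, p_w=-0.05)
    traj = dynamics.integrate(initial, static5, solid, t_end=5.0, dt=0.002)
    worst = 0.0
    for i in range(0, len(traj.times), 250):
        exact = dynamics.propagate_static(initial, 5.0, solid, traj.times[i])
        worst = max(worst, float(np.max(np.abs(traj.psi[i] - exact.as_array()))))
    record("RK4 == matrix-exponential propagator", worst <= 1e-6,
           f"max |diff| = {worst:.3g}")

    # Hamiltonian conservation under static input
    drift_h = np.max(np.abs(traj.hamiltonian_values - traj.hamiltonian_values[0]))
    record("Hamiltonian conserved (static s)", drift_h <= 1e-6,
           f"max |H(t)-H(0)| = {drift_h:.3g}")

    # zero-momentum manifold invariance
    traj0 = dynamics.integrate(PhaseState(0.0, 0.0), static5, solid,
                               t_end=10.0, dt=0.01)
    p_max = float(np.max(np.abs(traj0.psi[:, 2:])))
    record("zero-momentum manifold invariant", p_max <= 1e-10,
           f"max |p| = {p_max:.3g}")

    # closed-form fixed point vs linear solve (Hebbian sign)
    worst = 0.0
    for _ in range(50):
        params = _random_params(rng).replace(hebbian_sign=1)
        s = float(rng.uniform(-2, 2))
        try:
            mu_eq, w_eq = dynamics.closed_form_fixed_point(s, params)
            report = dynamics.fixed_point(s, params)
        except dynamics.DegenerateSystemError:
            continue
        worst = max(worst, abs(report.state.mu - mu_eq), abs(report.state.w - w_eq))
    record("closed form == linear solve", worst <= 1e-10, f"max |diff| = {worst:.3g}")

    # published fixed points (anti-Hebbian reproduction convention)
    fp_solid = dynamics.fixed_point(5.0, solid)
    fp_dotted = dynamics.fixed_point(5.0, preset("table1_dotted"))
    got = tuple(round(float(x), 1) for x in
                (fp_solid.state.w, fp_solid.state.mu,
                 fp_dotted.state.w, fp_dotted.state.mu))
    record("static-input fixed points", got == (-1.0, 0.1, -2.0, 0.0),
           f"(w,mu) solid/dotted rounded = {got}")

    # quadratic stationarity of the action
    base = dynamics.integrate(PhaseState(0.0, 0.0), static5, solid,
                              t_end=10.0, dt=0.005)
    table = stationarity_test(
        base, PerturbationSpec(component="mu"),
        amplitudes=[0.01, 0.02, 0.04], signal=static5, params=solid)
    dF = table["delta_F"].to_numpy()
    ratios = dF[1:] / dF[:-1]
    ok = bool(np.all(dF >= -1e-9) and np.all(np.abs(ratios - 4.0) <= 0.4))
    record("action stationarity (quadratic scaling)", ok,
           f"DeltaF = {dF.tolist()}, ratios = {ratios.tolist()}")

    return results
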