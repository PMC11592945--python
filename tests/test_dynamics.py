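"""Hamilton's equations, the affine form, integrators, fixed points, spectra."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import synbm
from synbm import (
    DegenerateSystemError,
    DivergenceError,
    PhaseState,
    PresynapticSignal,
    bm_rhs,
    build_linear_system,
    closed_form_fixed_point,
    fixed_point,
    integrate,
    propagate_static,
    spectrum,
)
from conftest import random_params


class TestRightHandSide:
    def test_equilibrium_without_input_is_stationary(self, solid):
        state = PhaseState(solid.mu_d, solid.w_d, 0.0, 0.0)
        rhs = bm_rhs(0.0, state, PresynapticSignal.static(0.0), solid)
        assert np.allclose(rhs, 0.0, atol=1e-14)

    def test_origin_under_hebbian_drive(self, solid, static5):
        hebbian = solid.replace(hebbian_sign=1)
        rhs = bm_rhs(0.0, PhaseState(0.0, 0.0), static5, hebbian)
        # mu_dot = gamma_mu*mu_d = 5; w_dot = gamma_w*w_d = 0.5; momenta rest
        assert np.allclose(rhs, [5.0, 0.5, 0.0, 0.0])

    def test_matches_affine_form_for_random_states(self, rng):
        """bm_rhs must coincide with R Psi + I everywhere."""
        for _ in range(250):
            params = random_params(rng)
            if rng.uniform() < 0.2:
                params = params.replace(nonlinear_weight_damping=True)
            s = float(rng.uniform(-10, 10))
            psi = rng.uniform(-10, 10, size=4)
            system = build_linear_system(s, params)
            rhs = bm_rhs(0.0, psi, PresynapticSignal.static(s), params)
            assert np.max(np.abs(rhs - (system.R @ psi + system.I))) < 1e-12


class TestLinearSystem:
    def test_published_first_row(self, solid):
        hebbian = solid.replace(hebbian_sign=1)
        system = build_linear_system(5.0, hebbian)
        assert np.allclose(system.R[0], [-1.0, 5.0, 0.2, 0.0])
        assert np.allclose(system.I, [5.0, 0.5, 0.0, 0.0])

    def test_anti_hebbian_flips_coupling_entries(self, solid):
        system = build_linear_system(5.0, solid)
        assert system.R[1, 0] == -5.0
        assert system.R[2, 3] == 5.0
        assert system.R[0, 1] == 5.0  # w*s drive in f is sign-independent
        assert system.R[3, 2] == -5.0

    def test_no_input_decouples_the_blocks(self, solid):
        system = build_linear_system(0.0, solid)
        off = system.R - np.diag(np.diag(system.R)) - np.diag(np.diag(system.R, 2), 2)
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(system.R),
                           [-solid.gamma_mu, -solid.gamma_w,
                            solid.gamma_mu, solid.gamma_w])

    def test_trace_vanishes_for_random_parameters(self, rng):
        for _ in range(100):
            params = random_params(rng)
            s = float(rng.uniform(-20, 20))
            assert abs(build_linear_system(s, params).trace_residual) < 1e-12

    def test_momentum_rows_have_no_state_feedback(self, rng):
        for _ in range(20):
            system = build_linear_system(float(rng.uniform(-5, 5)), random_params(rng))
            assert np.allclose(system.R[2:, :2], 0.0)


class TestSpectrum:
    def test_eigenvalue_sum_and_negation_symmetry(self, rng):
        for _ in range(100):
            params = random_params(rng)
            s = float(rng.uniform(-10, 10))
            eigs, _ = spectrum(s, params)
            assert abs(np.sum(eigs)) < 1e-9
            for z in eigs:
                assert np.min(np.abs(eigs + z)) < 1e-9

    def test_solid_anti_hebbian_is_a_stable_spiral(self, solid):
        eigs, label = spectrum(5.0, solid)
        assert label == "stable-spiral"
        # state block solves lambda^2 + 1.1 lambda + 25.1 = 0
        expected = complex(-0.55, np.sqrt(99.19) / 2)
        assert np.min(np.abs(eigs - expected)) < 1e-9
        assert np.min(np.abs(eigs - expected.conjugate())) < 1e-9

    def test_solid_hebbian_is_a_saddle(self, solid):
        hebbian = solid.replace(hebbian_sign=1)
        _, label = spectrum(5.0, hebbian)
        assert label == "saddle"
        # roots of lambda^2 + 1.1 lambda - 24.9 are real with opposite signs
        roots = np.roots([1.0, 1.1, -24.9])
        assert roots[0] * roots[1] < 0


class TestFixedPoint:
    def test_published_static_input_equilibria(self, solid, dotted):
        fp_solid = fixed_point(5.0, solid)
        fp_dotted = fixed_point(5.0, dotted)
        assert (round(fp_solid.state.w, 1), round(fp_solid.state.mu, 1)) == (-1.0, 0.1)
        assert (round(fp_dotted.state.w, 1), round(fp_dotted.state.mu, 1)) == (-2.0, 0.0)
        assert fp_solid.state.mu == pytest.approx(30 / 251, rel=1e-12)
        assert fp_solid.state.w == pytest.approx(-245 / 251, rel=1e-12)

    def test_momenta_vanish_at_equilibrium(self, solid):
        report = fixed_point(5.0, solid)
        assert report.momentum_components_zero
        assert report.state.p_mu == pytest.approx(0.0, abs=1e-12)
        assert report.state.p_w == pytest.approx(0.0, abs=1e-12)

    def test_zero_set_points_put_equilibrium_exactly_at_origin(self, solid):
        report = fixed_point(5.0, solid.replace(mu_d=0.0, w_d=0.0))
        assert tuple(report.state) == (0.0, 0.0, 0.0, 0.0)

    def test_closed_form_agrees_with_linear_solve(self, rng):
        for _ in range(100):
            params = random_params(rng, sign=1)
            s = float(rng.uniform(-2, 2))
            try:
                mu_eq, w_eq = closed_form_fixed_point(s, params)
                report = fixed_point(s, params)
            except DegenerateSystemError:
                continue
            scale = 1.0 + abs(mu_eq) + abs(w_eq)
            assert abs(report.state.mu - mu_eq) < 1e-10 * scale
            assert abs(report.state.w - w_eq) < 1e-10 * scale

    def test_resonant_input_raises(self, solid):
        hebbian = solid.replace(hebbian_sign=1)
        s_res = np.sqrt(hebbian.gamma_mu * hebbian.gamma_w)
        with pytest.raises(DegenerateSystemError):
            fixed_point(s_res, hebbian)
        with pytest.raises(DegenerateSystemError):
            closed_form_fixed_point(s_res, hebbian)

    def test_report_serializes_to_plain_json_types(self, solid):
        import json
        payload = fixed_point(5.0, solid).to_dict()
        text = json.dumps(payload)
        assert "stable-spiral" in text
        assert payload["trace_residual"] == pytest.approx(0.0, abs=1e-12)


class TestIntegration:
    def test_equilibrium_stays_put(self, solid):
        initial = PhaseState(solid.mu_d, solid.w_d, 0.0, 0.0)
        traj = integrate(initial, PresynapticSignal.static(0.0), solid,
                         t_end=5.0, dt=0.01)
        assert np.max(np.abs(traj.psi - initial.as_array())) < 1e-12

    def test_relaxation_to_the_published_fixed_point(self, solid, static5):
        traj = integrate(PhaseState(0.0, 0.0), static5, solid, t_end=50.0, dt=0.01)
        assert traj.final_state.w == pytest.approx(-245 / 251, abs=1e-3)
        assert traj.final_state.mu == pytest.approx(30 / 251, abs=1e-3)

    def test_matches_matrix_exponential_propagator(self, solid, static5):
        initial = PhaseState(0.0, 0.0, 0.1, -0.05)
        traj = integrate(initial, static5, solid, t_end=20.0, dt=0.002)
        for t_check in (1.0, 5.0, 20.0):
            i = int(round(t_check / 0.002))
            exact = propagate_static(initial, 5.0, solid, t_check)
            # momenta grow ~ e^{0.55 t}, so compare relative to the state scale
            scale = 1.0 + np.max(np.abs(exact.as_array()))
            assert np.max(np.abs(traj.psi[i] - exact.as_array())) < 1e-6 * scale

    def test_adaptive_method_agrees_with_rk4(self, solid, static5):
        initial = PhaseState(0.0, 0.0, 0.1, 0.0)
        rk4 = integrate(initial, static5, solid, t_end=5.0, dt=0.01)
        ada = integrate(initial, static5, solid, t_end=5.0, dt=0.01,
                        method="adaptive")
        assert np.max(np.abs(rk4.psi - ada.psi)) < 1e-5

    def test_hamiltonian_conserved_under_static_input(self, solid, static5):
        traj = integrate(PhaseState(1.0, -1.0, 0.2, 0.1), static5, solid,
                         t_end=5.0, dt=1e-3)
        drift = np.max(np.abs(traj.hamiltonian_values - traj.hamiltonian_values[0]))
        assert drift <= 1e-6

    def test_zero_momentum_manifold_is_invariant(self, solid, static5):
        traj = integrate(PhaseState(3.0, -2.0), static5, solid, t_end=20.0, dt=0.01)
        assert np.max(np.abs(traj.psi[:, 2:])) == 0.0

    def test_zero_momentum_flow_reduces_to_the_drift_ode(self, solid, static5):
        traj = integrate(PhaseState(0.0, 0.0), static5, solid, t_end=10.0, dt=0.002)
        sol = solve_ivp(
            lambda t, y: [synbm.drift_mu(y[0], y[1], 5.0, solid),
                          synbm.drift_w(y[1], y[0], 5.0, solid)],
            (0, 10), [0.0, 0.0], t_eval=traj.times, rtol=1e-11, atol=1e-12)
        assert np.max(np.abs(traj.mu - sol.y[0])) < 1e-8
        assert np.max(np.abs(traj.w - sol.y[1])) < 1e-8

    def test_saddle_with_excited_momenta_diverges(self, solid, static5):
        hebbian = solid.replace(hebbian_sign=1)
        with pytest.raises(DivergenceError) as err:
            integrate(PhaseState(0.0, 0.0, 1.0, 1.0), static5, hebbian,
                      t_end=400.0, dt=0.05)
        assert err.value.time is not None and err.value.time > 0

    def test_invalid_grid_rejected(self, solid, static5):
        with pytest.raises(ValueError):
            integrate(PhaseState(0.0, 0.0), static5, solid, t_end=1.0, dt=2.0)
        with pytest.raises(ValueError):
            integrate(PhaseState(0.0, 0.0), static5, solid, t_end=1.0, dt=0.1,
                      method="euler")


class TestStaticPropagator:
    def test_zero_time_is_the_identity(self, solid):
        initial = PhaseState(1.0, 2.0, 3.0, 4.0)
        out = propagate_static(initial, 5.0, solid, 0.0)
        assert np.allclose(out.as_array(), initial.as_array(), atol=1e-14)

    def test_long_time_limit_reaches_the_fixed_point(self, solid):
        report = fixed_point(5.0, solid)
        out = propagate_static(PhaseState(0.0, 0.0), 5.0, solid, 100.0)
        assert np.max(np.abs(out.as_array() - report.state.as_array())) < 1e-9

    def test_valid_at_resonant_input(self, solid):
        # the augmented-exponential form needs no inverse of R
        hebbian = solid.replace(hebbian_sign=1)
        s_res = np.sqrt(hebbian.gamma_mu * hebbian.gamma_w)
        out = propagate_static(PhaseState(0.0, 0.0), s_res, hebbian, 1.0)
        assert np.all(np.isfinite(out.as_array()))
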