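# synbm — Bayesian mechanics of synaptic learning

`synbm` simulates a single synapse that learns by free-energy minimization.
It is aimed at computational neuroscientists and free-energy-principle
researchers who want a small, fully testable dynamical model in which
synaptic *inference* (postsynaptic activity) and *learning* (synaptic
weight) co-evolve in continuous time, driven by a presynaptic input.

## The model

A presynaptic signal *s*(*t*) drives the postsynaptic activity μ through a
plastic weight *w*. The generative model treats both as overdamped Langevin
processes,

```
dμ/dt = f(μ, w; s) + ξ,     f = −γ_μ (μ − μ_d) + w s
dw/dt = h(w, μ; s) + χ,     h = −γ_w (w − w_d) ± s μ
```

with Gaussian white noises of strengths σ²_μ, σ²_w (precisions
m = 1/σ² act as masses). The ± selects Hebbian (+) or anti-Hebbian (−)
plasticity. The negative log probability of a path is the integral of the
Onsager–Machlup Lagrangian

```
L = (m_μ/2)(μ̇ − f)² + (m_w/2)(ẇ − h)²,
```

so free-energy minimization over paths is Hamilton's principle δ∫L dt = 0.
The resulting Hamiltonian mechanics for Ψ = (μ, w, p_μ, p_w) — the momenta
are precision-weighted prediction errors — is affine, Ψ̇ = R(t)Ψ + I, with a
traceless 4×4 matrix R. The package provides:

- the model quantities (drifts, Lagrangian, Hamiltonian, momenta, the
  fluctuation–dissipation mapping σ² = 2k_BT/γ) — `synbm.model`
- Hamilton's equations, RK4/adaptive integration, the matrix-exponential
  propagator for static input, fixed points and spectral stability —
  `synbm.dynamics`
- Euler–Maruyama sampling of the Langevin pair and discrete
  Onsager–Machlup path actions — `synbm.langevin`
- action evaluation, Euler–Lagrange residuals and direct numerical
  verification of the least-action property — `synbm.action`
- presynaptic input generators (static, sinusoid, decaying sinusoid,
  sampled tables) with seeded noise — `synbm.signals`

Two presets, `table1_solid` and `table1_dotted`, carry the published
parameter rows (m_μ=5, m_w=0.5, γ_μ=1, γ_w=0.1 with set-points (5, 5) and
(10, 0)). They use the anti-Hebbian sign, under which the reported
equilibria and damped oscillations are reproduced; see
[docs/methods.md](docs/methods.md) for the sign-convention analysis.

## Worked example

```python
from synbm import PhaseState, PresynapticSignal, fixed_point, integrate, preset

params = preset("table1_solid")           # anti-Hebbian reproduction preset
signal = PresynapticSignal.static(5.0)

report = fixed_point(5.0, params)
print(round(report.state.w, 4), round(report.state.mu, 4), report.stability)
# -0.9761 0.1195 stable-spiral

traj = integrate(PhaseState(mu=0.0, w=0.0), signal, params, t_end=50.0, dt=0.01)
print(round(traj.final_state.w, 4), round(traj.final_state.mu, 4))
# -0.9761 0.1195
```

The linear solve of RΨ + I = 0 puts the equilibrium at
(w, μ) = (−245/251, 30/251) ≈ (−1.0, 0.1); integrating Hamilton's equations
from rest spirals into the same point with decay rate 0.55 and angular
frequency ≈ 4.98 (the state-block eigenvalues −0.55 ± 4.98i). The
`examples/` directory contains short narrative scripts for each
capability — equilibria and stability, static-input relaxation, Langevin
sampling and path actions, the least-action check, and nonstationary
inputs.

A thin CLI wraps the library for shell use:

```sh
synbm simulate --preset table1_solid --t-end 50 --dt 0.01 --out run/
synbm fixed-point --preset table1_dotted      # w component rounds to -2.0
synbm reproduce fig4 --out repro/             # spiral to the origin
synbm validate                                # invariant self-check suite
```

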