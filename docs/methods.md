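# Methods

## Model and assumptions

The package implements the mechanics of a single synapse whose postsynaptic
activity μ and synaptic weight w are both dynamical variables, conditioned
on a prescribed presynaptic input s(t). The generative model is a pair of
coupled overdamped Langevin equations with linear drifts

    f(μ, w; s) = −γ_μ (μ − μ_d) + w s
    h(w, μ; s) = −γ_w (w − w_d) + σ s μ,        σ ∈ {+1, −1}

and independent Gaussian white noises. All quantities are dimensionless.
The assumptions baked into this model: Markovian state transitions, white
(delta-correlated) noise — colored noise is deliberately out of scope —
local thermal equilibrium so the fluctuation–dissipation relation
σ² = 2k_BT/γ can map friction and temperature to noise strength, and an
input s that is an external signal, not a dynamical variable.

Under white noise the log path probability is (minus) the time integral of
the Onsager–Machlup Lagrangian, a precision-weighted sum of squared rate
residuals. Identifying that integral with a classical action and applying
Hamilton's principle yields a 4-dimensional Hamiltonian system for
Ψ = (μ, w, p_μ, p_w). The momenta are the precisions times the rate
residuals — precision-weighted prediction errors in predictive-coding
language. Because the drifts are linear, the system is affine,
Ψ̇ = R(t)Ψ + I, and three exact structural facts follow:

- **Tr R = 0** and the spectrum is symmetric under λ ↔ −λ (the momentum
  block is minus the transpose of the state block). The full 4-D flow
  therefore always has expanding momentum directions; "stability" in all
  reports refers to the state block, i.e. to the dynamics on the
  zero-momentum manifold.
- **The zero-momentum manifold p_μ = p_w = 0 is invariant** (the momentum
  equations are homogeneous in p), and on it the mechanics reduces exactly
  to the drift ODE μ̇ = f, ẇ = h. The Lagrangian vanishes identically
  there: drift-following paths cost no action.
- **H is conserved for static s** (no explicit time dependence); for
  time-varying input it is not, and the package makes no conservation
  claim.

## Sign convention of the weight coupling

The printed form of the weight drift uses the Hebbian sign (+sμ), and the
printed closed-form equilibrium has denominator 1 − s²/(γ_μ γ_w). With the
published parameters (γ_μγ_w = 0.1) and s = 5 those two together give
(w, μ) ≈ (−1.02, −0.12) for the Solid row and a *saddle* state block — no
oscillation is possible. The reported equilibria (−1.0, 0.1) and
(−2.0, 0.0), and the reported damped-oscillatory ("transient harmonic",
spiral) behavior, are all reproduced exactly under the anti-Hebbian sign
(−sμ), which makes the state block a stable spiral with eigenvalues
−0.55 ± 4.98i. The text itself cannot disambiguate which sign the figures
used, so the package exposes both: `hebbian_sign` defaults to +1 in the
generic `ModelParams`, while the reproduction presets `table1_solid` and
`table1_dotted` fix −1. The sign is explicit in configs, logs and reports;
nothing is silently patched.

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| γ_μ | activity relaxation rate (1/time) | 1.0 | |
| γ_w | weight relaxation rate (1/time) | 0.1 | γ_μ/10: weights are slow |
| m_μ | activity precision (= 1/σ²_μ) | 5.0 | "mass" of μ |
| m_w | weight precision (= 1/σ²_w) | 0.5 | "mass" of w |
| μ_d, w_d | set-points without drive | 5, 5 | presets: (5,5) and (10,0) |
| hebbian_sign | ± of the sμ coupling | +1 (API), −1 (presets) | see above |
| k_BT | thermal energy | 1.0 | used only by the FDT chain |

No numeric temperature or noise strength is published; the precisions are
taken as primitive and `fdt_noise_strength`/`mass_from_noise` are provided
so users who think in (γ, T) terms can derive masses as m = γ/(2k_BT).
The optional input-gated weight damping −γ_w s²(w − w_d)
(`nonlinear_weight_damping`) is off by default.

## Input signals and their noise

Static s = 5, sinusoid 5 cos t, and transient 5 e^(−t/5) cos t match the
documented experiments; amplitude, frequency and decay time are
configurable, and sampled two-column text tables are interpolated linearly.
The fluctuation η added to the oscillatory inputs has no published
distribution or amplitude; it is modeled as Gaussian with a default
standard deviation of 0.25 (a visible but small perturbation at amplitude
5) in the figure-reproduction commands, and 0 wherever determinism matters.
Each evaluation time draws its noise from a counter-style generator keyed
on (seed, bit pattern of t): identical seeds give bit-identical values on
identical grids with no hidden state. Reproduction of the noisy figures is
therefore qualitative by construction; every deterministic quantity is
exact.

## Numerical choices

- **Integrator**: classical fixed-step RK4, default dt = 0.01 and
  t_end = 50 for static runs (the slowest decay rate is 0.55, so 50 time
  units is ≈ e^(−27) of the initial transient). An adaptive option wraps
  scipy's RK45 at rtol 1e−8 / atol 1e−10 and resamples onto the uniform
  grid. Divergence (expected for saddle configurations with excited
  momenta) raises an error naming the blow-up time.
- **Static propagator**: the exact solution for constant s is evaluated via
  the exponential of the augmented matrix [[R, I], [0, 0]], which avoids
  inverting R and remains valid at the resonant input strengths
  s² = ±γ_μγ_w where R is singular. The fixed-point solver, by contrast,
  must raise there: the equilibrium genuinely does not exist.
- **Fixed points**: solved by direct linear algebra on RΨ = −I
  (condition-number guard at 1e12); the Hebbian closed form is kept as an
  independent cross-check. Eigenvalues are sorted lexicographically by
  (real, imaginary) for deterministic output.
- **Stochastic scheme**: Euler–Maruyama with Ito (left-endpoint) drifts, one
  independent seeded stream per variable. The Jacobian (measure) correction
  sometimes added to Onsager–Machlup actions is deliberately omitted; the
  discrete action is exactly the negative log of the Gaussian
  transition-probability product, up to its grid-dependent normalization,
  so only action differences on a common grid are meaningful. The discrete
  action converges to the continuum quadrature at first order in dt.
- **Discrete calculus for action evaluation**: centered differences on the
  interior, second-order one-sided at the endpoints; trapezoid quadrature
  (matching the differencing order). The one-sided stencils leak a
  first-order error into the two grid points nearest each endpoint, so the
  Euler–Lagrange residual is reported on the interior excluding those
  points, where it converges as O(dt²).
- **Stationarity testing**: Hamilton's principle is a fixed-endpoint
  statement, so integrated (initial-value) solutions are perturbed only by
  bumps vanishing at both ends of the realized window. The action is a
  convex quadratic functional of the path, so stationarity strengthens to
  global minimality; the test checks ΔF ≥ 0 and the quadratic scaling
  ΔF(2ε)/ΔF(ε) ≈ 4. (Strictly, the variational principle asserts
  stationarity; the minimum claim rests on this convexity argument.)

## What the checks do and do not show

All quantitative targets are desk-scale linear-algebra facts and are
reproduced exactly; the property checks (conservation, invariance, oracle
equivalences between integrator and matrix exponential, least action,
stochastic limits) verify the implementation against independent routes to
the same quantity, at the problem sizes noted in the tests (ensembles of
2000 paths, horizons ≤ 50, grids down to dt = 10⁻³). They validate the
mechanics of this idealized model — linear drifts, white noise, a single
synapse. They say nothing about real neural data: no spike trains, no
colored noise, no nonstationary noise spectra, and weights here fluctuate
on the same footing as activity rather than consolidating slowly.

## Known limitations

- The time-ordered exponential for time-dependent R(t) is not implemented
  (R at different times do not commute); nonstationary inputs are handled
  by numerical integration only.
- No bifurcation continuation, no stochastic (noise-induced) stability
  analysis, no Fokker–Planck solver.
- Momentum-excited dynamics are exponentially unstable by construction
  (λ ↔ −λ); long-horizon integrations away from the zero-momentum manifold
  lose accuracy accordingly, and comparisons there are made relative to the
  state scale.
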