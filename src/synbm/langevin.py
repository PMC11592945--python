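"""Stochastic generative processes and discrete Onsager-Machlup actions.

The generative model states that activity and weight follow overdamped
Langevin equations

    dmu/dt = f(mu, w; s) + xi,    dw/dt = h(w, mu; s) + chi,

with independent Gaussian white noises of strengths sigma_mu^2, sigma_w^2.
Simulation uses the Euler-Maruyama scheme in the Ito convention (drift at
the left endpoint), so the zero-noise limit is exactly forward Euler.

The negative log probability of a sampled path, up to the dt-dependent
normalization, is the discrete Onsager-Machlup action

    A = sum_n dt [ (Dmu_n/dt - f_n)^2 / (2 sigma_mu^2)
                 + (Dw_n/dt  - h_n)^2 / (2 sigma_w^2) ],

whose continuum limit is the free-energy action integral.  Normalization
constants are suppressed throughout, so only action *differences* between
paths on the same grid are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DivergenceError
from .model import ModelParams, NoiseStrengths
from .signals import PresynapticSignal

__all__ = [
    "SamplePath",
    "simulate_langevin",
    "simulate_langevin_ensemble",
    "om_action_discrete",
    "om_action_sequence",
]


@dataclass(frozen=True)
class SamplePath:
    """A sampled (mu, w) path on a uniform time grid, with its noise model
    and the seed that produced it."""

    times: np.ndarray
    mu_values: np.ndarray
    w_values: np.ndarray
    seed: int
    noise: NoiseStrengths

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        mu = np.asarray(self.mu_values, dtype=float)
        w = np.asarray(self.w_values, dtype=float)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("a sample path needs at least 2 time points")
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=0):
            raise ValueError("times must be a uniform increasing grid")
        if mu.shape != times.shape or w.shape != times.shape:
            raise ValueError("mu_values and w_values must match times in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mu_values", mu)
        object.__setattr__(self, "w_values", w)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path) -> None:
        """Write (t, mu, w) as CSV; the seed is recorded in a leading
        comment line."""
        frame = pd.DataFrame({"t": self.times, "mu": self.mu_values,
                              "w": self.w_values})
        with open(path, "w") as handle:
            handle.write(f"# seed={self.seed}\n")
            frame.to_csv(handle, index=False, float_format="%.17g")


def _drifts(mu, w, s, params: ModelParams):
    gw = params.effective_gamma_w(s)
    f = -params.gamma_mu * (mu - params.mu_d) + w * s
    h = -gw * (w - params.w_d) + params.hebbian_sign * s * mu
    return f, h


def simulate_langevin(initial_mu: float, initial_w: float,
                      signal: PresynapticSignal, params: ModelParams,
                      noise: NoiseStrengths, t_end: float, dt: float,
                      seed: int = 0) -> SamplePath:
    """Euler-Maruyama simulation of the coupled Langevin pair.

    Each step is Dx_n = drift(x_n; s_n) dt + DW_n with DW_n ~
    Normal(0, sigma^2 dt), the drift evaluated at the left endpoint (Ito).
    The two noise streams are independent children of ``seed``, so mu- and
    w-noise are uncorrelated and the whole path is reproducible bit for
    bit.  Zero noise strengths give the forward-Euler deterministic path.
    """
    if not (t_end > 0 and dt > 0 and dt <= t_end):
        raise ValueError("need 0 < dt <= t_end")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    child_mu, child_w = np.random.SeedSequence(seed).spawn(2)
    rng_mu = np.random.default_rng(child_mu)
    rng_w = np.random.default_rng(child_w)
    dW_mu = (np.sqrt(noise.sigma2_mu * dt) * rng_mu.standard_normal(n)
             if noise.sigma2_mu > 0 else np.zeros(n))
    dW_w = (np.sqrt(noise.sigma2_w * dt) * rng_w.standard_normal(n)
            if noise.sigma2_w > 0 else np.zeros(n))

    mu = np.empty(n + 1)
    w = np.empty(n + 1)
    mu[0], w[0] = float(initial_mu), float(initial_w)
    for i in range(n):
        s = signal.evaluate(times[i])
        f, h = _drifts(mu[i], w[i], s, params)
        mu[i + 1] = mu[i] + f * dt + dW_mu[i]
        w[i + 1] = w[i] + h * dt + dW_w[i]
        if not (np.isfinite(mu[i + 1]) and np.isfinite(w[i + 1])):
            raise DivergenceError(
                f"sample path diverged at step {i + 1} (t={times[i + 1]:.6g})",
                time=float(times[i + 1]), step=i + 1)
    return SamplePath(times=times, mu_values=mu, w_values=w, seed=seed,
                      noise=noise)


def simulate_langevin_ensemble(n_paths: int, initial_mu: float, initial_w: float,
                               signal: PresynapticSignal, params: ModelParams,
                               noise: NoiseStrengths, t_end: float, dt: float,
                               seed: int = 0):
    """Simulate many independent paths at once (vectorized across paths).

    Returns ``(times, mu, w)`` where ``mu`` and ``w`` have shape
    (n_paths, n_times).  Useful for ensemble statistics such as the
    weak-noise law of large numbers.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be positive")
    n = int(round(t_end / dt))
    times = np.arange(n + 1) * dt
    rng = np.random.default_rng(seed)
    mu = np.empty((n_paths, n + 1))
    w = np.empty((n_paths, n + 1))
    mu[:, 0], w[:, 0] = float(initial_mu), float(initial_w)
    sd_mu = np.sqrt(noise.sigma2_mu * dt)
    sd_w = np.sqrt(noise.sigma2_w * dt)
    for i in range(n):
        s = signal.evaluate(times[i])
        f, h = _drifts(mu[:, i], w[:, i], s, params)
        mu[:, i + 1] = mu[:, i] + f * dt + sd_mu * rng.standard_normal(n_paths)
        w[:, i + 1] = w[:, i] + h * dt + sd_w * rng.standard_normal(n_paths)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(w))):
        raise DivergenceError("ensemble simulation produced non-finite values")
    return times, mu, w


def om_action_discrete(path: SamplePath, signal: PresynapticSignal,
                       params: ModelParams) -> float:
    """Discrete Onsager-Machlup action of a sampled path.

    Drifts are evaluated at the left endpoints (Ito), matching the
    transition-probability product the action is the negative log of.
    Nonnegative; zero exactly when every step follows the drift.
    """
    if len(path.times) < 2:
        raise ValueError("path must have at least 2 points")
    if not (path.noise.sigma2_mu > 0 and path.noise.sigma2_w > 0):
        raise ValueError("OM action requires strictly positive noise strengths")
    dt = path.dt
    t_left = path.times[:-1]
    s = signal.values(t_left)
    f, h = _drifts(path.mu_values[:-1], path.w_values[:-1], s, params)
    r_mu = np.diff(path.mu_values) / dt - f
    r_w = np.diff(path.w_values) / dt - h
    return float(dt * np.sum(r_mu ** 2 / (2 * path.noise.sigma2_mu)
                             + r_w ** 2 / (2 * path.noise.sigma2_w)))


def om_action_sequence(mu_fn: Callable[[np.ndarray], np.ndarray],
                       w_fn: Callable[[np.ndarray], np.ndarray],
                       signal: PresynapticSignal, params: ModelParams,
                       noise: NoiseStrengths, t_end: float,
                       dts: Sequence[float]) -> np.ndarray:
    """Discrete OM action of an analytic path at a sequence of step sizes.

    The path is given as closed-form functions mu(t), w(t); each entry of
    the returned array is the discrete action on the grid [0, t_end] with
    the corresponding dt.  As dt -> 0 the sequence approaches the continuum
    action (the quadrature of the path Lagrangian) at first order in dt,
    which is the sense in which the transition-probability product becomes
    the Onsager-Machlup path integral.
    """
    actions = []
    for dt in dts:
        n = int(round(t_end / dt))
        times = np.arange(n + 1) * dt
        path = SamplePath(times=times,
                          mu_values=np.asarray(mu_fn(times), dtype=float),
                          w_values=np.asarray(w_fn(times), dtype=float),
                          seed=0, noise=noise)
        actions.append(om_action_discrete(path, signal, params))
    return np.array(actions)
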