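"""Core types and pointwise quantities of the single-synapse model.

One synapse is described by three scalar signals: a presynaptic input ``s``,
the postsynaptic activity ``mu`` and the plastic weight ``w``.  Activity and
weight both follow overdamped Langevin dynamics whose deterministic drifts
are

.. math::

    f(\\mu, w; s) &= -\\gamma_\\mu (\\mu - \\mu_d) + w\\, s \\\\
    h(w, \\mu; s) &= -\\gamma_w  (w - w_d) + \\sigma\\, s\\, \\mu

with relaxation rates ``gamma_mu``, ``gamma_w``, set-points ``mu_d``,
``w_d`` and a coupling sign ``sigma`` that selects Hebbian (+1, co-activity
strengthens the synapse) or anti-Hebbian (-1) plasticity.

The negative log path probability of such a process is the time integral of
a quadratic Onsager-Machlup Lagrangian in the rate residuals
``mu_dot - f`` and ``w_dot - h``, weighted by the precisions (inverse noise
strengths) ``m_mu = 1/sigma_mu^2`` and ``m_w = 1/sigma_w^2``, which play the
role of masses.  This module houses the parameter container, the phase-space
state, the drifts, the Lagrangian, the conjugate momenta
(precision-weighted prediction errors), the Legendre-transformed Hamiltonian
and the fluctuation-dissipation mapping between friction, temperature and
noise strength.  All quantities are dimensionless (arbitrary units).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelParams",
    "PhaseState",
    "Trajectory",
    "NoiseStrengths",
    "PRESETS",
    "preset",
    "drift_mu",
    "drift_w",
    "momentum_from_rates",
    "lagrangian",
    "hamiltonian",
    "fdt_noise_strength",
    "mass_from_noise",
]


def _check_finite(**values) -> None:
    for name, value in values.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """All constants of the generative model and its Bayesian mechanics.

    Parameters
    ----------
    gamma_mu, gamma_w
        Relaxation (friction) rates of activity and weight, in inverse time.
        The default ratio gamma_mu = 10 * gamma_w encodes weight dynamics an
        order of magnitude slower than the activity.
    m_mu, m_w
        Precisions of the activity and weight generative processes,
        m = 1 / sigma^2; interpreted as masses in the Hamiltonian picture.
    mu_d, w_d
        Set-points: the steady-state activity and weight in the absence of
        presynaptic drive.
    hebbian_sign
        +1 for Hebbian coupling (+s*mu in the weight drift), -1 for
        anti-Hebbian (-s*mu).  The shipped reproduction presets use -1.
    kBT
        Thermal energy used only by the fluctuation-dissipation mapping;
        defaults to 1 so precisions can be set directly.
    nonlinear_weight_damping
        If True, the weight damping is the input-gated -gamma_w * s^2 *
        (w - w_d) instead of the linear -gamma_w * (w - w_d).
    """

    gamma_mu: float = 1.0
    gamma_w: float = 0.1
    m_mu: float = 5.0
    m_w: float = 0.5
    mu_d: float = 5.0
    w_d: float = 5.0
    hebbian_sign: int = 1
    kBT: float = 1.0
    nonlinear_weight_damping: bool = False

    def __post_init__(self):
        for name in ("gamma_mu", "gamma_w", "m_mu", "m_w", "kBT"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        _check_finite(mu_d=self.mu_d, w_d=self.w_d)
        if self.hebbian_sign not in (1, -1):
            raise ValueError(f"hebbian_sign must be +1 or -1, got {self.hebbian_sign!r}")

    @property
    def sigma2_mu(self) -> float:
        """Activity noise strength implied by the precision, 1/m_mu."""
        return 1.0 / self.m_mu

    @property
    def sigma2_w(self) -> float:
        """Weight noise strength implied by the precision, 1/m_w."""
        return 1.0 / self.m_w

    def effective_gamma_w(self, s: float):
        """Weight damping rate, input-gated when the nonlinear variant is on."""
        if self.nonlinear_weight_damping:
            return self.gamma_w * s * s
        return self.gamma_w

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "gamma_mu": self.gamma_mu,
            "gamma_w": self.gamma_w,
            "m_mu": self.m_mu,
            "m_w": self.m_w,
            "mu_d": self.mu_d,
            "w_d": self.w_d,
            "hebbian_sign": self.hebbian_sign,
            "kBT": self.kBT,
            "nonlinear_weight_damping": self.nonlinear_weight_damping,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(**{k: (int(v) if k == "hebbian_sign" else v)
                      for k, v in data.items()})


#: Named parameter presets.  The two "table1_*" rows are the published
#: parameter sets for the static-input experiments; they carry the
#: anti-Hebbian sign, which is the convention under which the reported fixed
#: points and damped oscillations are reproduced (see docs/methods.md).
PRESETS: dict[str, ModelParams] = {
    "table1_solid": ModelParams(gamma_mu=1.0, gamma_w=0.1, m_mu=5.0, m_w=0.5,
                                mu_d=5.0, w_d=5.0, hebbian_sign=-1),
    "table1_dotted": ModelParams(gamma_mu=1.0, gamma_w=0.1, m_mu=5.0, m_w=0.5,
                                 mu_d=10.0, w_d=0.0, hebbian_sign=-1),
}


def preset(name: str) -> ModelParams:
    """Look up a shipped parameter preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class PhaseState:
    """A point Psi = (mu, w, p_mu, p_w) in the 4-D synaptic phase space.

    ``mu`` is the postsynaptic activity, ``w`` the synaptic weight, and the
    momenta ``p_mu``, ``p_w`` are the precision-weighted prediction errors
    conjugate to them.
    """

    mu: float
    w: float
    p_mu: float = 0.0
    p_w: float = 0.0

    def __post_init__(self):
        _check_finite(mu=self.mu, w=self.w, p_mu=self.p_mu, p_w=self.p_w)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.w, self.p_mu, self.p_w], dtype=float)

    @classmethod
    def from_array(cls, psi) -> "PhaseState":
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (4,):
            raise ValueError(f"expected a 4-vector, got shape {psi.shape}")
        return cls(*psi)

    def __iter__(self) -> Iterator[float]:
        return iter((self.mu, self.w, self.p_mu, self.p_w))


@dataclass(frozen=True)
class Trajectory:
    """A sampled phase-space path with the input and energies along it.

    ``psi`` holds the states row-wise with columns (mu, w, p_mu, p_w);
    ``signal_values`` is the presynaptic input sampled on the same grid.
    The per-point Lagrangian/Hamiltonian and the accumulated action are
    optional, filled in by the integrator.
    """

    times: np.ndarray
    psi: np.ndarray
    signal_values: np.ndarray
    lagrangian_values: np.ndarray | None = None
    hamiltonian_values: np.ndarray | None = None
    cumulative_action: float | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        sig = np.asarray(self.signal_values, dtype=float)
        if times.ndim != 1 or len(times) < 2:
            raise ValueError("a trajectory needs at least 2 time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if psi.shape != (len(times), 4):
            raise ValueError(f"psi must have shape ({len(times)}, 4), got {psi.shape}")
        if sig.shape != times.shape:
            raise ValueError("signal_values must match times in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "signal_values", sig)
        for name in ("lagrangian_values", "hamiltonian_values"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value, dtype=float)
                if value.shape != times.shape:
                    raise ValueError(f"{name} must match times in length")
                object.__setattr__(self, name, value)

    @property
    def mu(self) -> np.ndarray:
        return self.psi[:, 0]

    @property
    def w(self) -> np.ndarray:
        return self.psi[:, 1]

    @property
    def p_mu(self) -> np.ndarray:
        return self.psi[:, 2]

    @property
    def p_w(self) -> np.ndarray:
        return self.psi[:, 3]

    @property
    def states(self) -> list[PhaseState]:
        return [PhaseState(*row) for row in self.psi]

    def state(self, i: int) -> PhaseState:
        return PhaseState(*self.psi[i])

    @property
    def final_state(self) -> PhaseState:
        return PhaseState(*self.psi[-1])

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t": self.times,
            "mu": self.mu,
            "w": self.w,
            "p_mu": self.p_mu,
            "p_w": self.p_w,
            "s": self.signal_values,
        }
        if self.lagrangian_values is not None:
            data["lagrangian"] = self.lagrangian_values
        if self.hamiltonian_values is not None:
            data["hamiltonian"] = self.hamiltonian_values
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write the trajectory as CSV with full (17 significant digit)
        precision so reruns are byte-identical."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class NoiseStrengths:
    """Noise variance rates (sigma_mu^2, sigma_w^2) of the two Langevin
    processes.  Zero is allowed and selects the deterministic limit."""

    sigma2_mu: float
    sigma2_w: float

    def __post_init__(self):
        for name in ("sigma2_mu", "sigma2_w"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be a finite nonnegative real, got {value!r}")

    @classmethod
    def from_params(cls, params: ModelParams) -> "NoiseStrengths":
        """Noise strengths consistent with the precisions, sigma^2 = 1/m."""
        return cls(sigma2_mu=params.sigma2_mu, sigma2_w=params.sigma2_w)


# ---------------------------------------------------------------------------
# pointwise model quantities


def drift_mu(mu, w, s, params: ModelParams):
    """Deterministic activity drift f = -gamma_mu (mu - mu_d) + w s."""
    _check_finite(mu=mu, w=w, s=s)
    return -params.gamma_mu * (np.asarray(mu, dtype=float) - params.mu_d) + np.asarray(w, dtype=float) * s


def drift_w(w, mu, s, params: ModelParams):
    """Deterministic weight drift h = -gamma_w (w - w_d) + sign * s * mu.

    With ``params.nonlinear_weight_damping`` the damping term is gated by
    the input power, -gamma_w s^2 (w - w_d).
    """
    _check_finite(mu=mu, w=w, s=s)
    gw = params.effective_gamma_w(np.asarray(s, dtype=float))
    return (-gw * (np.asarray(w, dtype=float) - params.w_d)
            + params.hebbian_sign * np.asarray(s, dtype=float) * mu)


def momentum_from_rates(mu_dot, w_dot, state_mu, state_w, s, params: ModelParams):
    """Conjugate momenta from path rates: p = m * (rate - drift).

    Each momentum is the precision-weighted discrepancy between the realized
    rate and the generative prediction -- the prediction error of predictive
    coding.
    """
    _check_finite(mu_dot=mu_dot, w_dot=w_dot)
    p_mu = params.m_mu * (np.asarray(mu_dot, dtype=float)
                          - drift_mu(state_mu, state_w, s, params))
    p_w = params.m_w * (np.asarray(w_dot, dtype=float)
                        - drift_w(state_w, state_mu, s, params))
    return p_mu, p_w


def lagrangian(mu_dot, w_dot, mu, w, s, params: ModelParams):
    """Onsager-Machlup Lagrangian: precision-weighted squared rate residuals.

    L = (m_mu/2)(mu_dot - f)^2 + (m_w/2)(w_dot - h)^2  >=  0.
    Its time integral is the free-energy action of the path.
    """
    r_mu = np.asarray(mu_dot, dtype=float) - drift_mu(mu, w, s, params)
    r_w = np.asarray(w_dot, dtype=float) - drift_w(w, mu, s, params)
    return 0.5 * params.m_mu * r_mu ** 2 + 0.5 * params.m_w * r_w ** 2


def hamiltonian(state, s, params: ModelParams):
    """Effective Hamiltonian H = p_mu^2/2m_mu + p_w^2/2m_w + p_mu f + p_w h.

    ``state`` may be a :class:`PhaseState` or any length-4 sequence.  H is
    not split into kinetic and potential parts; the drift terms couple
    momenta and positions, and H vanishes identically on the zero-momentum
    manifold.
    """
    if isinstance(state, PhaseState):
        mu, w, p_mu, p_w = state
    else:
        mu, w, p_mu, p_w = (np.asarray(x, dtype=float) for x in state)
    f = drift_mu(mu, w, s, params)
    h = drift_w(w, mu, s, params)
    return (p_mu ** 2 / (2.0 * params.m_mu) + p_w ** 2 / (2.0 * params.m_w)
            + p_mu * f + p_w * h)


def fdt_noise_strength(gamma: float, kBT: float = 1.0) -> float:
    """Fluctuation-dissipation mapping sigma^2 = 2 kBT / gamma."""
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValueError(f"gamma must be strictly positive, got {gamma!r}")
    if not (np.isfinite(kBT) and kBT > 0):
        raise ValueError(f"kBT must be strictly positive, got {kBT!r}")
    return 2.0 * kBT / gamma


def mass_from_noise(sigma2: float) -> float:
    """Precision (mass) from a noise strength, m = 1/sigma^2."""
    if not (np.isfinite(sigma2) and sigma2 > 0):
        raise ValueError(f"sigma2 must be strictly positive, got {sigma2!r}")
    return 1.0 / sigma2
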