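"""Presynaptic input streams s(t).

Four kinds of input are provided: a static level, a sinusoid, a decaying
(transient) sinusoid, and a user-supplied sampled series read from a
two-column text table.  The first three are the inputs of the numerical
experiments (amplitude 5, unit angular frequency, decay time 5); each may
carry additive Gaussian noise eta.

Noise is drawn per evaluation time from a counter-style generator keyed on
(seed, bit pattern of t): identical seeds therefore give bit-identical noisy
evaluations on identical grids, with no hidden state, and noise_sd = 0 makes
evaluation a pure function of t.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = ["PresynapticSignal", "UNDEFINED_LIMIT"]

#: Sentinel returned by :meth:`PresynapticSignal.s_infinity` when the input
#: has no long-time limit (e.g. a sinusoid).
UNDEFINED_LIMIT = None

_KINDS = ("static", "sinusoidal", "transient", "sampled")


@dataclass(frozen=True)
class PresynapticSignal:
    """A time-indexed presynaptic input s(t) with optional seeded noise.

    Attributes
    ----------
    kind
        One of ``static``, ``sinusoidal``, ``transient``, ``sampled``.
    amplitude
        Peak level of the deterministic part (default 5).
    angular_frequency
        omega in cos(omega t) for the oscillatory kinds (default 1).
    decay_time
        e-folding time of the transient envelope (default 5).
    noise_sd
        Standard deviation of the additive Gaussian fluctuation eta.
    seed
        Seed of the noise stream.
    samples
        (N, 2) array of (time, value) rows, for ``kind="sampled"`` only;
        evaluation interpolates linearly and raises outside the range.
    """

    kind: str = "static"
    amplitude: float = 5.0
    angular_frequency: float = 1.0
    decay_time: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0
    samples: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd!r}")
        if self.kind == "transient" and not self.decay_time > 0:
            raise ValueError("decay_time must be positive")
        if self.kind == "sampled":
            if self.samples is None:
                raise ValueError("kind='sampled' requires a samples table")
            samples = np.asarray(self.samples, dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 2:
                raise ValueError("samples must be an (N>=2, 2) table of (t, s)")
            if np.any(np.diff(samples[:, 0]) <= 0):
                raise ValueError("sample times must be strictly increasing")
            object.__setattr__(self, "samples", samples)

    # -- constructors -------------------------------------------------

    @classmethod
    def static(cls, amplitude: float = 5.0) -> "PresynapticSignal":
        """The constant input s = amplitude."""
        return cls(kind="static", amplitude=amplitude)

    @classmethod
    def sinusoidal(cls, amplitude: float = 5.0, angular_frequency: float = 1.0,
                   noise_sd: float = 0.0, seed: int = 0) -> "PresynapticSignal":
        """s(t) = amplitude * cos(omega t) + eta."""
        return cls(kind="sinusoidal", amplitude=amplitude,
                   angular_frequency=angular_frequency,
                   noise_sd=noise_sd, seed=seed)

    @classmethod
    def transient(cls, amplitude: float = 5.0, decay_time: float = 5.0,
                  angular_frequency: float = 1.0, noise_sd: float = 0.0,
                  seed: int = 0) -> "PresynapticSignal":
        """s(t) = amplitude * exp(-t/decay_time) * cos(omega t) + eta."""
        return cls(kind="transient", amplitude=amplitude, decay_time=decay_time,
                   angular_frequency=angular_frequency,
                   noise_sd=noise_sd, seed=seed)

    @classmethod
    def from_samples(cls, samples) -> "PresynapticSignal":
        return cls(kind="sampled", samples=np.asarray(samples, dtype=float))

    @classmethod
    def from_file(cls, path) -> "PresynapticSignal":
        """Read a sampled signal from a two-column whitespace- or
        comma-delimited text table of (t, s) rows."""
        text = Path(path).read_text()
        table = np.loadtxt(io.StringIO(text.replace(",", " ")))
        return cls.from_samples(np.atleast_2d(table))

    def with_seed(self, seed: int) -> "PresynapticSignal":
        return replace(self, seed=seed)

    # -- evaluation ---------------------------------------------------

    def _smooth(self, t: float) -> float:
        if self.kind == "static":
            return float(self.amplitude)
        if self.kind == "sinusoidal":
            return self.amplitude * np.cos(self.angular_frequency * t)
        if self.kind == "transient":
            return (self.amplitude * np.exp(-t / self.decay_time)
                    * np.cos(self.angular_frequency * t))
        # sampled
        times = self.samples[:, 0]
        if t < times[0] or t > times[-1]:
            raise ValueError(
                f"t={t} outside the sampled range [{times[0]}, {times[-1]}]")
        return float(np.interp(t, times, self.samples[:, 1]))

    def _noise(self, t: float) -> float:
        key = int(np.float64(t).view(np.uint64))
        rng = np.random.default_rng([self.seed, key])
        return self.noise_sd * rng.standard_normal()

    def evaluate(self, t: float) -> float:
        """The input value at time t (noisy if ``noise_sd > 0``)."""
        value = float(self._smooth(float(t)))
        if self.noise_sd > 0:
            value += self._noise(float(t))
        return value

    def values(self, times) -> np.ndarray:
        """Vectorized :meth:`evaluate` over a grid of times."""
        return np.array([self.evaluate(t) for t in np.asarray(times, dtype=float)])

    def __call__(self, t: float) -> float:
        return self.evaluate(t)

    def s_infinity(self):
        """Long-time limit s(t -> inf), or ``None`` when no limit exists.

        Static inputs saturate at their amplitude; noise-free transients
        decay to zero; sinusoids (and noisy or sampled signals) have no
        limit.
        """
        if self.kind == "static":
            return float(self.amplitude)
        if self.kind == "transient" and self.noise_sd == 0:
            return 0.0
        return UNDEFINED_LIMIT
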