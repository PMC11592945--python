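"""Exception types shared across the package."""


class DivergenceError(RuntimeError):
    """A trajectory left the finite domain during integration.

    Saddle configurations (Hebbian coupling with strong input) generically
    blow up once the momenta are excited; the error records when.
    """

    def __init__(self, message: str, time: float | None = None,
                 step: int | None = None):
        super().__init__(message)
        self.time = time
        self.step = step


class DegenerateSystemError(ValueError):
    """The stationarity system R Psi + I = 0 is singular.

    Occurs at the resonant input strengths s^2 = +/- gamma_mu * gamma_w,
    where the fixed point ceases to exist.
    """
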