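"""Exception types shared across the pipeline."""


class UsageError(ValueError):
    """Invalid arguments or configuration supplied by the caller."""


class DivergenceError(RuntimeError):
    """Level-set evolution produced non-finite values.

    Attributes
    ----------
    iteration : int
        1-based index of the time step at which φ first became non-finite.
    """

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(
            f"level-set evolution diverged (non-finite phi) at iteration {iteration}"
        )
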