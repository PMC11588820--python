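"""Exception types shared across the package."""


class ParameterDomainError(ValueError):
    """A parameter lies outside its legal interval.

    Parameters
    ----------
    field : str
        Name of the offending parameter.
    value : object
        The rejected value.
    legal : str
        Human-readable description of the legal interval.
    """

    def __init__(self, field: str, value, legal: str):
        self.field = field
        self.value = value
        self.legal = legal
        super().__init__(f"{field}={value!r} is out of range; expected {legal}")


class ConvergenceError(RuntimeError):
    """An iterative sample-size search failed to terminate."""


class DegenerateVarianceError(ValueError):
    """A variance that must be positive is zero."""


class InfeasibleDesignError(RuntimeError):
    """No design on the search grid stays under the sampling cap."""
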