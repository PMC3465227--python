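"""Exception hierarchy for model validation and simulation failures."""


class ModelError(Exception):
    """Base class for all model errors."""


class ValidationError(ModelError):
    """A configuration document is malformed or missing required keys."""


class RangeError(ValidationError):
    """A parameter lies outside its admissible range."""


class InfeasibleModelError(ModelError):
    """A transition-matrix row cannot be completed to a probability vector.

    Raised when the exit and death probabilities of a state sum to more
    than one, leaving a negative residual stay probability.
    """

    def __init__(self, state: str, age: float, residual: float, cycle: int | None = None):
        self.state = state
        self.age = age
        self.residual = residual
        self.cycle = cycle
        loc = f" (cycle {cycle})" if cycle is not None else ""
        super().__init__(
            f"row {state} at age {age:g}{loc}: exits plus death exceed 1 "
            f"(residual stay probability {residual:.6g})"
        )


class DegenerateCovarianceError(ModelError):
    """Too few samples or a singular covariance for ellipse construction."""
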