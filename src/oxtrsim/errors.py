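"""Exception hierarchy shared across the package."""


class OxtrsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OxtrsimError):
    """An input table or config names an unknown entity or is incomplete."""


class ValidationError(OxtrsimError):
    """A domain object violates one of its declared invariants."""


class SimulationError(OxtrsimError):
    """The ODE integrator failed or produced a non-finite state."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


class SpeciesLookupError(OxtrsimError, LookupError):
    """A named species is absent from a network or trajectory."""


class ResidueLookupError(OxtrsimError, LookupError):
    """A chain/residue pair is absent from a coordinate set."""


class PDBParseError(OxtrsimError):
    """A fixed-column coordinate line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class StructureError(OxtrsimError):
    """A residue is missing atoms required by a structural operation."""


class InfeasibleTargetError(OxtrsimError):
    """A calibration target lies outside the achievable range.

    Carries the achievable (lo, hi) interval evaluated at the bracket
    endpoints so callers can widen the bracket or rescale the target.
    """

    def __init__(self, message: str, achievable: tuple[float, float]):
        super().__init__(message)
        self.achievable = achievable


class NonMonotoneBracketError(OxtrsimError):
    """The response is not monotone over the requested bracket."""
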