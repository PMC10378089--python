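"""Exception hierarchy for entroage.

All domain errors derive from :class:`EntroageError` so callers can catch
library failures without masking programming errors.
"""


class EntroageError(Exception):
    """Base class for all entroage domain errors."""


class InvalidDistributionError(EntroageError, ValueError):
    """A density/probability vector violates its invariants (negative entry,
    all-zero mass, bad normalization)."""


class ShapeError(EntroageError, ValueError):
    """Two sequences that must share a length or mesh do not."""


class SupportError(EntroageError, ValueError):
    """The reference density q vanishes where p carries mass."""

    def __init__(self, message: str, compartment=None):
        super().__init__(message)
        self.compartment = compartment


class ParameterError(EntroageError, ValueError):
    """A scalar parameter is outside its admissible domain."""


class DegenerateStateError(EntroageError, ValueError):
    """A kinetic state has zero quadrature density at some spatial node."""

    def __init__(self, message: str, node=None):
        super().__init__(message)
        self.node = node


class DomainError(EntroageError, ValueError):
    """An integration/interpolation domain exceeds the data support."""


class ConvergenceError(EntroageError, RuntimeError):
    """Iterative solver failed to reach tolerance; carries the residual history."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class ConfigError(EntroageError, ValueError):
    """A run configuration contains unknown keys or out-of-domain values."""


class ProfileIOError(EntroageError, ValueError):
    """A profile file is missing, malformed, or violates invariants.

    Carries the 1-based line number of the offending row when applicable.
    """

    def __init__(self, message: str, line=None):
        super().__init__(message)
        self.line = line
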