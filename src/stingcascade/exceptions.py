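"""Exception hierarchy shared across the package."""


class StingCascadeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(StingCascadeError, ValueError):
    """An input object violates a structural invariant."""


class FeasibilityError(ValidationError):
    """A shape parameterisation falls outside its feasible region."""


class EnumerationCapError(StingCascadeError):
    """A combinatorial routine was asked to exceed its size cap."""


class FitError(StingCascadeError, RuntimeError):
    """An optimisation or sampling run failed to produce a usable result."""
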