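"""Exception types shared across the package."""


class BrinleySimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(BrinleySimError, ValueError):
    """A numeric parameter is outside its admissible range."""


class FormatError(BrinleySimError, ValueError):
    """A CSV/TSV artifact does not match the documented schema."""


class StructuralError(BrinleySimError, ValueError):
    """A table violates the design structure (missing group/condition)."""


class FitFailureError(BrinleySimError, RuntimeError):
    """A mixed-model fit failed to converge after all restarts."""
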