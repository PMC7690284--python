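"""Exception hierarchy.

``ValidationError`` covers bad user input (exit code 1 at the CLI);
everything else that goes wrong at run time maps to exit code 2.
"""


class HypoxiaQuantError(Exception):
    """Base class for all package errors."""


class ValidationError(HypoxiaQuantError, ValueError):
    """Invalid input values or inconsistent shapes/units."""


class ConfigurationError(ValidationError):
    """A phantom or pipeline specification violates its invariants."""


class GenerationError(HypoxiaQuantError, RuntimeError):
    """A synthetic-data request could not be satisfied (e.g. packing failure)."""


class LayoutError(ValidationError):
    """An array layout is missing required control spots."""
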