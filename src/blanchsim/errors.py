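"""Exception hierarchy.

Every error raised on bad user input derives from :class:`ValidationError`
(itself a ``ValueError``) so callers can catch one type; numerical-scheme
failures derive from :class:`NumericsError`.
"""


class BlanchSimError(Exception):
    """Base class for all package errors."""


class ValidationError(BlanchSimError, ValueError):
    """Invalid input (composition, grids, configuration values)."""


class CompositionError(ValidationError):
    """Mass fractions inconsistent (do not close to 1, negative, ...)."""


class ConfigError(ValidationError):
    """Configuration file or block violates the schema."""


class ExtrapolationError(ValidationError):
    """An observation time lies outside the prediction range."""


class NumericsError(BlanchSimError, RuntimeError):
    """Numerical-scheme failure (stability bound, step-size guard)."""


class StabilityError(NumericsError):
    """Explicit time step exceeds the stability bound."""


class StepSizeError(NumericsError):
    """ODE step too large for the stiffness guard."""


class FitError(BlanchSimError, RuntimeError):
    """Parameter-estimation failure (bad initial point, no convergence)."""
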