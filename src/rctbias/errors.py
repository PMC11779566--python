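"""Typed exceptions shared across the package."""


class RctBiasError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RctBiasError, ValueError):
    """A study or generator configuration violates its invariants."""


class InvalidInputError(RctBiasError, ValueError):
    """Operation inputs are malformed (length mismatch, empty arm, ...)."""


class DegenerateEstimateError(RctBiasError, ArithmeticError):
    """An effect estimate has zero standard error; inference is undefined.

    Raised instead of silently reporting p = 0 or p = 1 so callers can
    decide how a degenerate trial should enter downstream bookkeeping.
    """


class GenerationFailureError(RctBiasError, RuntimeError):
    """Accept/reject generation exhausted its attempt budget."""
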