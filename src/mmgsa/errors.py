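"""Exception hierarchy for mmgsa.

All package-raised errors derive from :class:`MmgsaError` so callers (and
the CLI) can distinguish input problems (:class:`ValidationError`,
:class:`ParseError`) from runtime/model failures.
"""


class MmgsaError(Exception):
    """Base class for all mmgsa errors."""


class ValidationError(MmgsaError):
    """Input violates a documented invariant (bad metadata, bad config, ...)."""


class ParseError(MmgsaError):
    """A file could not be parsed (malformed GMT line, non-numeric cell, ...)."""


class DegenerateDataError(MmgsaError):
    """Data carry no usable variation (e.g. all expression values identical)."""


class SetLookupError(MmgsaError, KeyError):
    """A requested gene set or gene is not present."""


class ConvergenceError(MmgsaError):
    """Optimizer failed fatally (normally reported as converged=False instead)."""
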