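"""Exception hierarchy.

All data-contract violations raise :class:`BCellHCCError` subclasses so callers
can distinguish bad inputs from programming errors. Loaders never repair data
silently; every rejection names the offending item.
"""


class BCellHCCError(ValueError):
    """Base class for all package errors."""


class LoadError(BCellHCCError):
    """A file violated the tabular format contract (names the row/column)."""


class ValidationError(BCellHCCError):
    """An in-memory object violated a type invariant."""


class DegenerateInputError(BCellHCCError):
    """An operation received input on which its statistic is undefined
    (constant column, zero-variance gene, empty group, ...)."""


class ConvergenceError(BCellHCCError):
    """An iterative fit failed to converge."""


class MonotoneLikelihoodError(ConvergenceError):
    """Cox partial likelihood is monotone (e.g. a group without events);
    the hazard-ratio estimate diverges."""
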