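"""Exception hierarchy shared by all moxatox modules."""


class MoxatoxError(Exception):
    """Base class for all package errors."""


class ValidationError(MoxatoxError, ValueError):
    """Raised when an input value violates a domain invariant.

    The message always names the offending field so callers (and the CLI,
    which maps this to exit code 2) can point users at the bad column.
    """


class EstimationError(MoxatoxError, RuntimeError):
    """Raised when an estimator cannot produce a result from valid inputs
    (e.g. mortality never brackets 50%).  Maps to CLI exit code 3.
    """
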