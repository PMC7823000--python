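"""Exception hierarchy.

Every error raised by the package derives from :class:`ECAPError`, itself a
``ValueError``, so callers can catch broadly or by failure mode.  The
fine-grained classes matter operationally: an electrode whose curves raise
:class:`InsufficientRegionError` or :class:`NoOverlapError` is *excluded from
analysis with a reason*, mirroring how real AGF studies discard electrodes
without measurable growth functions.
"""


class ECAPError(ValueError):
    """Base class for all ecapagf errors."""


class DomainError(ECAPError):
    """A physical quantity is outside its valid domain (e.g. current <= 0)."""


class ValidationError(ECAPError):
    """A data structure violates its invariants (lengths, ordering, signs)."""


class InsufficientRegionError(ECAPError):
    """Fewer than the minimum number of points fall in the linear region.

    Signals that the curve is unusable for slope/offset analysis.
    """


class NoOverlapError(ECAPError):
    """The linear regions of two curves share no usable amplitude range."""


class InvalidFitError(ECAPError):
    """An operation required a converged sigmoid fit but got a failed one."""


class ParseError(ECAPError):
    """A tabular input file is malformed; the message lists offending lines."""


class ConfigError(ECAPError):
    """Invalid configuration (unknown keys, wrong condition structure, ...)."""
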