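"""Exception types shared across the package."""


class RhizonetError(Exception):
    """Base class for all package errors."""


class ValidationError(RhizonetError):
    """Input violates a structural contract (duplicates, bad levels, ...)."""


class ParseError(RhizonetError):
    """A delimited file could not be parsed into a numeric table."""


class EmptyResultError(RhizonetError):
    """A filtering step removed everything."""


class InsufficientDataError(RhizonetError):
    """Too few samples/taxa for the requested statistic."""
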