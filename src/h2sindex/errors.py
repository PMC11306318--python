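"""Exception hierarchy shared across the package."""


class H2SIndexError(Exception):
    """Base class for all package errors."""


class ParseError(H2SIndexError):
    """A source file could not be parsed; message names the offending line."""


class OrderingError(ParseError):
    """Timestamps in a gas log are not strictly increasing."""


class ConfigError(H2SIndexError):
    """An invalid option or configuration value was supplied."""


class InvariantError(H2SIndexError):
    """A domain-type invariant was violated (e.g. negative peak count)."""


class UndefinedStatisticError(H2SIndexError):
    """A requested statistic is undefined for the given input (e.g. TWA of
    an empty log, a ratio with zero denominator)."""


class ModelError(H2SIndexError):
    """A model could not be fitted or evaluated on the given data."""
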