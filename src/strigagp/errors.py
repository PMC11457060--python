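"""Exception hierarchy shared across the package."""


class StrigaGPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StrigaGPError, ValueError):
    """An invalid simulation or pipeline configuration."""


class DomainError(StrigaGPError, ValueError):
    """An input outside the mathematical domain of an operation."""


class DimensionError(StrigaGPError, ValueError):
    """Mismatched shapes or identifier sets between linked objects."""


class EmptyResultError(StrigaGPError, ValueError):
    """An operation legitimately produced nothing (e.g. QC removed all markers)."""


class ParseError(StrigaGPError, ValueError):
    """A malformed input file; carries row/column coordinates where known."""
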