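"""Exception hierarchy for the pipeline.

All errors derive from :class:`EcogKitError` so callers can catch the
package's failures with one clause; each subclass also derives from the
closest builtin so idiomatic ``except ValueError`` style keeps working.
"""


class EcogKitError(Exception):
    """Base class for all ecogkit errors."""


class ConfigError(EcogKitError, ValueError):
    """Invalid configuration: unknown keys, unmappable channels, bad specs."""


class SizeError(EcogKitError, ValueError):
    """Input too short / empty for the requested operation."""


class BlockError(EcogKitError, ValueError):
    """Recording cannot accommodate the requested analysis blocks."""


class FilterError(EcogKitError, ValueError):
    """Filter specification invalid for the sampling rate."""


class ParseError(EcogKitError, ValueError):
    """Malformed delimited input; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateInputError(EcogKitError, ValueError):
    """Input on which the statistic is mathematically undefined (e.g. zero
    total power, zero pre-drug spike rate)."""
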