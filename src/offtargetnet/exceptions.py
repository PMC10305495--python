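"""Exception hierarchy shared across the package.

All errors derive from :class:`OffTargetNetError` so callers can catch the
package's failures with a single except clause while the CLI maps them to
exit codes.
"""


class OffTargetNetError(Exception):
    """Base class for all package errors."""


class SnapshotFormatError(OffTargetNetError, ValueError):
    """A flat-file snapshot violates its schema (missing column, bad row)."""


class MissingNodeError(OffTargetNetError, KeyError):
    """A requested protein/drug identifier is absent from its container."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class UsageError(OffTargetNetError, ValueError):
    """An operation was invoked with arguments outside its contract."""


class DomainError(OffTargetNetError, ValueError):
    """A numeric argument violates the mathematical domain of an operation."""


class UndefinedResultError(OffTargetNetError, ValueError):
    """The requested quantity is mathematically undefined for this input.

    Raised instead of silently returning 0 for e.g. the Jaccard index of two
    empty sets, the mean degree over an empty neighbor set, or a PTM
    breakdown with zero events.
    """


class ConfigError(OffTargetNetError, ValueError):
    """A simulation or pipeline configuration is invalid or unachievable."""
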