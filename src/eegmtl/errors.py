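"""Exception hierarchy.

All package-raised errors derive from :class:`EEGMTLError` so callers can
catch everything from one base; subclasses keep the distinctions the API
contracts promise (a missing channel is not a parse failure).
"""


class EEGMTLError(Exception):
    """Base class for all errors raised by eegmtl."""


class ParameterError(EEGMTLError, ValueError):
    """An argument violates a documented precondition."""


class ChannelError(EEGMTLError, KeyError):
    """A requested channel is absent from a recording or file."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ParseError(EEGMTLError, ValueError):
    """A data file contains content that cannot be interpreted."""


class ConsistencyError(EEGMTLError, ValueError):
    """A collection of inputs is internally inconsistent (shapes, rates)."""


class ConfigError(EEGMTLError, ValueError):
    """A configuration object or file fails validation."""


class VariantInterfaceError(EEGMTLError, AttributeError):
    """A task output was requested from a variant that does not expose it."""


class LabelError(EEGMTLError, ValueError):
    """A class label is outside the valid range for its task."""


class DependencyError(EEGMTLError, RuntimeError):
    """A pipeline step requires an artifact a prior step has not produced."""
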