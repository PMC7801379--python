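"""Exception hierarchy for capcontact.

All package errors derive from :class:`CapContactError`; configuration and
input-parsing problems are distinguished from computation failures so the CLI
can map them to distinct exit codes (2 vs 1).
"""


class CapContactError(Exception):
    """Base class for all capcontact errors."""


class InvalidInputError(CapContactError, ValueError):
    """An argument violates a documented precondition."""


class ParseError(CapContactError, ValueError):
    """A text input file is malformed; message carries the line number."""


class ConfigurationError(CapContactError):
    """A run configuration is inconsistent or references missing inputs."""


class ChromosomeLookupError(CapContactError, KeyError):
    """A chromosome (or interval on it) is unknown to the coordinate map."""


class LabelLookupError(CapContactError, KeyError):
    """A condition/replicate/sample label is not present in the data."""


class DegenerateLibraryError(CapContactError):
    """A sample has no usable reads where a normalization total is required."""


class PairingError(CapContactError):
    """Replicate labels cannot be matched one-to-one across conditions."""


class EmptyWindowError(CapContactError):
    """A window contains no member fragments."""


class UndefinedFactorError(CapContactError):
    """A spike-in normalization factor cannot be computed (zero counts)."""


class UndefinedCorrelationError(CapContactError):
    """A dataset column has zero variance; correlation is undefined."""


class InsufficientDataError(CapContactError):
    """Too few observations for the requested procedure."""
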