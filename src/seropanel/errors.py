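"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors are click's own (exit 2),
:class:`DataError` subclasses exit 3, anything else exits 1.
"""


class SeropanelError(Exception):
    """Base class for all package errors."""


class ConfigError(SeropanelError):
    """Invalid configuration value; the message names the offending field."""


class DataError(SeropanelError):
    """Input data violates a precondition (bad file, missing column, degenerate array)."""


class FormatError(DataError):
    """A file does not conform to the documented schema."""


class ParseError(DataError):
    """A row or cell could not be parsed; the message carries the location."""


class AnalysisError(SeropanelError):
    """An analysis step cannot proceed (e.g. single-class labels, empty panel)."""
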