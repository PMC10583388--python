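"""Exception hierarchy shared across the package.

Three failure classes are distinguished so callers (and the CLI) can map
them to exit codes: bad configuration, malformed input files, and
analysis-stage violations (e.g. too few baseline cycles).
"""


class NevoltError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NevoltError):
    """A parameter or protocol violates its invariants."""


class FormatError(NevoltError):
    """An input file or stream does not match the expected layout."""


class AnalysisError(NevoltError):
    """A computation's preconditions are not met by the data."""
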