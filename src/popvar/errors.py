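"""Exception hierarchy.

Every user-facing failure derives from :class:`PopvarError` so that the CLI
can map validation problems onto a single exit code.
"""


class PopvarError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PopvarError, ValueError):
    """Invalid configuration value (bad fraction, non-positive size, ...)."""


class FormatError(PopvarError, ValueError):
    """Malformed or inconsistent input file content."""


class AnalysisError(PopvarError, ValueError):
    """Input data violate a precondition of an analysis step."""
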