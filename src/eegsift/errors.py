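"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3;
everything else is a plain bug and propagates.
"""


class EEGSiftError(Exception):
    """Base class for all package errors."""


class ConfigError(EEGSiftError):
    """Invalid configuration (bad schema, out-of-range parameter)."""


class DataError(EEGSiftError):
    """Invalid or inconsistent input data (missing channel, short signal...)."""
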