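"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``FormatError``/``DataError``
to exit code 3.
"""


class OftPhaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OftPhaseError):
    """Invalid or missing configuration (bad cutoff, missing fs, ...)."""


class FormatError(OftPhaseError):
    """On-disk data does not match its declared format or metadata."""


class DataError(OftPhaseError):
    """Input data violates a precondition (too short, empty, non-finite)."""
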