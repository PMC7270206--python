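"""Exception hierarchy.

``DataValidationError`` maps to CLI exit code 3, ``ConfigError`` to exit
code 2; everything else is a plain failure.
"""


class WerfeError(Exception):
    """Base class for all package errors."""


class DataValidationError(WerfeError):
    """Input data violates a structural invariant (shapes, labels, NaNs)."""


class ConfigError(WerfeError):
    """A parameter or configuration value is invalid or unknown."""
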