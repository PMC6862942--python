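"""Exception hierarchy.

All package errors derive from :class:`UsualIntakeError` so callers can
catch everything with one clause; the three subclasses map onto the CLI
exit codes (config 2, data 3, model 4).
"""


class UsualIntakeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(UsualIntakeError, ValueError):
    """Invalid configuration or invalid argument combination."""


class DataError(UsualIntakeError, ValueError):
    """Input data violate a contract (nonpositive intakes, duplicates, ...)."""


class ModelError(UsualIntakeError, RuntimeError):
    """Model fitting failed or is not identifiable on the given data."""
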