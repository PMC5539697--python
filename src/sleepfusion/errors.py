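"""Exception types shared across the package."""


class SleepFusionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SleepFusionError, ValueError):
    """A parameter or configuration value is invalid."""


class InputError(SleepFusionError, ValueError):
    """An input signal or table violates a precondition."""


class SchemaError(SleepFusionError, KeyError):
    """A feature table does not match the expected column schema."""
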