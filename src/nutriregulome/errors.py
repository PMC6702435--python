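"""Exception types shared across the pipeline."""


class NutriregulomeError(Exception):
    """Base class for all package errors."""


class ConfigError(NutriregulomeError):
    """A configuration value violates its documented domain."""


class ValidationError(NutriregulomeError):
    """An input object violates a precondition of an operation."""


class SchemaError(NutriregulomeError):
    """A table does not match its documented column schema."""
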