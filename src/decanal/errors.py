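"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class InputError(ValueError):
    """Invalid data passed to an operation (lengths, ranges, emptiness)."""


class SchemaError(ValueError):
    """A table does not match its declared variable schema."""
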