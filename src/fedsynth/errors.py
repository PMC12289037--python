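"""Shared exception types."""


class InvalidInputError(ValueError):
    """Raised when data violates an operation's preconditions."""


class ConfigError(ValueError):
    """Raised when a configuration value is out of its legal range."""
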