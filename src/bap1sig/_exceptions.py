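"""Package exception types."""


class ConfigError(ValueError):
    """A configuration value is outside its documented range."""


class InputError(ValueError):
    """An input table violates a schema or invariant."""
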