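"""Exception hierarchy shared across the pipeline.

Every stage raises :class:`ValidationError` (or a subclass) for bad input so
the CLI can map it to exit code 2, distinct from unexpected failures.
"""


class ValidationError(ValueError):
    """Input violates a documented invariant (bad data, not a bug)."""


class ParseError(ValidationError):
    """A file could not be parsed; message carries location (line/row/column)."""


class ConfigurationError(ValidationError):
    """The requested configuration is inconsistent with the supplied data."""
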