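"""Error types shared across the package."""


class ConfigurationError(ValueError):
    """A model/option combination that can never be valid (e.g. attention
    reduction ratio not dividing the channel count)."""


class ValidationError(ValueError):
    """Input data that violates an operation's preconditions (shape
    mismatches, non-finite or non-binary arrays)."""
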