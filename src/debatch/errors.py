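"""Exception types raised by the data layer."""


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class ValidationError(ValueError):
    """Values violate a dataset invariant (NaN/Inf, label gaps, ...)."""


class JoinError(ValueError):
    """Matrix and metadata do not describe the same set of samples."""
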