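class ValidationError(ValueError):
    """Input data violates a documented precondition."""


class FormatError(ValueError):
    """An on-disk file does not match its declared format."""
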