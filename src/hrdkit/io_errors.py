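"""Shared exception types for readers and validators."""


class ValidationError(ValueError):
    """An input file or in-memory table violates a documented invariant."""
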