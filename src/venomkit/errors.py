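"""Exception types shared across venomkit modules."""


class ValidationError(ValueError):
    """Input violates a documented contract (bad value, missing id, ...)."""


class ParseError(ValueError):
    """A structured text input could not be parsed; message carries location."""
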