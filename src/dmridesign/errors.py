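"""Exception types shared across the package."""


class InputValidationError(ValueError):
    """Raised when an operation receives arguments outside its contract."""


class ConfigurationError(ValueError):
    """Raised when an experiment configuration is inconsistent or incomplete."""
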