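"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A hyperparameter or option is outside its valid range."""


class ContractError(ValueError):
    """Inputs violate a data contract (shape mismatch, non-probabilities, ...)."""


class InvalidLabelError(ContractError):
    """A label mask contains a value outside [0, num_classes - 1]."""


class GenerationError(RuntimeError):
    """The synthetic-data generator cannot satisfy the requested constraints."""
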