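"""Exception types shared across the package."""


class FormatError(ValueError):
    """A data file or container does not have the expected layout."""


class ConfigurationError(ValueError):
    """An option or argument combination is invalid."""


class TrainingError(RuntimeError):
    """Optimization failed (for example, the loss became non-finite)."""
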