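"""Exception types shared across the package."""


class NeuroFuzzyError(ValueError):
    """Base class for errors raised by this package."""


class ConfigurationError(NeuroFuzzyError):
    """A configuration is inconsistent (e.g. empty class, rule cap exceeded)."""


class DegenerateInputError(NeuroFuzzyError):
    """An input makes a computation undefined (e.g. zero total firing strength)."""


class DivergenceError(NeuroFuzzyError):
    """Training produced non-finite loss values."""
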