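"""Exception hierarchy shared across the package."""


class PatModelsError(ValueError):
    """Base class for all package errors."""


class ConfigurationError(PatModelsError):
    """Invalid task / agent / run configuration."""


class DataError(PatModelsError):
    """Invalid or incomplete input data (traces, trial tables, samples)."""


class ModelError(PatModelsError):
    """Model specification or fitting problem (mismatched parameter sets,
    rank deficiency, incompatible fits)."""
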