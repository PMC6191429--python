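"""Exception hierarchy shared across the pipeline stages."""


class MetaPhewasError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MetaPhewasError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ConfigError(MetaPhewasError, ValueError):
    """A configuration object or file is inconsistent."""


class DegenerateInputError(MetaPhewasError, ValueError):
    """Input data admit no meaningful fit (single-class labels, constant dosage...)."""


class AlleleMismatchError(MetaPhewasError, ValueError):
    """An allele pair cannot be reconciled with the reference orientation."""
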