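"""Exception hierarchy shared by all pipeline stages."""


class CorogrowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CorogrowError):
    """Invalid phantom or pipeline configuration."""


class ParameterError(CorogrowError):
    """A numeric parameter is out of its valid range."""


class InputError(CorogrowError):
    """Invalid input data (shape mismatch, non-finite values, bad coordinates)."""


class FormatError(CorogrowError):
    """A file on disk does not satisfy the expected format contract."""


class TrainingError(CorogrowError):
    """The segmenter cannot be trained from the given data."""


class LocalizationError(CorogrowError):
    """No valid seed point could be derived from the aorta masks."""


class EvaluationError(CorogrowError):
    """A metric is undefined for the given inputs (e.g. empty comparison set)."""
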