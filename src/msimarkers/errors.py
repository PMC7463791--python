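"""Exception hierarchy shared by all pipeline stages."""


class MsiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MsiError):
    """A file is missing, truncated or not in the expected on-disk format."""


class SchemaError(MsiError):
    """A tabular input lacks required columns or has an invalid header."""


class ParseError(MsiError):
    """A row or value in a tabular input could not be parsed."""


class ParameterError(MsiError, ValueError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class ConfigError(MsiError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class EmptyDataError(MsiError):
    """An operation received an empty dataset, selection or sample."""


class NormalizationError(MsiError):
    """A spectrum cannot be normalized (e.g. all intensities are zero)."""
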