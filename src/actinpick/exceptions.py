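"""Exception types shared across the package."""


class ActinpickError(Exception):
    """Base class for all package errors."""


class ParameterError(ActinpickError, ValueError):
    """A parameter or argument violates its documented constraints."""


class FormatError(ActinpickError, ValueError):
    """An on-disk file is malformed or has an unsupported layout."""


class ConfigError(ActinpickError, ValueError):
    """A configuration file is invalid (unknown key, bad value)."""


class DataError(ActinpickError, ValueError):
    """A dataset is empty, inconsistent, or incompatible with a model."""
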