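"""Exception hierarchy shared across the package."""


class ImmunosigError(Exception):
    """Base class for all errors raised by immunosig."""


class DataValidationError(ImmunosigError, ValueError):
    """Input data violate a container invariant or an operation precondition."""


class ParseError(ImmunosigError, ValueError):
    """An on-disk file could not be parsed; the message names the location."""


class ConfigError(ImmunosigError, ValueError):
    """A configuration object or file is invalid."""
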