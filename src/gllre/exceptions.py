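"""Exception types raised by the gllre package."""


class GLLREError(Exception):
    """Base class for all gllre-specific errors."""


class InvalidInputError(GLLREError, ValueError):
    """An input array violates a structural precondition (shape, dtype, range)."""


class InvalidParameterError(GLLREError, ValueError):
    """A configuration parameter is out of its admissible domain."""


class NoThresholdError(GLLREError, RuntimeError):
    """No admissible threshold exists (e.g. a constant image)."""
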