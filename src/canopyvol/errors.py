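"""Exception hierarchy for canopyvol.

``CanopyVolError`` covers data/validation failures; ``ConfigError`` covers
bad configuration. The CLI maps these onto distinct exit codes.
"""


class CanopyVolError(Exception):
    """Base class for data and validation errors."""


class ImageFormatError(CanopyVolError):
    """Input image is not a 3-channel 8-bit RGB image."""


class ValidationError(CanopyVolError):
    """An input record or argument violates a precondition."""


class DegenerateInputError(CanopyVolError):
    """An operation received an input on which its result is undefined
    (e.g. an empty canopy mask, a zero denominator)."""


class FitError(CanopyVolError):
    """A model fit failed to converge.

    Carries ``params`` with the initialiser's parameter estimates so a
    caller can fall back to them or report them.
    """

    def __init__(self, message: str, params: tuple | None = None):
        super().__init__(message)
        self.params = params


class RenderError(CanopyVolError):
    """The synthetic renderer could not reach the requested canopy cover."""


class ConfigError(Exception):
    """Invalid run configuration (CLI / config file)."""
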