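"""Exception hierarchy shared across the pipeline stages."""


class FcorError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FcorError):
    """A file could not be parsed as the expected format."""


class ShapeError(FcorError):
    """Array dimensions are inconsistent with what an operation requires."""


class ParameterError(FcorError, ValueError):
    """A parameter value is outside its valid domain."""


class CapacityError(FcorError):
    """A mask is too small to host the requested spatial structures."""


class ConfigError(FcorError):
    """A pipeline configuration is incomplete or inconsistent."""


class DegenerateSeedError(FcorError):
    """A seed time course is constant, so correlations are undefined."""


class DesignError(FcorError):
    """A statistical design matrix is rank deficient or otherwise unusable."""
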