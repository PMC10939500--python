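"""Exception hierarchy shared across the package."""


class CraniomorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CraniomorphError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateGeometryError(CraniomorphError, ValueError):
    """Geometry does not support the requested operation
    (collinear landmarks, zero-size shape, zero vertex normal, ...)."""


class ParseError(CraniomorphError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ManifestError(CraniomorphError, ValueError):
    """A cohort manifest is inconsistent or references missing files."""


class CollinearityError(CraniomorphError, ValueError):
    """The design matrix is rank-deficient or the contrast lies in the
    span of the nuisance covariates."""


class SaturationError(CraniomorphError, ValueError):
    """All droplets positive: the Poisson concentration estimate diverges."""
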