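"""Exception hierarchy for isletwave."""


class IsletWaveError(Exception):
    """Base class for all package-specific errors."""


class PackingInfeasibleError(IsletWaveError):
    """Requested cell count cannot be packed into the islet at the given spacing."""


class FormatError(IsletWaveError):
    """An input file or array does not match the expected format."""


class OutOfBoundsError(IsletWaveError):
    """An ROI or cell position falls outside the image field of view."""


class NotAWaveError(IsletWaveError):
    """Velocity requested for an event that did not propagate between regions."""


class UndefinedVelocityError(IsletWaveError):
    """Velocity d/dt is undefined (zero onset lag)."""


class BaselineUndefinedError(IsletWaveError):
    """Week-0 baseline value is missing, undefined, or zero."""
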