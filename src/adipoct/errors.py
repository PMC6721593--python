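"""Exception hierarchy shared across the package."""


class AdipoCTError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AdipoCTError):
    """An input violates a documented precondition."""


class GeometryError(AdipoCTError):
    """A geometric construction is impossible (tumor outside breast, VOI off-grid...)."""


class UnitError(AdipoCTError):
    """A volume carries the wrong physical unit for the requested operation."""


class FormatError(AdipoCTError):
    """A file on disk is not a readable 3-D volume."""


class InsufficientAdiposeError(AdipoCTError):
    """Too few fat-window voxels inside a VOI to trust the mean attenuation.

    Mirrors the clinical exclusion of patients without enough breast adipose
    tissue for measurement.  ``side`` labels which VOI failed ("tumor" or
    "contralateral") when known.
    """

    def __init__(self, message: str, side: str | None = None):
        super().__init__(message)
        self.side = side


class DegenerateDataError(AdipoCTError):
    """A statistic is undefined for the given data (zero variance, one class...)."""


class ConvergenceError(AdipoCTError):
    """A model fit failed to converge (e.g. monotone Cox partial likelihood)."""
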