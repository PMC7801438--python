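"""Exception hierarchy shared by all hydrokin modules."""


class HydrokinError(Exception):
    """Base class for all package errors."""


class InsufficientDataError(HydrokinError):
    """Too few points/frames/lags for the requested operation."""


class DomainError(HydrokinError):
    """An input value is outside the mathematically valid domain."""


class SingularDesignError(HydrokinError):
    """Regression design matrix is rank-deficient (e.g. duplicate temperatures)."""


class ConfigurationError(HydrokinError):
    """A required field/setting is missing or inconsistent."""


class FormatError(HydrokinError):
    """A file does not conform to the expected on-disk format."""


class TimestepTooLargeError(HydrokinError):
    """Discrete hop probability exceeds validity bound; reduce dt or rates."""
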