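"""Exception hierarchy shared across punctakit modules."""


class PunctakitError(Exception):
    """Base class for all punctakit errors."""


class CalibrationError(PunctakitError):
    """Missing or invalid spatial/temporal calibration."""


class TimeAxisError(PunctakitError):
    """A time-lapse operation was requested on a single-frame stack."""


class AlignmentError(PunctakitError):
    """Channel alignment could not be determined (e.g. featureless input)."""


class MaskError(PunctakitError):
    """Invalid, empty or incongruent region mask."""


class BorderError(PunctakitError):
    """A measurement site lies too close to the image border."""


class InsufficientSitesError(PunctakitError):
    """Fewer valid measurement sites than the configured minimum."""


class ParameterError(PunctakitError):
    """A parameter value outside its valid range."""


class PackingError(PunctakitError):
    """Requested objects cannot be placed in the available field."""


class NormalizationError(PunctakitError):
    """Image intensities are not on the expected normalized scale."""


class NoCellsError(PunctakitError):
    """No nuclei / cells could be identified in the image."""
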