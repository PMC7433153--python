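"""Exception hierarchy for the dectpeel pipeline."""


class DectpeelError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(DectpeelError):
    """An input violates a precondition (shape mismatch, bad parameter...)."""


class GeometryError(ValidationError):
    """Phantom geometry is inconsistent (e.g. tumor not inside the liver)."""


class SingularCalibrationError(ValidationError):
    """Iodine sensitivities coincide; the two-material system is singular."""


class EmptyRegionError(DectpeelError):
    """A region that must contain voxels is empty."""


class SegmentationFailedError(DectpeelError):
    """Region growing could not produce a usable mask."""


class NormalizationError(DectpeelError):
    """Aortic iodine concentration is non-positive; NIC is undefined."""


class ParenchymaUndefinedError(EmptyRegionError):
    """No liver voxels remain after removing tumor, layers and exclusions."""


class DegenerateTableError(DectpeelError):
    """A contingency table has an expected count of zero."""


class UndefinedOddsRatioError(DectpeelError):
    """Zero cells in a cross pattern make the odds ratio undefined."""


class DegenerateDataError(DectpeelError):
    """A reliability statistic is undefined (e.g. zero total variance)."""
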