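"""Exception hierarchy.

Every error raised by this package derives from :class:`PhycoSpecError` so
callers can catch the whole family; argument-validation errors additionally
derive from :class:`ValueError`.
"""


class PhycoSpecError(Exception):
    """Base class for all phycospec errors."""


class InvalidArgumentError(PhycoSpecError, ValueError):
    """An argument violates a documented precondition."""


class ShapeError(InvalidArgumentError):
    """Array dimensions are inconsistent with each other or with a grid."""


class FormatError(PhycoSpecError):
    """A file does not conform to the expected on-disk format."""


class CorruptionError(FormatError):
    """Header metadata and binary payload disagree."""


class DegenerateReferenceError(PhycoSpecError):
    """Reference data carry no usable signal (zero white-dark gap, constant y)."""


class DegenerateBandError(PhycoSpecError):
    """One or more spectral bands have zero variance across samples."""

    def __init__(self, bands, message=None):
        self.bands = list(bands)
        super().__init__(message or f"zero-variance bands: {self.bands}")


class DegenerateSpectrumError(PhycoSpecError):
    """A spectrum is constant and cannot be row-scaled."""

    def __init__(self, rows, message=None):
        self.rows = list(rows)
        super().__init__(message or f"constant spectra at rows: {self.rows}")


class DegenerateFitError(PhycoSpecError):
    """A per-row regression has a vanishing slope (MSC correction undefined)."""

    def __init__(self, rows, message=None):
        self.rows = list(rows)
        super().__init__(message or f"degenerate scatter fit at rows: {self.rows}")


class DegenerateTargetError(PhycoSpecError):
    """The regression target has zero variance."""


class EmptyROIError(PhycoSpecError):
    """A region-of-interest mask contains no pixels."""


class InvalidModelError(PhycoSpecError):
    """Model coefficients are unusable (e.g. singular pigment-equation matrix)."""


class IncompatibleGridError(PhycoSpecError):
    """Two spectral objects are defined on different wavelength grids."""


class ConvergenceError(PhycoSpecError):
    """An iterative solver exhausted its iteration budget."""
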