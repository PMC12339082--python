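"""Exception hierarchy for the osteoquant pipeline."""


class OsteoquantError(Exception):
    """Base class for all osteoquant errors."""


class InvalidStandardsError(OsteoquantError):
    """Calibration standards are degenerate (equal or inverted gray levels)."""


class GrayLevelDomainError(OsteoquantError):
    """A gray level lies outside the 8-bit range or the calibrated Ca range."""


class ImageFormatError(OsteoquantError):
    """The input raster is not a single-channel 8-bit image."""


class EmptyRegionError(OsteoquantError):
    """A region of interest contains no contributing pixels."""


class EmptyCurveError(OsteoquantError):
    """A BMDD curve has no mass (all-zero frequencies)."""


class BinningError(OsteoquantError):
    """BMDD curves with incompatible binning were combined."""


class FrontNotFoundError(OsteoquantError):
    """No transverse unmineralized band separating two mineralized compartments."""


class EmptyROIError(OsteoquantError):
    """A derived ROI is empty or lies entirely outside the image."""


class EmptyPhaseError(OsteoquantError):
    """No mineralized pixels in the ROI for a phase-based measurement."""


class ProvenanceError(OsteoquantError):
    """Records do not originate from the mask/ROI they are summarized against."""


class SampleSizeError(OsteoquantError):
    """A statistical routine received fewer observations than it supports."""


class DegenerateSampleError(OsteoquantError):
    """A statistical routine received a constant (zero-variance) sample."""


class DesignError(OsteoquantError):
    """A factorial design is incomplete (an empty cell)."""


class ConfigError(OsteoquantError):
    """A synthetic-image or run configuration is internally inconsistent."""


class MetadataError(OsteoquantError):
    """Required per-sample metadata (e.g. standards gray levels) is missing."""


class ReferenceError_(OsteoquantError):
    """No samples available to build the reference BMDD."""
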