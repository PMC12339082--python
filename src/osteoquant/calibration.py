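"""Gray-level to calcium weight-percent calibration for qBEI images.

Backscattered-electron gray values scale with the local mean atomic number,
so in mineralized bone they encode calcium content.  Each imaging session is
anchored by measuring two pure standards, carbon (Z=6) and aluminum (Z=13).
The measured standard gray levels are mapped onto fixed *canonical* positions
(defaults 25 and 225), which absorbs detector gain/offset drift between
sessions, and the canonical scale is converted to wt% calcium with a fixed
slope of 0.17 wt%Ca per canonical gray-level step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GrayLevelDomainError, ImageFormatError, InvalidStandardsError

#: Maximum physically meaningful calcium content (pure hydroxyapatite ~39.9,
#: values above 45 indicate a broken calibration).
CA_MAX_WT_PCT = 45.0

#: Default spatial resolution of the imaging protocol, µm per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.88


@dataclass(frozen=True)
class CalibrationConstants:
    """Session-independent constants of the canonical calcium scale."""

    carbon_gl_canonical: float = 25.0
    aluminum_gl_canonical: float = 225.0
    ca_per_canonical_gl: float = 0.17  # wt%Ca per canonical gray-level step
    zero_ca_gl: float = 25.0  # canonical gray level at which Ca = 0


@dataclass(frozen=True)
class CalibrationModel:
    """Two-point affine map from measured gray level to wt% calcium.

    ``canonical(g)`` rescales a measured gray level so the measured standards
    land exactly on their canonical anchors; ``ca(g)`` then applies the fixed
    calcium slope around the zero-calcium offset.
    """

    slope: float  # wt%Ca per canonical gray-level step
    offset_gl: float  # canonical gray level at Ca = 0
    carbon_gl_measured: float
    aluminum_gl_measured: float
    carbon_gl_canonical: float
    aluminum_gl_canonical: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidStandardsError("calibration slope must be positive")
        if not self.aluminum_gl_measured > self.carbon_gl_measured:
            raise InvalidStandardsError(
                "aluminum standard must backscatter more than carbon "
                f"(got C={self.carbon_gl_measured}, Al={self.aluminum_gl_measured})"
            )

    @property
    def canonical_per_measured(self) -> float:
        return (self.aluminum_gl_canonical - self.carbon_gl_canonical) / (
            self.aluminum_gl_measured - self.carbon_gl_measured
        )

    def canonical(self, gray):
        """Map measured gray level(s) onto the canonical gray scale."""
        gray = np.asarray(gray, dtype=float)
        return self.carbon_gl_canonical + (gray - self.carbon_gl_measured) * self.canonical_per_measured

    def ca(self, gray):
        """Calcium content (wt%Ca) for measured gray level(s), unclipped."""
        return self.slope * (self.canonical(gray) - self.offset_gl)

    def gray_for_ca(self, ca):
        """Inverse map: measured gray level that calibrates to ``ca`` wt%Ca."""
        ca = np.asarray(ca, dtype=float)
        canonical = ca / self.slope + self.offset_gl
        return self.carbon_gl_measured + (canonical - self.carbon_gl_canonical) / self.canonical_per_measured


@dataclass
class CaMap:
    """Calibrated raster of calcium content.

    ``values`` holds wt%Ca per pixel; off-sample pixels (embedding resin,
    area outside the section) are marked NaN.  ``pixel_size`` is µm/px.
    """

    values: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ImageFormatError("CaMap values must be a 2D raster")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        on = self.values[np.isfinite(self.values)]
        if on.size and (on.min() < 0 or on.max() > CA_MAX_WT_PCT):
            raise GrayLevelDomainError(
                "calibrated Ca values outside [0, 45] wt%Ca; check the standards"
            )

    @property
    def on_sample(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def shape(self):
        return self.values.shape

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))


def fit_calibration(
    carbon_gl_measured: float,
    aluminum_gl_measured: float,
    constants: CalibrationConstants | None = None,
) -> CalibrationModel:
    """Fit the two-point gray-level calibration from the measured standards.

    Parameters
    ----------
    carbon_gl_measured, aluminum_gl_measured
        Mean gray levels measured on the carbon and aluminum standards
        (0–255).  Aluminum must be strictly brighter than carbon.
    constants
        Canonical anchor positions and calcium slope; defaults follow common
        qBEI practice (carbon → 25, aluminum → 225, 0.17 wt%Ca per step).
    """
    constants = constants or CalibrationConstants()
    for name, g in (("carbon", carbon_gl_measured), ("aluminum", aluminum_gl_measured)):
        if not (0 <= g <= 255):
            raise GrayLevelDomainError(f"{name} standard gray level {g} outside [0, 255]")
    if aluminum_gl_measured <= carbon_gl_measured:
        raise InvalidStandardsError(
            "standard gray levels equal or inverted: "
            f"C={carbon_gl_measured}, Al={aluminum_gl_measured}"
        )
    return CalibrationModel(
        slope=constants.ca_per_canonical_gl,
        offset_gl=constants.zero_ca_gl,
        carbon_gl_measured=float(carbon_gl_measured),
        aluminum_gl_measured=float(aluminum_gl_measured),
        carbon_gl_canonical=constants.carbon_gl_canonical,
        aluminum_gl_canonical=constants.aluminum_gl_canonical,
    )


def apply_calibration(
    raw: np.ndarray,
    model: CalibrationModel,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    sample_mask: np.ndarray | None = None,
) -> CaMap:
    """Convert a raw 8-bit raster to a calibrated :class:`CaMap`.

    Calcium values below zero (organic matrix / resin darker than the zero
    point) are clipped to 0; they fall below the mineralized threshold
    downstream either way.  Pixels flagged False in ``sample_mask`` are
    marked off-sample (NaN).
    """
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise ImageFormatError(f"expected single-channel 2D image, got shape {raw.shape}")
    if raw.dtype != np.uint8 and (raw.min() < 0 or raw.max() > 255):
        raise ImageFormatError("expected 8-bit gray levels in [0, 255]")
    ca = np.clip(model.ca(raw.astype(float)), 0.0, None)
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, dtype=bool)
        if sample_mask.shape != raw.shape:
            raise ImageFormatError("sample_mask shape does not match image")
        ca = np.where(sample_mask, ca, np.nan)
    return CaMap(values=ca, pixel_size=pixel_size)


def load_image(path) -> np.ndarray:
    """Read a single-channel 8-bit TIFF or PNG into a uint8 array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path}: expected 8-bit data, got {arr.dtype}")
    return arr
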