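"""Bone mineralization density distribution (BMDD).

The BMDD is the histogram of calcium content over mineralized bone area,
expressed in percent of bone area per bin.  Five scalar descriptors are
derived from it:

* CaMean — frequency-weighted mean calcium content,
* CaPeak — position of the histogram mode,
* CaWidth — full width at half maximum (mineralization heterogeneity),
* CaLow / CaHigh — percent of bone area below the 5th / above the 95th
  calcium percentile of a designated reference BMDD (here, the pooled
  wild-type metaphyseal distribution of the matching age group).

Bins are half-open ``[k*w, (k+1)*w)`` anchored at 0 wt%Ca, with the default
width ``w = 0.17`` wt%Ca equal to the resolution of the calcium scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CaMap
from .errors import BinningError, EmptyCurveError, EmptyRegionError

DEFAULT_BIN_WIDTH = 0.17  # wt%Ca
DEFAULT_MINERAL_THRESHOLD = 5.2  # wt%Ca; boundary between unmineralized and mineralized

_BIN_RTOL = 1e-6


@dataclass
class BMDDCurve:
    """Normalized calcium histogram: frequencies in % of mineralized area."""

    bin_centers: np.ndarray  # wt%Ca, uniform spacing, anchored so edges are k*w
    frequencies: np.ndarray  # % of bone area per bin, sums to 100
    bin_width: float
    n_pixels: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.bin_centers.shape != self.frequencies.shape or self.bin_centers.ndim != 1:
            raise BinningError("bin_centers and frequencies must be matching 1D arrays")
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency in BMDD curve")
        if self.bin_centers.size > 1:
            steps = np.diff(self.bin_centers)
            if not np.allclose(steps, self.bin_width, rtol=_BIN_RTOL, atol=1e-9):
                raise BinningError("bin centers are not uniformly spaced at bin_width")
        if self.n_pixels > 0 and abs(self.frequencies.sum() - 100.0) > 1e-9:
            raise ValueError("frequencies of a non-empty curve must sum to 100")

    @property
    def lower_edges(self) -> np.ndarray:
        return self.bin_centers - self.bin_width / 2.0

    @property
    def upper_edges(self) -> np.ndarray:
        return self.bin_centers + self.bin_width / 2.0

    def same_binning(self, other: "BMDDCurve") -> bool:
        if abs(self.bin_width - other.bin_width) > _BIN_RTOL * self.bin_width:
            return False
        # bins must sit on the same lattice (anchored at 0)
        offset = (self.bin_centers[0] - other.bin_centers[0]) / self.bin_width
        return abs(offset - round(offset)) < 1e-6

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"bin_center_wt_pct_ca": self.bin_centers, "frequency_pct": self.frequencies}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class BMDDParams:
    ca_mean: float  # wt%Ca
    ca_peak: float  # wt%Ca
    ca_width: float  # wt%Ca (FWHM)
    ca_low: float | None = None  # % of bone area below reference p5
    ca_high: float | None = None  # % of bone area above reference p95


@dataclass
class ReferenceBMDD:
    """Pooled reference distribution and its 5th/95th calcium percentiles."""

    pooled_curve: BMDDCurve
    p5: float
    p95: float

    def __post_init__(self) -> None:
        if not self.p5 < self.p95:
            raise ValueError("reference percentiles must satisfy p5 < p95")


def compute_bmdd(
    camap: CaMap,
    region: np.ndarray | None = None,
    threshold: float = DEFAULT_MINERAL_THRESHOLD,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BMDDCurve:
    """Histogram the calcium content of mineralized pixels in a region.

    ``region`` is an optional boolean raster selecting the evaluated area
    (``ROISpec.mask`` works directly); off-sample pixels and pixels below
    ``threshold`` never contribute.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    values = camap.values
    select = np.isfinite(values) & (values >= threshold)
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != values.shape:
            raise EmptyRegionError("region shape does not match the CaMap")
        select &= region
    ca = values[select]
    if ca.size == 0:
        raise EmptyRegionError("no mineralized on-sample pixels in the region")
    # the small epsilon keeps values that land exactly on a bin edge (gray
    # levels calibrate onto multiples of the bin width) in a consistent bin
    idx = np.floor(ca / bin_width + 1e-9).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    freqs = counts / counts.sum() * 100.0
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return BMDDCurve(bin_centers=centers, frequencies=freqs, bin_width=bin_width, n_pixels=ca.size)


def bmdd_params(curve: BMDDCurve) -> BMDDParams:
    """CaMean, CaPeak and CaWidth of a BMDD curve.

    CaPeak is the center of the maximal bin; exact ties average the tied
    centers.  CaWidth is the full width at half the peak frequency using
    linear interpolation between bin centers and the *outermost* half-max
    crossings, with virtual zero bins padding both ends.
    """
    f = curve.frequencies
    if f.size == 0 or f.sum() == 0:
        raise EmptyCurveError("cannot derive parameters from an empty BMDD curve")
    c = curve.bin_centers
    w = curve.bin_width
    ca_mean = float(np.sum(f * c) / f.sum())

    fmax = f.max()
    ca_peak = float(c[f == fmax].mean())

    half = fmax / 2.0
    fp = np.concatenate(([0.0], f, [0.0]))
    cp = np.concatenate(([c[0] - w], c, [c[-1] + w]))
    above = np.nonzero(fp >= half)[0]
    lo, hi = above[0], above[-1]  # outermost crossings bracket the peak
    x_left = cp[lo - 1] + (half - fp[lo - 1]) / (fp[lo] - fp[lo - 1]) * w
    x_right = cp[hi] + (fp[hi] - half) / (fp[hi] - fp[hi + 1]) * w
    return BMDDParams(ca_mean=ca_mean, ca_peak=ca_peak, ca_width=float(x_right - x_left))


def _check_common_binning(curves: list[BMDDCurve]) -> None:
    first = curves[0]
    for other in curves[1:]:
        if not first.same_binning(other):
            raise BinningError("BMDD curves have incompatible binning")


def _aligned_frequencies(curves: list[BMDDCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Stack frequencies on a common bin lattice, padding with zeros."""
    w = curves[0].bin_width
    start = min(int(round(cv.lower_edges[0] / w)) for cv in curves)
    stop = max(int(round(cv.upper_edges[-1] / w)) for cv in curves)
    centers = (np.arange(start, stop) + 0.5) * w
    stacked = np.zeros((len(curves), stop - start))
    for i, cv in enumerate(curves):
        k0 = int(round(cv.lower_edges[0] / w)) - start
        stacked[i, k0 : k0 + cv.frequencies.size] = cv.frequencies
    return centers, stacked


def reference_percentiles(curves: list[BMDDCurve]) -> ReferenceBMDD:
    """Pool curves (unweighted per-sample mean) and locate p5/p95.

    Each sample counts equally regardless of its bone area, matching the
    per-animal weighting of the cohort statistics.  Percentiles are found by
    linear interpolation on the cumulative distribution of the pooled curve,
    treating each bin as uniform over its extent.
    """
    if not curves:
        raise EmptyCurveError("need at least one curve to build a reference")
    _check_common_binning(curves)
    centers, stacked = _aligned_frequencies(curves)
    pooled = stacked.mean(axis=0)
    pooled = pooled / pooled.sum() * 100.0
    w = curves[0].bin_width
    n_pixels = int(sum(cv.n_pixels for cv in curves))
    pooled_curve = BMDDCurve(bin_centers=centers, frequencies=pooled, bin_width=w, n_pixels=n_pixels)

    lower = pooled_curve.lower_edges
    cum = np.concatenate(([0.0], np.cumsum(pooled)))  # at bin edges

    def _percentile(q: float) -> float:
        k = int(np.searchsorted(cum, q, side="right")) - 1
        k = min(max(k, 0), pooled.size - 1)
        inside = (q - cum[k]) / pooled[k] if pooled[k] > 0 else 0.0
        return float(lower[k] + inside * w)

    return ReferenceBMDD(pooled_curve=pooled_curve, p5=_percentile(5.0), p95=_percentile(95.0))


def ca_low_high(curve: BMDDCurve, ref: ReferenceBMDD) -> tuple[float, float]:
    """Percent of bone area below ref.p5 (CaLow) and above ref.p95 (CaHigh).

    Bins straddling a percentile are apportioned linearly.
    """
    if not curve.same_binning(ref.pooled_curve):
        raise BinningError("curve and reference have incompatible binning")
    lo = curve.lower_edges
    w = curve.bin_width
    frac_below = np.clip((ref.p5 - lo) / w, 0.0, 1.0)
    frac_above = np.clip((lo + w - ref.p95) / w, 0.0, 1.0)
    ca_low = float(np.sum(curve.frequencies * frac_below))
    ca_high = float(np.sum(curve.frequencies * frac_above))
    return ca_low, ca_high
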