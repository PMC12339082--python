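"""Structural histomorphometry of mineralized bone on 2D qBEI sections.

Works from a binary mineral mask (Ca >= 5.2 wt%Ca).  The section layout is a
longitudinal long-bone cut: an epiphyseal mineralized compartment, the
unmineralized growth-plate band (resting + proliferative cartilage), and the
metaphyseal compartment below it.  Measurements:

* the per-column mineralization front on the metaphyseal side of the band,
* primary-spongiosa (first 500 µm below the front) and secondary-spongiosa
  (next 1000 µm) band ROIs,
* BV/TV (area fraction), Tb.Th (local-thickness mean) and Tb.N (plate model)
  per ROI,
* the growth-plate thickness as the per-column unmineralized gap between the
  two compartments.

Axis convention: the bone long axis runs along image rows ("vertical"),
metaphysis at larger row indices; pixel coordinates are 0-based row-major
and band intervals are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .calibration import CaMap
from .errors import EmptyPhaseError, EmptyROIError, FrontNotFoundError

DEFAULT_MINERAL_THRESHOLD = 5.2  # wt%Ca
PRIMARY_BAND_UM = 500.0
SECONDARY_BAND_UM = 1000.0


@dataclass
class MineralMask:
    """Binary raster of mineralized tissue with its provenance threshold."""

    mask: np.ndarray
    threshold: float
    pixel_size: float
    off_sample: np.ndarray | None = None  # True where outside the section

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.off_sample is not None:
            self.off_sample = np.asarray(self.off_sample, dtype=bool)

    @property
    def shape(self):
        return self.mask.shape


@dataclass
class ROISpec:
    """A named region of interest as a boolean raster."""

    label: str
    mask: np.ndarray
    axis: str = "vertical"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptyROIError(f"ROI '{self.label}' is empty")

    @classmethod
    def from_rect(cls, label, shape, rows: slice, cols: slice) -> "ROISpec":
        m = np.zeros(shape, dtype=bool)
        m[rows, cols] = True
        return cls(label=label, mask=m)


@dataclass(frozen=True)
class HistomorphResult:
    region_label: str
    bv_tv: float  # %
    tb_th: float | None  # µm (None when not computed)
    tb_n: float | None  # per mm
    bone_area: float  # µm²
    tissue_area: float  # µm²


@dataclass
class GrowthPlateResult:
    mean_thickness: float  # µm
    per_column_thickness: np.ndarray  # µm, valid columns only
    n_valid_columns: int


@dataclass
class FrontLine:
    """Per-column metaphyseal mineralization front below the growth plate."""

    rows: np.ndarray  # row index of first mineralized pixel, per column
    valid: np.ndarray  # columns where a crossing was found
    band_rows: tuple[int, int]  # detected unmineralized band core [start, stop)

    def filled_rows(self) -> np.ndarray:
        """Front rows with invalid columns filled by linear interpolation."""
        if not self.valid.any():
            raise FrontNotFoundError("no valid front columns")
        cols = np.arange(self.rows.size)
        return np.round(
            np.interp(cols, cols[self.valid], self.rows[self.valid].astype(float))
        ).astype(int)


def make_mineral_mask(camap: CaMap, threshold: float = DEFAULT_MINERAL_THRESHOLD) -> MineralMask:
    """Threshold a CaMap; off-sample pixels are never mineralized."""
    on = camap.on_sample
    mask = on & (np.nan_to_num(camap.values, nan=-1.0) >= threshold)
    off = None if on.all() else ~on
    return MineralMask(mask=mask, threshold=threshold, pixel_size=camap.pixel_size, off_sample=off)


def _opened(mask: MineralMask, opening_radius: int) -> np.ndarray:
    """Morphological opening to suppress single-pixel noise in the mask."""
    if opening_radius <= 0:
        return mask.mask
    size = 2 * opening_radius + 1
    return ndi.binary_opening(mask.mask, structure=np.ones((size, size), dtype=bool))


def _find_band(m: np.ndarray, band_frac: float, min_rows: int) -> tuple[int, int]:
    """Locate the transverse unmineralized band core as a row interval.

    The band is the longest run of rows whose mineralized fraction is at most
    ``band_frac``, required to have mineralized rows both above and below.
    ``band_frac`` tolerates partial bone bridges across the band but must
    stay below the mineral fraction of the sparsest trabecular compartment.
    """
    profile = m.mean(axis=1)
    low = profile <= band_frac
    best = None
    r = 0
    n = low.size
    while r < n:
        if low[r]:
            start = r
            while r < n and low[r]:
                r += 1
            if (best is None) or (r - start > best[1] - best[0]):
                best = (start, r)
        else:
            r += 1
    if best is None or best[1] - best[0] < min_rows:
        raise FrontNotFoundError("no transverse unmineralized band found")
    start, stop = best
    if not m[:start].any() or not m[stop:].any():
        raise FrontNotFoundError("unmineralized band is not flanked by mineralized compartments")
    return start, stop


def _overhang_limit(start: int, stop: int, overhang_frac: float) -> int:
    """Columns whose crossing lies further than this beyond the band core
    belong to deeper structures (open marrow), not the band boundary."""
    return max(int(round(overhang_frac * (stop - start))), 8)


def detect_mineralization_front(
    mask: MineralMask,
    opening_radius: int = 1,
    band_frac: float = 0.08,
    band_min_rows: int = 3,
    overhang_frac: float = 0.5,
) -> FrontLine:
    """Per-column first mineralized pixel on the metaphyseal side of the band.

    The mask is opened first (3×3 by default) so isolated noise pixels do not
    create spurious fronts.  Columns that are mineralized inside the band
    core (bone bridges), never become mineralized below it, or only become
    mineralized far beyond the band core (marrow channels rather than the
    band boundary) are invalid.
    """
    m = _opened(mask, opening_radius)
    start, stop = _find_band(m, band_frac, band_min_rows)
    center = (start + stop) // 2
    n_rows, n_cols = m.shape
    rows = np.full(n_cols, -1, dtype=int)
    valid = np.zeros(n_cols, dtype=bool)
    below = m[center:, :]
    bridged = m[center, :]
    first = np.argmax(below, axis=0)
    has = below.any(axis=0)
    ok = has & ~bridged & (center + first <= stop + _overhang_limit(start, stop, overhang_frac))
    rows[ok] = center + first[ok]
    valid[ok] = True
    if not valid.any():
        raise FrontNotFoundError("no column crosses into mineralized metaphysis")
    return FrontLine(rows=rows, valid=valid, band_rows=(start, stop))


def define_spongiosa_rois(
    front: FrontLine,
    shape: tuple[int, int],
    pixel_size: float,
    primary_um: float = PRIMARY_BAND_UM,
    secondary_um: float = SECONDARY_BAND_UM,
    column_range: tuple[int, int] | None = None,
) -> tuple[ROISpec, ROISpec]:
    """Per-column primary and secondary spongiosa band ROIs below the front.

    Primary spans ``[front, front + 500 µm)``, secondary the following
    1000 µm, measured per column from the detected front (invalid columns
    interpolated).  Band depths are rounded to the nearest pixel count.
    ``column_range`` restricts the bands laterally (e.g. to exclude cortex).
    """
    n_rows, n_cols = shape
    d1 = int(round(primary_um / pixel_size))
    d2 = int(round(secondary_um / pixel_size))
    f = front.filled_rows()
    cols = np.zeros(n_cols, dtype=bool)
    if column_range is None:
        cols[:] = True
    else:
        cols[column_range[0] : column_range[1]] = True
    rr = np.arange(n_rows)[:, None]
    primary = (rr >= f[None, :]) & (rr < f[None, :] + d1) & cols[None, :]
    secondary = (rr >= f[None, :] + d1) & (rr < f[None, :] + d1 + d2) & cols[None, :]
    if (f + d1 + d2).max() > n_rows:
        warnings.warn("spongiosa bands clipped at the image border", stacklevel=2)
    if not primary.any() or not secondary.any():
        raise EmptyROIError("spongiosa band lies entirely outside the image")
    return (
        ROISpec(label="primary_spongiosa", mask=primary),
        ROISpec(label="secondary_spongiosa", mask=secondary),
    )


def bv_tv(mask: MineralMask, roi: ROISpec) -> HistomorphResult:
    """Bone area fraction (%) of the ROI, with absolute areas in µm²."""
    roi_px = int(roi.mask.sum())
    if roi_px == 0:
        raise EmptyROIError(f"ROI '{roi.label}' is empty")
    bone_px = int((mask.mask & roi.mask).sum())
    px_area = mask.pixel_size**2
    return HistomorphResult(
        region_label=roi.label,
        bv_tv=100.0 * bone_px / roi_px,
        tb_th=None,
        tb_n=None,
        bone_area=bone_px * px_area,
        tissue_area=roi_px * px_area,
    )


def local_thickness(mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """2D local-thickness field: per foreground pixel, the diameter of the
    largest inscribed disc containing it, in µm.

    Uses the distance-transform/sphere-covering construction: pixels whose
    distance to background rounds to r seed discs of diameter ``2r - 1``
    pixels; discs are painted in descending radius order so each pixel keeps
    the largest covering disc.  Everything outside the raster counts as
    background (no disc may extend past the border).
    """
    mask = np.asarray(mask, dtype=bool)
    lt = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return lt
    padded = np.pad(mask, 1, constant_values=False)
    dt = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
    # a disc of integer radius ceil(dt)-1 around a pixel always fits inside
    # the phase, and no larger integer radius does
    rint = np.ceil(dt - 1e-9).astype(int)
    for r in np.unique(rint[rint > 0])[::-1]:
        seeds = rint >= r
        if r > 1:
            covered = ndi.distance_transform_edt(~seeds) <= (r - 1)
        else:
            covered = seeds
        sel = mask & covered & (lt == 0)
        lt[sel] = 2 * r - 1
    return lt * pixel_size


def trabecular_thickness(mask: MineralMask, roi: ROISpec, pad: int | None = None) -> float:
    """Mean trabecular thickness (µm) over mineralized pixels of the ROI.

    Area-weighted mean of the local-thickness field.  The field is computed
    on a window padded beyond the ROI bounding box so structures crossing
    the ROI boundary keep their true thickness; the pad defaults to twice
    the largest inscribed-disc radius in the image, which guarantees that
    every disc covering an ROI pixel (and the background defining it) lies
    inside the window.
    """
    sel = mask.mask & roi.mask
    if not sel.any():
        raise EmptyPhaseError(f"no mineralized pixels in ROI '{roi.label}'")
    if pad is None:
        dt_full = ndi.distance_transform_edt(mask.mask)
        pad = 2 * int(np.ceil(dt_full.max())) + 3
    rows, cols = np.nonzero(sel)
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + 1 + pad, mask.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + 1 + pad, mask.shape[1])
    lt = local_thickness(mask.mask[r0:r1, c0:c1], mask.pixel_size)
    return float(lt[rows - r0, cols - c0].mean())


def trabecular_number(bv_tv_pct: float, tb_th_um: float) -> float:
    """Plate-model trabecular number, per mm: (BV/TV)/Tb.Th."""
    if tb_th_um <= 0:
        raise ZeroDivisionError("Tb.Th must be positive for the plate model")
    return (bv_tv_pct / 100.0) / tb_th_um * 1000.0


def growth_plate_thickness(
    mask: MineralMask,
    opening_radius: int = 1,
    band_frac: float = 0.08,
    band_min_rows: int = 3,
    column_range: tuple[int, int] | None = None,
    overhang_frac: float = 0.5,
) -> GrowthPlateResult:
    """Mean unmineralized growth-plate thickness (µm) across columns.

    Per column, the gap in pixels between the last epiphyseal mineralized
    pixel and the first metaphyseal mineralized pixel around the detected
    band core.  Columns bridged by bone inside the band, whose band runs
    into the image border, or whose nearest mineral lies far beyond the
    band core (open marrow channels rather than the band boundary) are
    excluded.
    """
    m = _opened(mask, opening_radius)
    start, stop = _find_band(m, band_frac, band_min_rows)
    center = (start + stop) // 2
    n_rows, n_cols = m.shape
    c0, c1 = (0, n_cols) if column_range is None else column_range
    above = m[:center, c0:c1]
    below = m[center:, c0:c1]
    bridged = m[center, c0:c1]
    has_above = above.any(axis=0)
    has_below = below.any(axis=0)
    last_epi = (center - 1) - np.argmax(above[::-1, :], axis=0)
    first_met = center + np.argmax(below, axis=0)
    overhang = _overhang_limit(start, stop, overhang_frac)
    ok = (
        has_above
        & has_below
        & ~bridged
        & (first_met <= stop + overhang)
        & (last_epi >= start - 1 - overhang)
    )
    if not ok.any():
        raise FrontNotFoundError("no column with a measurable growth-plate gap")
    gap_px = (first_met[ok] - last_epi[ok] - 1).astype(float)
    thickness = gap_px * mask.pixel_size
    return GrowthPlateResult(
        mean_thickness=float(thickness.mean()),
        per_column_thickness=thickness,
        n_valid_columns=int(ok.sum()),
    )
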