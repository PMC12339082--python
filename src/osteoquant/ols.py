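"""Osteocyte lacunae sections (OLS).

Osteocyte lacunae appear in qBEI images as small unmineralized voids fully
enclosed by mineralized matrix.  They are extracted as connected components
of the unmineralized phase (8-connectivity for voids, the standard digital
topology pairing with 4-connected foreground), gated to sectional areas
between 5 and 200 µm², and summarized as porosity, density and median
geometry.  The empty-lacuna fraction comes from upstream manual histology
counts, not from the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import EmptyRegionError, ProvenanceError
from .histomorphometry import MineralMask, ROISpec

OLS_MIN_AREA_UM2 = 5.0
OLS_MAX_AREA_UM2 = 200.0


@dataclass(frozen=True)
class OLSRecord:
    """Geometry of one lacuna section."""

    id: int
    area: float  # µm²
    perimeter: float  # µm, Crofton 4-direction estimate
    centroid: tuple[float, float]  # (row, col) pixel coordinates


@dataclass(frozen=True)
class OLSSummary:
    ols_porosity: float  # % of evaluated bone area occupied by lacunae
    ols_density: float  # lacunae per mm² of evaluated bone area
    median_area: float | None  # µm²; None when no lacunae
    median_perimeter: float | None  # µm; None when no lacunae
    n_lacunae: int


@dataclass(frozen=True)
class LacunaCounts:
    """Manual empty/total lacuna counts from decalcified histology."""

    sample_id: str
    n_empty: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_empty <= self.n_total):
            raise ValueError("need 0 <= n_empty <= n_total")


def extract_ols(
    mask: MineralMask,
    min_area: float = OLS_MIN_AREA_UM2,
    max_area: float = OLS_MAX_AREA_UM2,
    roi: ROISpec | None = None,
) -> list[OLSRecord]:
    """Extract lacuna sections from the unmineralized phase of the mask.

    A void component qualifies only if it is fully enclosed by mineralized
    matrix: it must touch neither the raster border nor (8-adjacency) any
    off-sample pixel — marrow space and canals connected to the outside are
    thereby excluded.  Components with area in ``[min_area, max_area]``
    (inclusive, µm²) are returned; ``roi`` optionally restricts records to
    those whose centroid lies inside it.
    """
    if not (0 < min_area < max_area):
        raise ValueError("need 0 < min_area < max_area")
    voids = ~mask.mask
    near_off = None
    if mask.off_sample is not None:
        voids &= ~mask.off_sample
        near_off = ndi.binary_dilation(mask.off_sample, structure=np.ones((3, 3), bool))
    labels = measure.label(voids, connectivity=2)
    if labels.max() == 0:
        return []

    n = labels.max()
    border_ids = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    excluded = np.zeros(n + 1, dtype=bool)
    excluded[border_ids] = True
    if near_off is not None:
        excluded[np.unique(labels[near_off])] = True
    excluded[0] = True

    px_area = mask.pixel_size**2
    records: list[OLSRecord] = []
    for prop in measure.regionprops(labels):
        if excluded[prop.label]:
            continue
        area = prop.area * px_area
        if not (min_area <= area <= max_area):
            continue
        if roi is not None:
            r, c = prop.centroid
            if not roi.mask[int(round(r)), int(round(c))]:
                continue
        records.append(
            OLSRecord(
                id=prop.label,
                area=float(area),
                perimeter=float(prop.perimeter_crofton * mask.pixel_size),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return records


def ols_summary(
    records: list[OLSRecord],
    mask: MineralMask,
    roi: ROISpec | None = None,
) -> OLSSummary:
    """Cohort-level OLS statistics over an evaluated bone area.

    The evaluated bone area is mineralized area plus lacunar area (the
    lacunae are part of the bone they perforate).  Medians use the standard
    mean-of-two convention for even counts.
    """
    sel = mask.mask if roi is None else (mask.mask & roi.mask)
    if roi is not None:
        for rec in records:
            r, c = (int(round(rec.centroid[0])), int(round(rec.centroid[1])))
            if not roi.mask[r, c]:
                raise ProvenanceError(f"lacuna {rec.id} lies outside ROI '{roi.label}'")
    mineral_area = float(sel.sum()) * mask.pixel_size**2
    lacunar_area = float(sum(r.area for r in records))
    eval_area = mineral_area + lacunar_area
    if eval_area <= 0:
        raise EmptyRegionError("no evaluated bone area")
    n = len(records)
    if n == 0:
        return OLSSummary(0.0, 0.0, None, None, 0)
    return OLSSummary(
        ols_porosity=100.0 * lacunar_area / eval_area,
        ols_density=n / (eval_area / 1e6),
        median_area=float(np.median([r.area for r in records])),
        median_perimeter=float(np.median([r.perimeter for r in records])),
        n_lacunae=n,
    )


def empty_fraction(counts: LacunaCounts) -> float:
    """Percent of counted lacunae that are empty."""
    if counts.n_total == 0:
        raise EmptyRegionError("no counted lacunae")
    return 100.0 * counts.n_empty / counts.n_total
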