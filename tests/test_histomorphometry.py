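"""Trabecular and growth-plate histomorphometry on constructed geometries."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from osteoquant.calibration import CaMap
from osteoquant.errors import EmptyPhaseError, EmptyROIError, FrontNotFoundError
from osteoquant.histomorphometry import (
    MineralMask,
    ROISpec,
    bv_tv,
    define_spongiosa_rois,
    detect_mineralization_front,
    growth_plate_thickness,
    local_thickness,
    make_mineral_mask,
    trabecular_number,
    trabecular_thickness,
)


def mmask(mask, pixel_size=0.88) -> MineralMask:
    return MineralMask(mask=np.asarray(mask, bool), threshold=5.2, pixel_size=pixel_size)


def banded_mask(n_rows=400, n_cols=200, band=(100, 150), pixel_size=0.88) -> MineralMask:
    m = np.ones((n_rows, n_cols), dtype=bool)
    m[band[0] : band[1], :] = False
    return mmask(m, pixel_size)


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: exhaustive largest-inscribed-disc search.

    For every foreground pixel q, find the largest integer radius rho such
    that all pixels within Euclidean distance rho of q are foreground; every
    pixel covered by that disc sees a structure of diameter 2*rho + 1 px.
    """
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    lt = np.zeros((h, w))
    fg = np.argwhere(mask)
    for r0, c0 in fg:
        rho = 0
        while True:
            nxt = rho + 1
            rr, cc = np.ogrid[-nxt : nxt + 1, -nxt : nxt + 1]
            disc = rr**2 + cc**2 <= nxt**2
            ri, ci = r0 - nxt, c0 - nxt
            if ri < 0 or ci < 0 or r0 + nxt >= h or c0 + nxt >= w:
                break
            if not mask[ri : r0 + nxt + 1, ci : c0 + nxt + 1][disc].all():
                break
            rho = nxt
        rr, cc = np.ogrid[-rho : rho + 1, -rho : rho + 1]
        disc = rr**2 + cc**2 <= rho**2
        window = lt[r0 - rho : r0 + rho + 1, c0 - rho : c0 + rho + 1]
        window[disc] = np.maximum(window[disc], 2 * rho + 1)
    return lt


class TestMineralMask:
    def test_uniform_above_threshold_all_true(self):
        camap = CaMap(values=np.full((5, 5), 25.0))
        assert make_mineral_mask(camap).mask.all()

    def test_uniform_below_threshold_all_false(self):
        camap = CaMap(values=np.full((5, 5), 3.0))
        assert not make_mineral_mask(camap).mask.any()

    def test_pixelwise_threshold(self):
        vals = np.array([[4.0, 6.0], [6.0, 4.0]])
        mask = make_mineral_mask(CaMap(values=vals)).mask
        assert np.array_equal(mask, vals >= 5.2)

    def test_off_sample_pixels_never_mineralized(self):
        vals = np.full((3, 3), 25.0)
        vals[1, 1] = np.nan
        mask = make_mineral_mask(CaMap(values=vals))
        assert not mask.mask[1, 1]
        assert mask.off_sample[1, 1]


class TestFrontDetection:
    def test_flat_band_front(self):
        front = detect_mineralization_front(banded_mask(), opening_radius=0)
        assert front.valid.all()
        assert np.all(front.rows == 150)
        assert front.band_rows == (100, 150)

    def test_sinusoidal_boundary_recovered_exactly(self):
        n_rows, n_cols = 400, 240
        cols = np.arange(n_cols)
        boundary = 150 + np.round(3 * np.sin(2 * np.pi * cols / 120)).astype(int)
        m = np.zeros((n_rows, n_cols), dtype=bool)
        m[:100, :] = True
        m[(np.arange(n_rows)[:, None] >= boundary[None, :])] = True
        front = detect_mineralization_front(mmask(m))
        assert front.valid.all()
        assert np.array_equal(front.rows, boundary)

    def test_all_mineralized_raises(self):
        with pytest.raises(FrontNotFoundError):
            detect_mineralization_front(mmask(np.ones((100, 50), bool)))

    def test_all_unmineralized_raises(self):
        with pytest.raises(FrontNotFoundError):
            detect_mineralization_front(mmask(np.zeros((100, 50), bool)))


class TestSpongiosaRois:
    def test_band_depths_at_protocol_pixel_size(self):
        front = detect_mineralization_front(banded_mask(n_rows=2000), opening_radius=0)
        primary, secondary = define_spongiosa_rois(front, (2000, 200), pixel_size=0.88)
        rows_p = np.nonzero(primary.mask[:, 0])[0]
        rows_s = np.nonzero(secondary.mask[:, 0])[0]
        assert rows_p[0] == 150 and rows_p.size == 568  # 500/0.88 = 568.2
        assert rows_s[0] == 150 + 568 and rows_s.size == 1136

    def test_unit_pixel_size_gives_500_rows(self):
        front = detect_mineralization_front(banded_mask(n_rows=2000, pixel_size=1.0), opening_radius=0)
        primary, _ = define_spongiosa_rois(front, (2000, 200), pixel_size=1.0)
        assert primary.mask[:, 0].sum() == 500

    def test_clipped_band_warns(self):
        # image only 650 px deep below the front: secondary band is clipped
        front = detect_mineralization_front(banded_mask(n_rows=800), opening_radius=0)
        with pytest.warns(UserWarning, match="clipped"):
            _, secondary = define_spongiosa_rois(front, (800, 200), pixel_size=1.0)
        assert secondary.mask[:, 0].sum() == 150  # rows 650..800

    def test_band_outside_image_raises(self):
        front = detect_mineralization_front(banded_mask(n_rows=400), opening_radius=0)
        with pytest.raises(EmptyROIError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                define_spongiosa_rois(front, (400, 200), pixel_size=1.0,
                                      primary_um=300.0, secondary_um=1000.0)


class TestBvTv:
    def test_all_mineralized_is_100(self):
        mask = mmask(np.ones((50, 50), bool), pixel_size=1.0)
        roi = ROISpec.from_rect("r", (50, 50), slice(0, 50), slice(0, 50))
        res = bv_tv(mask, roi)
        assert res.bv_tv == pytest.approx(100.0)
        assert res.bone_area == res.tissue_area == pytest.approx(2500.0)

    def test_alternating_stripes_are_50(self):
        m = np.zeros((100, 200), bool)
        for start in range(0, 200, 100):
            m[:, start : start + 50] = True
        roi = ROISpec.from_rect("r", (100, 200), slice(0, 100), slice(0, 200))
        assert bv_tv(mmask(m), roi).bv_tv == pytest.approx(50.0)

    def test_random_mask_recovers_planted_density(self):
        rng = np.random.default_rng(7)
        m = rng.random((1000, 1000)) < 0.3
        roi = ROISpec.from_rect("r", m.shape, slice(0, 1000), slice(0, 1000))
        assert bv_tv(mmask(m), roi).bv_tv == pytest.approx(30.0, abs=0.2)

    def test_rotation_and_reflection_invariance(self):
        rng = np.random.default_rng(11)
        m = rng.random((60, 80)) < 0.4
        roi = np.zeros_like(m)
        roi[10:50, 20:70] = True
        base = bv_tv(mmask(m), ROISpec("r", roi)).bv_tv
        for transform in (np.rot90, np.fliplr, np.flipud):
            assert bv_tv(mmask(transform(m)), ROISpec("r", transform(roi))).bv_tv == pytest.approx(base)

    def test_dilation_never_decreases_bvtv(self):
        rng = np.random.default_rng(13)
        m = rng.random((80, 80)) < 0.2
        roi = ROISpec.from_rect("r", m.shape, slice(0, 80), slice(0, 80))
        before = bv_tv(mmask(m), roi).bv_tv
        dilated = ndi.binary_dilation(m, np.ones((3, 3), bool))
        assert bv_tv(mmask(dilated), roi).bv_tv >= before

    def test_empty_roi_raises(self):
        mask = mmask(np.ones((10, 10), bool))
        roi = ROISpec.from_rect("r", (10, 10), slice(0, 10), slice(0, 10))
        roi.mask[:] = False
        with pytest.raises(EmptyROIError):
            bv_tv(mask, roi)


class TestTrabecularThickness:
    def test_stripe_width_recovered(self):
        # 50 px stripes at 0.88 µm/px = 44 µm slabs
        m = np.zeros((200, 400), bool)
        for start in range(0, 400, 100):
            m[:, start : start + 50] = True
        mask = mmask(m)
        roi = ROISpec.from_rect("r", m.shape, slice(0, 200), slice(0, 400))
        assert trabecular_thickness(mask, roi) == pytest.approx(44.0, rel=0.05)

    def test_matches_brute_force_oracle_on_random_blobs(self):
        rng = np.random.default_rng(5)
        m = ndi.binary_closing(rng.random((60, 60)) < 0.45, np.ones((3, 3), bool))
        lt = local_thickness(m, pixel_size=1.0)
        oracle = brute_force_local_thickness(m)
        sel = m & (oracle > 0)
        assert lt[sel].mean() == pytest.approx(oracle[sel].mean(), rel=0.05)

    def test_filled_disc_diameter(self):
        h = w = 120
        rr, cc = np.ogrid[:h, :w]
        m = (rr - 60) ** 2 + (cc - 60) ** 2 <= 40**2  # diameter 80 px
        roi = ROISpec.from_rect("r", (h, w), slice(0, h), slice(0, w))
        assert trabecular_thickness(mmask(m, pixel_size=1.0), roi) == pytest.approx(80.0, rel=0.05)

    def test_single_pixel_is_one_pixel_thick(self):
        m = np.zeros((11, 11), bool)
        m[5, 5] = True
        roi = ROISpec.from_rect("r", (11, 11), slice(0, 11), slice(0, 11))
        assert trabecular_thickness(mmask(m, pixel_size=0.88), roi) == pytest.approx(0.88)

    def test_no_mineral_raises(self):
        roi = ROISpec.from_rect("r", (10, 10), slice(0, 10), slice(0, 10))
        with pytest.raises(EmptyPhaseError):
            trabecular_thickness(mmask(np.zeros((10, 10), bool)), roi)


class TestTrabecularNumber:
    def test_plate_model_values(self):
        assert trabecular_number(50.0, 44.0) == pytest.approx(11.36, abs=0.01)
        assert trabecular_number(0.0, 44.0) == 0.0
        assert trabecular_number(100.0, 1000.0) == pytest.approx(1.0)

    def test_zero_thickness_raises(self):
        with pytest.raises(ZeroDivisionError):
            trabecular_number(50.0, 0.0)


class TestGrowthPlate:
    def test_uniform_band_thickness(self):
        mask = banded_mask(band=(100, 150))  # 50 px at 0.88 µm/px
        res = growth_plate_thickness(mask, opening_radius=0)
        assert res.mean_thickness == pytest.approx(50 * 0.88, abs=0.88)
        assert res.n_valid_columns == 200

    def test_wedge_band_mean_matches_per_column_oracle(self):
        n_rows, n_cols, ps = 500, 200, 1.0
        widths = np.round(np.linspace(100, 200, n_cols)).astype(int)
        m = np.ones((n_rows, n_cols), bool)
        for c in range(n_cols):
            m[150 : 150 + widths[c], c] = False
        # the band is twice as wide on one side as the other, so allow
        # crossings well beyond the common (fully unmineralized) core
        res = growth_plate_thickness(mmask(m, ps), opening_radius=0, overhang_frac=1.2)
        # oracle: brute per-column scan of the constructed mask
        oracle = []
        for c in range(n_cols):
            col = m[:, c]
            gaps = np.nonzero(~col)[0]
            oracle.append(gaps.size * ps)
        assert res.mean_thickness == pytest.approx(np.mean(oracle), abs=ps)
        assert res.mean_thickness == pytest.approx(150.0, abs=1.5)

    def test_bridged_columns_excluded(self):
        mask = banded_mask(band=(100, 150))
        mask.mask[100:150, 0:10] = True  # bone bridge occluding some columns
        res = growth_plate_thickness(mask, opening_radius=0)
        assert res.n_valid_columns == 190
        assert res.mean_thickness == pytest.approx(50 * 0.88, abs=0.88)

    def test_no_band_raises(self):
        with pytest.raises(FrontNotFoundError):
            growth_plate_thickness(mmask(np.ones((100, 100), bool)))
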