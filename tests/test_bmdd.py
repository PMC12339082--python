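"""Bone mineralization density distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osteoquant.bmdd import (
    BMDDCurve,
    bmdd_params,
    ca_low_high,
    compute_bmdd,
    reference_percentiles,
)
from osteoquant.calibration import CaMap
from osteoquant.errors import BinningError, EmptyCurveError, EmptyRegionError


def camap_from(values, pixel_size=1.0) -> CaMap:
    return CaMap(values=np.atleast_2d(np.asarray(values, dtype=float)), pixel_size=pixel_size)


def curve_from_freqs(freqs, bin_width=1.0, first_center=None) -> BMDDCurve:
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum() * 100.0
    if first_center is None:
        first_center = bin_width / 2.0
    centers = first_center + np.arange(freqs.size) * bin_width
    return BMDDCurve(bin_centers=centers, frequencies=freqs, bin_width=bin_width, n_pixels=1000)


class TestComputeBmdd:
    def test_constant_input_single_bin(self):
        curve = compute_bmdd(camap_from(np.full((10, 10), 22.1)))
        assert (curve.frequencies > 0).sum() == 1
        k = np.argmax(curve.frequencies)
        assert curve.lower_edges[k] <= 22.1 < curve.upper_edges[k]
        assert curve.frequencies[k] == pytest.approx(100.0)

    def test_symmetric_two_point_input(self):
        vals = np.array([[20.0] * 50 + [24.0] * 50])
        curve = compute_bmdd(camap_from(vals))
        nz = curve.frequencies[curve.frequencies > 0]
        assert nz.size == 2
        assert np.allclose(nz, 50.0)

    def test_histogram_ignores_pixel_arrangement(self, rng):
        vals = rng.uniform(6, 30, size=(50, 50))
        shuffled = rng.permutation(vals.ravel()).reshape(50, 50)
        a = compute_bmdd(camap_from(vals))
        b = compute_bmdd(camap_from(shuffled))
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_threshold_excludes_unmineralized(self):
        vals = np.array([[3.0] * 30 + [20.0] * 10])
        curve = compute_bmdd(camap_from(vals), threshold=5.2)
        assert curve.n_pixels == 10

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            compute_bmdd(camap_from(np.full((5, 5), 1.0)), threshold=5.2)

    def test_quantized_values_on_bin_edges_stay_in_one_bin(self):
        # gray-level-quantized Ca lands on exact multiples of the bin width;
        # each level must fall into exactly one bin (no comb artifact)
        levels = np.repeat(np.arange(100, 120), 50) * 0.17
        curve = compute_bmdd(camap_from(levels[None, :]), bin_width=0.17)
        nz = curve.frequencies[curve.frequencies > 0]
        assert nz.size == 20
        assert np.allclose(nz, 5.0)


class TestBmddParams:
    def test_mean_of_two_equal_bins(self):
        vals = np.array([[20.0] * 50 + [24.0] * 50])
        params = bmdd_params(compute_bmdd(camap_from(vals)))
        assert params.ca_mean == pytest.approx(22.0, abs=0.51)  # bin-center resolution

    def test_gaussian_fwhm_matches_closed_form(self, rng):
        # FWHM of a Gaussian is 2*sqrt(2 ln 2)*sigma = 2.3548*sigma
        vals = rng.normal(25.0, 1.5, size=(1000, 1000)).clip(6, 44)
        params = bmdd_params(compute_bmdd(camap_from(vals), bin_width=0.17))
        assert params.ca_mean == pytest.approx(25.0, abs=0.05)
        assert params.ca_width == pytest.approx(2.3548 * 1.5, rel=0.03)

    def test_tied_peaks_average(self):
        curve = curve_from_freqs([10, 0, 30, 0, 0, 0, 30, 0, 10], bin_width=1.0, first_center=20.0)
        params = bmdd_params(curve)
        assert params.ca_peak == pytest.approx((22.0 + 26.0) / 2.0)

    def test_single_bin_width_equals_bin_width(self):
        curve = curve_from_freqs([100.0], bin_width=0.17, first_center=22.185)
        assert bmdd_params(curve).ca_width == pytest.approx(0.17)

    def test_empty_curve_raises(self):
        curve = BMDDCurve(
            bin_centers=np.array([0.5, 1.5]),
            frequencies=np.zeros(2),
            bin_width=1.0,
            n_pixels=0,
        )
        with pytest.raises(EmptyCurveError):
            bmdd_params(curve)


class TestShiftEquivariance:
    @settings(deadline=None, max_examples=20)
    @given(shift_bins=st.integers(1, 50), seed=st.integers(0, 1000))
    def test_shifting_pixels_shifts_mean_and_peak(self, shift_bins, seed):
        # shift by an exact number of bins: the histogram translates rigidly
        w = 0.17
        shift = shift_bins * w
        rng = np.random.default_rng(seed)
        vals = rng.normal(20.0, 2.0, size=(40, 40)).clip(6, 30)
        base = bmdd_params(compute_bmdd(camap_from(vals)))
        moved = bmdd_params(compute_bmdd(camap_from(vals + shift)))
        assert moved.ca_mean - base.ca_mean == pytest.approx(shift, abs=w)
        assert moved.ca_peak - base.ca_peak == pytest.approx(shift, abs=w)
        assert moved.ca_width == pytest.approx(base.ca_width, abs=w)


class TestReferencePercentiles:
    def test_uniform_curve_closed_form(self):
        # uniform density over [20, 30): p5 = 20.5, p95 = 29.5
        curve = curve_from_freqs(np.ones(20), bin_width=0.5, first_center=20.25)
        ref = reference_percentiles([curve])
        assert ref.p5 == pytest.approx(20.5, abs=1e-9)
        assert ref.p95 == pytest.approx(29.5, abs=1e-9)

    def test_pooling_identical_curves_is_idempotent(self):
        curve = curve_from_freqs([5, 20, 50, 20, 5], bin_width=0.5, first_center=20.25)
        ref = reference_percentiles([curve, curve])
        assert np.allclose(ref.pooled_curve.frequencies, curve.frequencies)

    def test_disjoint_support_percentiles(self):
        lo = curve_from_freqs(np.ones(10), bin_width=1.0, first_center=10.5)  # [10,20)
        hi = curve_from_freqs(np.ones(10), bin_width=1.0, first_center=30.5)  # [30,40)
        ref = reference_percentiles([lo, hi])
        # cumulative-sum oracle: each curve carries 50% of pooled mass
        assert 10.0 < ref.p5 < 20.0
        assert 30.0 < ref.p95 < 40.0
        assert ref.p5 == pytest.approx(11.0, abs=1e-9)  # 5% of 100 = 10% into [10,20)
        assert ref.p95 == pytest.approx(39.0, abs=1e-9)

    def test_mismatched_binning_rejected(self):
        a = curve_from_freqs(np.ones(5), bin_width=0.5, first_center=20.25)
        b = curve_from_freqs(np.ones(5), bin_width=1.0, first_center=20.5)
        with pytest.raises(BinningError):
            reference_percentiles([a, b])


class TestCaLowHigh:
    def test_self_reference_identity(self):
        curve = curve_from_freqs([2, 10, 25, 30, 22, 8, 3], bin_width=0.5, first_center=20.25)
        ref = reference_percentiles([curve])
        lo, hi = ca_low_high(curve, ref)
        assert lo == pytest.approx(5.0, abs=0.5)
        assert hi == pytest.approx(5.0, abs=0.5)

    def test_curve_entirely_below_reference(self):
        ref_curve = curve_from_freqs(np.ones(10), bin_width=1.0, first_center=30.5)
        ref = reference_percentiles([ref_curve])
        low_curve = curve_from_freqs(np.ones(5), bin_width=1.0, first_center=10.5)
        lo, hi = ca_low_high(low_curve, ref)
        assert lo == pytest.approx(100.0)
        assert hi == pytest.approx(0.0)

    def test_upward_shift_moves_mass_across_percentiles(self):
        freqs = np.array([2, 10, 25, 30, 22, 8, 3], dtype=float)
        curve = curve_from_freqs(freqs, bin_width=0.5, first_center=20.25)
        ref = reference_percentiles([curve])
        shifted = curve_from_freqs(freqs, bin_width=0.5, first_center=20.75)
        lo0, hi0 = ca_low_high(curve, ref)
        lo1, hi1 = ca_low_high(shifted, ref)
        assert lo1 < lo0
        assert hi1 > hi0


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000), n=st.integers(5, 500))
def test_normalization_and_mean_bounds(seed, n):
    """Every computed curve sums to 100% and CaMean lies inside its support."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(5.3, 40.0, size=(1, n))
    curve = compute_bmdd(camap_from(vals))
    assert curve.frequencies.sum() == pytest.approx(100.0, abs=1e-9)
    params = bmdd_params(curve)
    assert curve.bin_centers[0] <= params.ca_mean <= curve.bin_centers[-1]
    assert curve.bin_centers[0] <= params.ca_peak <= curve.bin_centers[-1]
    assert params.ca_width >= curve.bin_width * (1 - 1e-9)
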