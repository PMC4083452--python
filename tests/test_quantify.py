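"""The ASL quantification chain, stage by stage and end to end."""

import numpy as np
import pytest

from aslrisk.errors import CalibrationError, DimensionError, FormatError
from aslrisk.quantify import (AcquisitionParams, ASLDataset, PerfusionMap,
                              QuantConfig, clamp_negative, coil_correction,
                              estimate_m0_blood, partial_volume_correct,
                              physiological_filter, quantify_cbf,
                              slice_ti2, smooth_map, surround_subtraction)

GRID = (4, 4, 20)


def _params(**kw):
    return AcquisitionParams(**kw)


def _dataset(series, params=None):
    grid = series.shape[:3]
    return ASLDataset(series=series, csf_scan=np.ones(grid),
                      min_contrast_scan=np.ones(grid),
                      params=params or _params(n_slices=grid[2]))


def _series(n_pairs, control, tag, grid=GRID):
    """Alternating series, tag first; control/tag may be per-frame callables."""
    frames = []
    for k in range(2 * n_pairs):
        value = tag(k) if k % 2 == 0 else control(k)
        frames.append(np.full(grid, value, dtype=float))
    return np.stack(frames, axis=-1)


class TestSurroundSubtraction:
    def test_constant_series_recovers_difference(self):
        series = _series(5, control=lambda k: 100.0, tag=lambda k: 100.0 - 7.0)
        assert np.allclose(surround_subtraction(_dataset(series)), 7.0)

    def test_null_perfusion_gives_zero(self):
        series = _series(4, control=lambda k: 55.0, tag=lambda k: 55.0)
        assert np.allclose(surround_subtraction(_dataset(series)), 0.0)

    def test_exact_under_linear_drift_where_pairwise_is_biased(self):
        """Surround subtraction cancels a linear drift exactly; simple
        pairwise control-minus-tag differencing is biased by the
        per-frame slope."""
        a, b, d = 200.0, 1.5, 6.0
        series = _series(6, control=lambda k: a + b * k,
                         tag=lambda k: a + b * k - d)
        dm = surround_subtraction(_dataset(series))
        assert np.allclose(dm, d, rtol=0, atol=1e-12)
        pairwise = (series[..., 1::2] - series[..., 0::2]).mean(axis=-1)
        assert abs(pairwise.mean() - (d + b)) < 1e-12   # biased estimator

    def test_rejects_single_pair(self):
        series = _series(1, control=lambda k: 1.0, tag=lambda k: 0.0)
        with pytest.raises(FormatError):
            surround_subtraction(_dataset(series))

    def test_odd_frame_count_rejected_at_dataset(self):
        series = np.zeros(GRID + (5,))
        with pytest.raises(FormatError):
            _dataset(series)


class TestSliceTiming:
    def test_first_slice_is_nominal_ti2(self):
        assert slice_ti2(_params(), 0) == 1600.0

    def test_arithmetic_and_degenerate(self):
        assert slice_ti2(_params(slice_time=50.0), 3) == 1750.0
        assert slice_ti2(_params(slice_time=0.0), 19) == 1600.0

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            slice_ti2(_params(), 20)


class TestM0Calibration:
    def test_uniform_and_single_voxel(self):
        cfg = QuantConfig(csf_to_blood_scale=1.06)
        scan = np.full((3, 3, 3), 200.0)
        assert estimate_m0_blood(scan, np.ones_like(scan, bool), cfg) == \
            pytest.approx(1.06 * 200.0)
        scan = np.zeros((3, 3, 3))
        mask = np.zeros_like(scan, bool)
        scan[1, 1, 1], mask[1, 1, 1] = 100.0, True
        assert estimate_m0_blood(scan, mask, cfg) == pytest.approx(106.0)

    def test_median_is_robust_to_outlier(self):
        cfg = QuantConfig(csf_to_blood_scale=1.0)
        scan = np.array([100.0, 100.0, 100.0, 10000.0]).reshape(4, 1, 1)
        mask = np.ones_like(scan, bool)
        m0 = estimate_m0_blood(scan, mask, cfg)
        assert m0 == pytest.approx(100.0)       # mean would give 2575
        assert abs(m0 - scan.mean()) > 1000

    def test_empty_mask_and_nonpositive(self):
        cfg = QuantConfig()
        scan = np.ones((2, 2, 2))
        with pytest.raises(CalibrationError):
            estimate_m0_blood(scan, np.zeros_like(scan, bool), cfg)
        with pytest.raises(CalibrationError):
            estimate_m0_blood(-scan, np.ones_like(scan, bool), cfg)


def _pmap(values, valid=None):
    cbf = np.asarray(values, dtype=float)
    valid = np.ones_like(cbf, bool) if valid is None else valid
    return PerfusionMap(cbf=cbf, valid=valid, stage="test")


class TestCoilCorrection:
    def test_flat_gain_of_any_level_is_identity(self):
        pmap = _pmap(np.arange(8.0).reshape(2, 2, 2) + 1)
        out = coil_correction(pmap, np.full((2, 2, 2), 2.0))
        assert np.allclose(out.cbf, pmap.cbf)

    def test_hot_voxel_is_scaled_down(self):
        pmap = _pmap(np.full((8, 1, 1), 10.0))
        gain = np.ones((8, 1, 1))
        gain[0] = 2.0
        out = coil_correction(pmap, gain)
        norm = gain / gain.mean()
        assert np.allclose(out.cbf, 10.0 / norm)
        assert out.cbf[0, 0, 0] < out.cbf[1, 0, 0]

    def test_zero_gain_invalidates_not_infinite(self):
        pmap = _pmap(np.full((4, 1, 1), 10.0))
        gain = np.ones((4, 1, 1))
        gain[2] = 0.0
        out = coil_correction(pmap, gain)
        assert not out.valid[2, 0, 0]
        assert np.isfinite(out.cbf).all()


class TestQuantifyCbf:
    def test_zero_dm_and_linearity(self):
        params, cfg = _params(), QuantConfig()
        zero = quantify_cbf(np.zeros(GRID), 1000.0, params, cfg)
        assert np.allclose(zero.cbf, 0.0)
        dm = np.random.default_rng(0).random(GRID)
        one = quantify_cbf(dm, 1000.0, params, cfg)
        two = quantify_cbf(2 * dm, 1000.0, params, cfg)
        assert np.allclose(two.cbf, 2 * one.cbf)
        # inverse linearity in M0b
        half_m0 = quantify_cbf(dm, 500.0, params, cfg)
        assert np.allclose(half_m0.cbf, 2 * one.cbf)

    def test_forward_inverse_round_trip_at_60(self):
        """A difference signal forward-modelled at f = 60 in every slice
        is inverted back to exactly 60, slice-specific TI2 included."""
        params, cfg = _params(), QuantConfig()
        f = 60.0
        ti2s = params.ti2 + params.slice_time * np.arange(params.n_slices)
        decay = np.exp(-ti2s / cfg.t1_blood)
        m0b = 1000.0
        dm = (2 * cfg.inversion_efficiency * m0b * (f / cfg.unit_conversion)
              * params.ti1 * decay)[np.newaxis, np.newaxis, :] * np.ones(GRID)
        out = quantify_cbf(dm, m0b, params, cfg)
        assert np.allclose(out.cbf, 60.0, rtol=1e-12)


class TestPartialVolumeCorrection:
    @pytest.mark.parametrize("uncorr,gm,wm,expected", [
        (60.0, 1.0, 0.0, 60.0),    # pure GM: identity
        (24.0, 0.0, 1.0, 60.0),    # pure WM: x2.5 (GM flow = 2.5x WM flow)
        (35.0, 0.5, 0.5, 50.0),    # mixed: 35 / (0.5 + 0.4*0.5)
    ])
    def test_formula(self, uncorr, gm, wm, expected):
        cfg = QuantConfig()
        out = partial_volume_correct(_pmap([[[uncorr]]]),
                                     np.array([[[gm]]]), np.array([[[wm]]]), cfg)
        assert out.cbf[0, 0, 0] == pytest.approx(expected)
        assert out.valid[0, 0, 0]

    def test_below_denominator_floor_is_invalidated(self):
        cfg = QuantConfig()
        out = partial_volume_correct(_pmap([[[40.0]]]),
                                     np.array([[[0.02]]]), np.array([[[0.1]]]), cfg)
        assert not out.valid[0, 0, 0]
        assert np.isfinite(out.cbf).all()

    def test_monotone_nonincreasing_in_gm(self):
        cfg = QuantConfig()
        gms = np.linspace(0.1, 1.0, 10)
        corrected = [partial_volume_correct(
            _pmap([[[30.0]]]), np.array([[[g]]]), np.array([[[0.2]]]),
            cfg).cbf[0, 0, 0] for g in gms]
        assert all(a >= b for a, b in zip(corrected, corrected[1:]))


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        pmap = _pmap(np.random.default_rng(1).random((6, 6, 6)))
        out = smooth_map(pmap, 0.0, 4.0)
        assert np.array_equal(out.cbf, pmap.cbf)

    def test_constant_region_preserved(self):
        pmap = _pmap(np.full((8, 8, 8), 42.0))
        out = smooth_map(pmap, 4.0, 4.0)
        assert np.allclose(out.cbf, 42.0, rtol=1e-12)

    def test_kernel_mass_conserved_on_impulse(self):
        cbf = np.zeros((15, 15, 15))
        cbf[7, 7, 7] = 1.0
        out = smooth_map(_pmap(cbf), 4.0, 4.0)
        assert out.cbf.sum() == pytest.approx(1.0, abs=1e-6)

    def test_invalid_voxels_do_not_bleed_in(self):
        cbf = np.full((9, 9, 9), 50.0)
        cbf[4, 4, 4] = 1e6
        valid = np.ones((9, 9, 9), bool)
        valid[4, 4, 4] = False
        out = smooth_map(PerfusionMap(cbf, valid, "t"), 4.0, 4.0)
        assert np.allclose(out.cbf[valid], 50.0)


class TestClampAndFilter:
    def test_clamp(self):
        out = clamp_negative(_pmap([[[-5.0, 0.0, 42.5]]]))
        assert out.cbf.tolist() == [[[0.0, 0.0, 42.5]]]

    def test_filter_boundaries_are_inclusive(self):
        cfg = QuantConfig()
        out = physiological_filter(_pmap([[[9.99, 10.0, 150.0, 150.01]]]), cfg)
        assert out.valid.ravel().tolist() == [False, True, True, False]

    def test_filter_trivial_cases_and_idempotence(self):
        cfg = QuantConfig()
        assert physiological_filter(_pmap(np.full((3, 3, 3), 60.0)), cfg).valid.all()
        assert not physiological_filter(_pmap(np.zeros((3, 3, 3))), cfg).valid.any()
        once = physiological_filter(_pmap([[[5.0, 60.0, 200.0]]]), cfg)
        twice = physiological_filter(once, cfg)
        assert np.array_equal(once.valid, twice.valid)
        assert np.array_equal(once.cbf, twice.cbf)


def test_processing_order_pvc_before_filter_is_pinned():
    """A voxel with uncorrected CBF 8 and tissue denominator 0.5 corrects
    to 16: it survives the physiological filter only because partial
    volume correction is applied first.  Filtering first would discard
    it, so this pins the stage order."""
    cfg = QuantConfig()
    gm, wm = np.array([[[0.3]]]), np.array([[[0.5]]])
    start = _pmap([[[8.0]]])
    pinned = physiological_filter(
        clamp_negative(partial_volume_correct(start, gm, wm, cfg)), cfg)
    assert pinned.valid[0, 0, 0]
    assert pinned.cbf[0, 0, 0] == pytest.approx(16.0)
    swapped = partial_volume_correct(
        clamp_negative(physiological_filter(start, cfg)), gm, wm, cfg)
    assert not swapped.valid[0, 0, 0]


def test_grid_mismatch_raises():
    with pytest.raises(DimensionError):
        ASLDataset(series=np.zeros((4, 4, 20, 4)), csf_scan=np.zeros((3, 3, 3)),
                   min_contrast_scan=np.zeros((4, 4, 20)), params=_params())
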