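from __future__ import annotations

import numpy as np
import pytest

from oracles import recompute_calibration
from xrh import new_volume
from xrh.calibrate import (
    MaterialLevels,
    apply_calibration,
    build_calibration,
    calibration_factor,
    contrast_factor,
    estimate_material_levels,
    stability_report,
)
from xrh.phantom import PhantomSpec, cylinder_masks, make_calibration_phantom


class TestContrastFactor:
    @pytest.mark.parametrize(
        "i_air,i_wax,expected",
        [
            (50.0, 100.0, 0.5),
            (0.0, 30419.0, 1.0),  # calibrated data: air at 0
            (25.0, 100.0, 0.75),
        ],
    )
    def test_direct_substitution(self, i_air, i_wax, expected):
        assert contrast_factor((i_air, i_wax)) == pytest.approx(expected)

    def test_zero_contrast(self):
        with pytest.warns(UserWarning, match="ordering"):
            assert contrast_factor((100.0, 100.0)) == 0.0

    def test_zero_wax_undefined(self):
        with pytest.raises(ValueError):
            contrast_factor((0.0, 0.0))

    def test_nonphysical_ordering_warns(self):
        with pytest.warns(UserWarning, match="ordering"):
            contrast_factor((200.0, 100.0))


class TestCalibrationFactor:
    def test_direct_substitution(self):
        assert calibration_factor(0.5, 0.25) == pytest.approx(2.0)

    @pytest.mark.parametrize("cf", [0.3, 0.75, 1.0])
    def test_self_calibration_identity(self, cf):
        assert calibration_factor(cf, cf) == 1.0

    def test_zero_sample_contrast_is_an_error(self):
        with pytest.raises(ValueError):
            calibration_factor(0.5, 0.0)


class TestEstimateMaterialLevels:
    def test_exact_two_valued_slice(self):
        data = np.full((3, 10, 10), 10.0, dtype=np.float32)
        data[:, :, 5:] = 200.0
        levels = estimate_material_levels(new_volume(data, 1.0))
        assert levels.i_air == pytest.approx(10.0)
        assert levels.i_wax == pytest.approx(200.0)

    def test_noisy_phantom_recovered_within_sampling_error(self):
        spec = PhantomSpec(
            shape=(16, 64, 64), gray_air=100.0, gray_wax=1000.0, gray_tissue=1100.0,
            noise_sigma=5.0, seed=7, calibration_state="preprocessed",
        )
        vol = make_calibration_phantom(spec)
        levels = estimate_material_levels(vol)
        wax, air = cylinder_masks(spec)
        n_air, n_wax = int(air[8].sum()), int(wax[8].sum())
        assert abs(levels.i_air - 100.0) < 3 * 5.0 / np.sqrt(n_air)
        assert abs(levels.i_wax - 1000.0) < 3 * 5.0 / np.sqrt(n_wax)

    def test_constant_slice_is_an_error(self):
        vol = new_volume(np.full((3, 8, 8), 5.0, dtype=np.float32), 1.0)
        with pytest.raises(ValueError, match="two material modes"):
            estimate_material_levels(vol)

    def test_roi_masks_give_exact_means(self, rng):
        data = rng.normal(500.0, 10.0, size=(4, 8, 8)).astype(np.float32)
        air = np.zeros(data.shape, dtype=bool)
        air[:, :4] = True
        wax = ~air
        data[air] -= 400.0
        vol = new_volume(data, 1.0)
        levels = estimate_material_levels(vol, method="roi_masks", masks={"air": air, "wax": wax})
        assert levels.i_air == pytest.approx(float(data[air].mean()))
        assert levels.i_wax == pytest.approx(float(data[wax].mean()))

    def test_empty_roi_mask_is_an_error(self):
        vol = new_volume(np.zeros((2, 4, 4), dtype=np.float32), 1.0)
        empty = np.zeros(vol.data.shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            estimate_material_levels(
                vol, method="roi_masks", masks={"air": empty, "wax": ~empty}
            )


def _two_material_volume(i_air, i_wax, dtype=np.float32):
    data = np.full((4, 8, 8), i_air, dtype=np.float64)
    data[:, :, 4:] = i_wax
    return new_volume(data.astype(dtype), 1.0, calibration_state="preprocessed")


class TestApplyCalibration:
    def test_self_calibration_shifts_air_to_zero_only(self):
        levels = MaterialLevels(50.0, 100.0)
        result = build_calibration(levels, levels)
        assert result.calibration_factor == 1.0
        vol = _two_material_volume(50.0, 100.0)
        out = apply_calibration(vol, result)
        # factor 1: values move by the air offset alone
        np.testing.assert_allclose(out.data, vol.data - 50.0, atol=1e-6)
        assert out.meta.calibration_state == "calibrated"

    def test_contrast_transfer_hand_derived(self):
        # phantom cf 0.75, sample (50, 100) -> k = 0.75/0.5 = 1.5,
        # calibrated air 0 and calibrated wax = cf_phantom * i_wax_sample = 75
        result = build_calibration(MaterialLevels(25.0, 100.0), MaterialLevels(50.0, 100.0))
        assert result.calibration_factor == pytest.approx(1.5)
        out = apply_calibration(_two_material_volume(50.0, 100.0), result)
        air_mean = float(out.data[:, :, :4].mean())
        wax_mean = float(out.data[:, :, 4:].mean())
        assert air_mean == pytest.approx(0.0, abs=1e-9)
        assert wax_mean == pytest.approx(0.75 * 100.0, abs=1e-9)

    def test_uint16_air_mean_zero_within_rounding(self):
        result = build_calibration(MaterialLevels(800.0, 24000.0), MaterialLevels(1200.0, 21000.0))
        vol = _two_material_volume(1200, 21000, dtype=np.uint16)
        out = apply_calibration(vol, result)
        assert out.data.dtype == np.uint16
        assert abs(float(out.data[:, :, :4].mean())) <= 0.5

    def test_already_calibrated_rejected(self):
        result = build_calibration(MaterialLevels(0.0, 10.0), MaterialLevels(0.0, 10.0))
        vol = new_volume(
            np.zeros((2, 2, 2), dtype=np.float32), 1.0, calibration_state="calibrated"
        )
        with pytest.raises(ValueError, match="already calibrated"):
            apply_calibration(vol, result)

    @pytest.mark.parametrize("scale", [0.5, 1.0, 3.0])
    def test_dual_route_against_equation_oracle(self, rng, scale):
        """Calibrated output equals a direct recomputation from the two
        equations, including for rescaled raw grays (the contrast factor is
        scale-invariant, so the output scales with the input)."""
        base = rng.normal(0, 1, size=(4, 8, 8))
        i_air_s, i_wax_s = 50.0 * scale, 100.0 * scale
        data = (np.where(base > 0, i_wax_s, i_air_s) + rng.normal(0, 2, base.shape)).astype(
            np.float32
        )
        vol = new_volume(data, 1.0, calibration_state="preprocessed")
        levels_s = MaterialLevels(i_air_s, i_wax_s)
        levels_p = MaterialLevels(20.0, 90.0)
        out = apply_calibration(vol, build_calibration(levels_p, levels_s))
        expected = recompute_calibration(data, 20.0, 90.0, i_air_s, i_wax_s)
        np.testing.assert_allclose(out.data, expected, atol=1e-3)


class TestStabilityReport:
    @staticmethod
    def _calibrated(mean, shape=(2, 4, 4)):
        return new_volume(
            np.full(shape, mean, dtype=np.float32), 1.0, calibration_state="calibrated"
        )

    def test_identical_volumes_have_zero_fluctuation(self):
        vols = [self._calibrated(30419.0) for _ in range(9)]
        masks = [np.ones((2, 4, 4), dtype=bool)] * 9
        report = stability_report(vols, wax_masks=masks)
        wax = report.materials["wax"]
        assert wax.sem == 0.0
        assert wax.max_pct_fluctuation == 0.0
        assert wax.grand_mean == pytest.approx(30419.0)

    def test_hand_computed_two_specimen_case(self):
        vols = [self._calibrated(100.0), self._calibrated(120.0)]
        masks = [np.ones((2, 4, 4), dtype=bool)] * 2
        report = stability_report(vols, wax_masks=masks)
        wax = report.materials["wax"]
        assert wax.grand_mean == pytest.approx(110.0)
        assert wax.max_pct_fluctuation == pytest.approx(100 * 10 / 110)
        assert wax.sem == pytest.approx(np.std([100, 120], ddof=1) / np.sqrt(2))

    def test_nine_stable_phantoms_stay_below_one_percent(self, rng):
        # specimen wax means drawn around 30419 with a sub-percent spread
        means = rng.normal(30419.0, 60.0, size=9)
        vols = [self._calibrated(m) for m in means]
        masks = [np.ones((2, 4, 4), dtype=bool)] * 9
        report = stability_report(vols, wax_masks=masks)
        assert report.materials["wax"].max_pct_fluctuation < 1.0

    def test_uncalibrated_or_single_volume_rejected(self):
        good = self._calibrated(10.0)
        with pytest.raises(ValueError, match="at least 2"):
            stability_report([good], wax_masks=[np.ones((2, 4, 4), bool)])
        raw = new_volume(np.zeros((2, 4, 4), dtype=np.float32), 1.0)
        with pytest.raises(ValueError, match="calibrated"):
            stability_report([good, raw], wax_masks=[np.ones((2, 4, 4), bool)] * 2)
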