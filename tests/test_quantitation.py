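"""Calibration fitting, detection limits, inverse prediction and verdicts."""

import numpy as np
import pytest

from tlcdens.datasets import load_published_calibration
from tlcdens.errors import (ConfigError, InsufficientDataError,
                            InvalidModelError, OutOfCalibrationError)
from tlcdens.quantitation import (CalibrationModel, QuantConfig, SampleResult,
                                  analyze_sample, content_verdict,
                                  fit_calibration, lod_loq, predict_conc,
                                  to_api_content)
from tlcdens.synthetic import build_assay_spec, render_plate


PUB = load_published_calibration().set_index("name")
S_PUB = float(PUB.loc["imagej", "slope"])          # 10701
B_PUB = float(PUB.loc["imagej", "intercept"])      # 7502


class TestFitCalibration:
    def test_exact_line_recovered(self):
        x = np.array([0.5, 1, 1.5, 2, 3, 4])
        m = fit_calibration(x, S_PUB * x + B_PUB)
        assert np.isclose(m.slope, S_PUB)
        assert np.isclose(m.intercept, B_PUB)
        assert m.sy == pytest.approx(0.0, abs=1e-8)
        assert m.r_squared == pytest.approx(1.0)
        assert m.linear_range == (0.5, 4.0)

    def test_duplicated_points_interpolate_with_zero_residual(self):
        m = fit_calibration([1, 1, 3, 3], [10, 10, 30, 30])
        assert np.isclose(m.slope, 10) and np.isclose(m.intercept, 0)
        assert m.sy == pytest.approx(0.0, abs=1e-10)

    def test_monte_carlo_slope_within_two_percent(self):
        rng = np.random.default_rng(314)
        x = np.linspace(0.5, 4, 6)
        slopes = [fit_calibration(x, 100 * x + 20 + rng.normal(0, 5, 6)).slope
                  for _ in range(500)]
        assert abs(np.mean(slopes) - 100) / 100 < 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([1, 2], [10, 20])

    def test_degenerate_concentrations_rejected(self):
        with pytest.raises(InvalidModelError):
            fit_calibration([2, 2, 2], [10, 11, 12])


class TestLodLoq:
    def test_zero_residual_gives_zero_limits(self):
        m = fit_calibration([1, 2, 3], [10, 20, 30])
        assert m.lod == 0.0 and m.loq == 0.0

    def test_ratio_fixed_at_10_over_3p3(self):
        m = CalibrationModel(slope=200.0, intercept=5.0, r_squared=0.99,
                             sy=12.0, n_points=6, linear_range=(0.5, 4))
        assert np.isclose(m.loq / m.lod, 10 / 3.3)
        assert np.isclose(m.lod, 3.3 * 12 / 200)

    def test_published_lod_round_trip(self):
        # back-solve the residual SD from the published LoD, then verify the
        # forward formula reproduces it
        lod_pub = float(PUB.loc["imagej", "lod_mg_ml"])     # 1.45
        sy = lod_pub * S_PUB / 3.3
        m = CalibrationModel(slope=S_PUB, intercept=B_PUB, r_squared=0.99,
                             sy=sy, n_points=6, linear_range=(0.5, 4))
        assert np.isclose(m.lod, lod_pub)

    def test_limits_scale_with_sy_over_slope(self):
        m1 = CalibrationModel(1000, 0, 0.99, 10, 6, (0.5, 4))
        m2 = CalibrationModel(1000, 0, 0.99, 20, 6, (0.5, 4))
        m3 = CalibrationModel(2000, 0, 0.99, 10, 6, (0.5, 4))
        assert np.isclose(m2.lod, 2 * m1.lod)
        assert np.isclose(m3.lod, m1.lod / 2)
        assert m1.lod < m1.loq

    def test_non_positive_slope_rejected(self):
        m = CalibrationModel(1000, 0, 0.99, 10, 6, (0.5, 4))
        m.slope = -5.0
        with pytest.raises(InvalidModelError):
            lod_loq(m)


class TestPredictConc:
    MODEL = CalibrationModel(S_PUB, B_PUB, 1.0, 0.0, 6, (0.0, 4.0))

    def test_intercept_maps_to_zero(self):
        assert predict_conc(self.MODEL, B_PUB) == 0.0

    def test_forward_inverse_round_trip(self):
        for c in (0.5, 1.2, 2.0, 4.0):
            assert np.isclose(predict_conc(self.MODEL, S_PUB * c + B_PUB), c)

    def test_out_of_range_warns_or_rejects(self):
        auc_high = S_PUB * 6 + B_PUB
        with pytest.warns(UserWarning, match="linear range"):
            assert np.isclose(predict_conc(self.MODEL, auc_high), 6.0)
        with pytest.raises(OutOfCalibrationError):
            predict_conc(self.MODEL, auc_high, policy="reject")

    def test_negative_estimate_clamped(self):
        with pytest.warns(UserWarning):
            assert predict_conc(self.MODEL, B_PUB - 100) == 0.0


class TestContentRules:
    CFG = QuantConfig()

    def test_dilution_factor_conversion(self):
        assert to_api_content(4.0, self.CFG) == 500.0
        assert to_api_content(3.31, self.CFG) == pytest.approx(413.75)
        assert to_api_content(0.0, self.CFG) == 0.0

    @pytest.mark.parametrize("api,ok", [
        (413.75, False),   # the flagged survey sample
        (479.02, True),
        (450.0, True),     # inclusive boundaries
        (550.0, True),
        (449.99, False),
        (550.01, False),
    ])
    def test_pharmacopeial_band(self, api, ok):
        assert content_verdict(api, self.CFG) is ok

    def test_verdict_consistency_enforced(self):
        with pytest.raises(ConfigError):
            SampleResult("x", 0.6, True, 4.0, 500.0, True, "substandard_content")


class TestAnalyzeSample:
    """End-to-end verdicts on rendered plates (ladder + one sample lane)."""

    LEVELS = [0.5, 1, 2, 3, 4]

    def _run(self, level, rf_true, seed):
        spec, _ = build_assay_spec(self.LEVELS, [level], sample_rf=[rf_true],
                                   noise_sd=0.005, seed=seed)
        img, _ = render_plate(spec)
        # calibrate from the same plate's ladder lanes
        from tlcdens.chromatography import assign_lanes, select_principal
        from tlcdens.pipeline import run_pipeline
        spots, stages = run_pipeline(img)
        lane_map = assign_lanes(
            spots, stages["plate"].pixels.shape[1] / (2 * len(spec.lanes)))
        groups = lane_map.lanes(spots)
        model = fit_calibration(
            self.LEVELS, [select_principal(g).auc for g in groups[:5]])
        return analyze_sample(img, model, standard_rf=0.604, sample_lane=5,
                              expected_lanes=len(spec.lanes))

    def test_nominal_sample_passes(self):
        res = self._run(4.0, 0.60, seed=21)
        assert res.verdict == "pass" and res.rf_ok and res.content_ok
        assert res.api_mg_per_tablet == pytest.approx(500, rel=0.05)

    def test_low_content_flagged_substandard(self):
        res = self._run(3.31, 0.604, seed=22)
        assert res.verdict == "substandard_content"
        assert res.rf_ok and not res.content_ok
        assert res.api_mg_per_tablet == pytest.approx(413.75, rel=0.05)

    def test_wrong_rf_is_identity_fail(self):
        res = self._run(4.0, 0.40, seed=23)
        assert res.verdict == "identity_fail" and not res.rf_ok

    def test_empty_plate_yields_identity_fail(self):
        from tlcdens.synthetic import SyntheticPlateSpec
        img, _ = render_plate(SyntheticPlateSpec(noise_sd=0.005, seed=5))
        model = CalibrationModel(S_PUB, B_PUB, 1.0, 0.0, 6, (0.0, 4.0))
        res = analyze_sample(img, model, standard_rf=0.604)
        assert res.verdict == "identity_fail"
        assert res.conc_mg_ml is None
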