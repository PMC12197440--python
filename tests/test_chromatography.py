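"""Retention factors, lane clustering, principal-spot selection, Rf identity."""

import numpy as np
import pytest

from tlcdens.chromatography import (assign_lanes, compute_rf, rf_match,
                                    select_principal)
from tlcdens.errors import EmptyLaneError, GeometryError, UndefinedStatError
from tlcdens.pipeline import Spot, run_pipeline
from tlcdens.synthetic import build_assay_spec, render_plate


def make_spot(row, col, auc=1.0, area=100):
    r, c = int(round(row)), int(round(col))
    return Spot(contour=np.array([[r, c]], float), centroid=(row, col),
                bbox=(r - 5, c - 5, r + 6, c + 6), area_px=area, auc=auc)


class TestComputeRf:
    def test_origin_is_zero_front_is_one(self):
        assert compute_rf(make_spot(399, 50), 399, 0).rf == 0.0
        assert compute_rf(make_spot(0, 50), 399, 0).rf == 1.0

    def test_reference_position_recovers_standard_value(self):
        # a spot at 60.4% of the origin -> front distance
        rf = compute_rf(make_spot(399 - 0.604 * 399, 50), 399, 0).rf
        assert np.isclose(rf, 0.604)

    def test_invariant_under_vertical_rescaling(self):
        for scale in (0.5, 2.0, 3.7):
            rf1 = compute_rf(make_spot(250.0, 10), 399, 0).rf
            rf2 = compute_rf(make_spot(250.0 * scale, 10), 399 * scale, 0).rf
            assert np.isclose(rf1, rf2)

    def test_centroid_outside_development_region_rejected(self):
        with pytest.raises(GeometryError):
            compute_rf(make_spot(450, 50), 399, 0)
        with pytest.raises(GeometryError):
            compute_rf(make_spot(10, 50), 399, 100)

    def test_detected_rf_matches_ground_truth(self):
        spec, _ = build_assay_spec([2.0], rf_true=0.604, noise_sd=0.005, seed=2)
        img, _ = render_plate(spec)
        spots, stages = run_pipeline(img)
        assert len(spots) == 1
        plate = stages["plate"]
        rf = compute_rf(spots[0], plate.origin_row, plate.front_row).rf
        assert abs(rf - 0.604) <= 0.02


class TestAssignLanes:
    def test_gap_clustering(self):
        spots = [make_spot(100, c) for c in (50, 52, 150, 250)]
        lane_map = assign_lanes(spots, gap_threshold=40)
        assert len(lane_map.lane_centers) == 3
        assert [spots[i].lane for i in range(4)] == [0, 0, 1, 2]

    def test_all_close_columns_one_lane(self):
        spots = [make_spot(100, c) for c in (50, 60, 70)]
        assert len(assign_lanes(spots, gap_threshold=15).lane_centers) == 1

    def test_single_spot_single_lane(self):
        assert len(assign_lanes([make_spot(10, 10)], 5).lane_centers) == 1

    def test_lane_centers_strictly_increasing(self):
        spots = [make_spot(100, c) for c in (250, 50, 150)]
        centers = assign_lanes(spots, 40).lane_centers
        assert centers == sorted(centers) and len(set(centers)) == len(centers)

    def test_recovers_synthetic_lane_count(self):
        spec, lanes = build_assay_spec([0.5, 1, 2, 3, 4], [2.0],
                                       noise_sd=0.005, seed=9)
        img, _ = render_plate(spec)
        spots, stages = run_pipeline(img)
        n = len(spec.lanes)
        lane_map = assign_lanes(spots, stages["plate"].pixels.shape[1] / (2 * n))
        assert len(lane_map.lane_centers) == n

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyLaneError):
            assign_lanes([], 10)


class TestSelectPrincipal:
    def test_single_spot_returns_itself(self):
        s = make_spot(10, 10)
        assert select_principal([s]) is s

    def test_largest_auc_wins(self):
        a, b = make_spot(10, 10, auc=120), make_spot(20, 10, auc=300)
        assert select_principal([a, b]) is b

    def test_ties_broken_by_area_then_row(self):
        a = make_spot(100, 10, auc=10, area=50)
        b = make_spot(100, 30, auc=10, area=80)
        assert select_principal([a, b]) is b
        c = make_spot(50, 10, auc=10, area=80)   # nearer the front
        assert select_principal([b, c]) is c

    def test_principal_vs_faint_satellite(self):
        from tlcdens.synthetic import SyntheticPlateSpec, LaneSpec, SpotSpec
        spec = SyntheticPlateSpec(
            width=120, height=400, noise_sd=0.005, seed=3,
            lanes=(LaneSpec(60, (SpotSpec(0.6, 0.5, 6.0),
                                 SpotSpec(0.3, 0.1, 6.0))),))
        img, manifest = render_plate(spec)
        spots, stages = run_pipeline(img)
        assert len(spots) == 2
        principal = select_principal(spots)
        truth = manifest.spots.loc[manifest.spots.amplitude.idxmax()]
        assert abs(principal.centroid[0] - truth.row) <= 1.0

    def test_empty_lane_rejected(self):
        with pytest.raises(EmptyLaneError):
            select_principal([])


class TestRfMatch:
    @pytest.mark.parametrize("sample,expected", [
        (0.58, True),    # 4.0% relative deviation
        (0.54, False),   # 10.6% relative deviation
        (0.604, True),   # exact match
    ])
    def test_ten_percent_relative_rule(self, sample, expected):
        assert rf_match(sample, 0.604) is expected

    def test_boundary_is_inclusive(self):
        # 0.625 vs 0.5 is exactly 25% relative deviation (exact in binary)
        assert rf_match(0.625, 0.5, tolerance_frac=0.25)

    def test_monotone_in_tolerance(self):
        assert not rf_match(0.54, 0.604, 0.10)
        assert rf_match(0.54, 0.604, 0.15)

    def test_zero_standard_rejected(self):
        with pytest.raises(UndefinedStatError):
            rf_match(0.5, 0.0)
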