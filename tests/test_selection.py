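import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedsqi import (
    SeedRecord,
    calibrate_dual,
    calibrate_single,
    cross_validate,
    select_dual,
    select_single,
    selection_stats,
)


def records_from_values(values, truth_sound, pixels=None):
    out = []
    for i, (v, ok) in enumerate(zip(values, truth_sound)):
        out.append(
            SeedRecord(
                seed_id=i + 1,
                sqi_areal=float(v),
                truth_class="sound" if ok else "shibudane",
                sqi_pixels=None if pixels is None else np.asarray(pixels[i], float),
            )
        )
    return out


class TestSelectionStats:
    def test_near_perfect_lot(self):
        # 180 seeds, 120 sound; 120 recovered of which 119 sound
        truth = [True] * 120 + [False] * 60
        selected = [True] * 119 + [False] + [True] + [False] * 59
        stats = selection_stats(truth, selected)
        assert stats.sr == pytest.approx(119 / 120)
        assert stats.yr == pytest.approx(119 / 120)
        assert stats.ter == pytest.approx(2 / 180)
        assert round(100 * stats.ter, 1) == 1.1

    def test_sparse_sound_lot(self):
        # 180 seeds, 31 sound; 29 recovered of which 27 sound
        truth = [True] * 31 + [False] * 149
        selected = [True] * 27 + [False] * 4 + [True] * 2 + [False] * 147
        stats = selection_stats(truth, selected)
        assert stats.ter == pytest.approx(6 / 180)
        assert stats.sr == pytest.approx(27 / 29)
        assert stats.yr == pytest.approx(27 / 31)
        assert round(100 * stats.ter, 1) == 3.3

    def test_empty_selection_degenerate(self):
        stats = selection_stats([True, False, True], [False, False, False])
        assert stats.rr == 0.0
        assert stats.sr is None  # undefined, not zero
        assert stats.ter == pytest.approx(2 / 3)

    def test_perfect_selection(self):
        truth = [True, False, True, False]
        stats = selection_stats(truth, truth)
        assert stats.ter == 0.0
        assert stats.sr == 1.0 and stats.yr == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            selection_stats([True], [True, False])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_identities(self, flags):
        truth = [t for t, _ in flags]
        selected = [s for _, s in flags]
        stats = selection_stats(truth, selected)
        # TER numerator is the integer misclassification count
        assert stats.misclassified == sum(t != s for t, s in flags)
        assert stats.ter * stats.N == pytest.approx(stats.misclassified)
        if stats.sr is not None and stats.yr is not None:
            # RR*SR == YR*SR_init (both equal N_get|OK / N)
            assert stats.rr * stats.sr == pytest.approx(stats.yr * stats.sr_init)


class TestSelectionRules:
    def test_single_is_strict_at_boundary(self):
        records = records_from_values([100.0, 122.0, 150.0], [True, True, False])
        np.testing.assert_array_equal(select_single(records, 122.0), [True, False, False])

    def test_single_extremes(self):
        records = records_from_values([100.0, 250.0], [True, False])
        assert select_single(records, 360.0).all()
        assert not select_single(records, 1e-9).any()

    def test_dual_is_strict_at_boundary(self):
        pixels = [[10.0] * 10 + [300.0] * 90,
                  [10.0] * 27 + [300.0] * 73,
                  [10.0] * 40 + [300.0] * 60]
        records = records_from_values([90.0] * 3, [False, True, True], pixels=pixels)
        np.testing.assert_array_equal(select_dual(records, 100.0, 0.27), [False, False, True])

    def test_dual_extremes(self):
        pixels = [[10.0, 300.0], [300.0, 300.0]]
        records = records_from_values([90.0, 200.0], [True, False], pixels=pixels)
        np.testing.assert_array_equal(select_dual(records, 100.0, 0.0), [True, False])
        assert not select_dual(records, 100.0, 1.0).any()


def brute_force_threshold_optimum(values, truth):
    """Independent oracle: try a threshold below, between, and above every
    pair of consecutive sorted values; return the minimum misclassifications."""
    values = np.asarray(values, float)
    truth = np.asarray(truth, bool)
    points = np.unique(values)
    candidates = np.concatenate([[points[0] - 1], points, points + 1e-9, [points[-1] + 1]])
    best = None
    for c in candidates:
        selected = values < c
        err = int((selected != truth).sum())
        best = err if best is None else min(best, err)
    return best


class TestCalibrateSingle:
    def test_separable_lot_zero_ter(self):
        records = records_from_values(
            [100.0, 110.0, 120.0, 130.0, 140.0], [True, True, True, False, False]
        )
        result = calibrate_single(records)
        assert result.min_ter == 0.0
        assert result.chosen_params == (125.0,)
        assert all(120.0 < p[0] <= 130.0 for p in result.optimal_params)

    def test_inseparable_lot(self):
        records = records_from_values([100.0, 130.0, 120.0], [True, True, False])
        result = calibrate_single(records)
        assert result.min_ter == pytest.approx(1 / 3)
        assert brute_force_threshold_optimum([100.0, 130.0, 120.0], [True, True, False]) == 1

    def test_all_sound_threshold_above_maximum(self):
        with pytest.warns(UserWarning, match="one truth class"):
            result = calibrate_single(
                records_from_values([100.0, 120.0], [True, True])
            )
        assert result.min_ter == 0.0
        assert result.chosen_params[0] > 120.0

    def test_matches_brute_force_over_all_label_assignments(self):
        # every truth assignment of lots up to 6 seeds with fixed SQI values
        rng = np.random.default_rng(2)
        for n in range(1, 7):
            values = np.round(rng.uniform(20, 340, n), 1)
            for assignment in itertools.product([False, True], repeat=n):
                records = records_from_values(values, assignment)
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    result = calibrate_single(records)
                oracle = brute_force_threshold_optimum(values, assignment)
                assert result.min_ter * n == pytest.approx(oracle)

    def test_unlabelled_records_rejected(self):
        records = records_from_values([100.0], [True])
        records[0].truth_class = "unknown"
        with pytest.raises(ValueError, match="truth"):
            calibrate_single(records)


class TestCalibrateDual:
    def toy_lot(self):
        rng = np.random.default_rng(9)
        pixels, truth = [], []
        for i in range(5):
            sound = i % 2 == 0
            low = rng.uniform(20, 60, 30 if sound else 6)
            high = rng.uniform(150, 300, 10 if sound else 34)
            pixels.append(np.concatenate([low, high]))
            truth.append(sound)
        records = records_from_values([100.0] * 5, truth, pixels=pixels)
        return records, truth

    def test_grid_search_equals_double_loop_oracle(self):
        records, truth = self.toy_lot()
        result = calibrate_dual(records, sqi_step=5.0, pbr_step=0.05)

        lo = np.floor(min(r.sqi_pixels.min() for r in records))
        hi = np.ceil(max(r.sqi_pixels.max() for r in records))
        oracle_cells = []
        best = None
        for max_sqi in np.arange(lo, hi + 2.5, 5.0):
            for min_pbr in np.round(np.arange(0.0, 1.0001, 0.05), 10):
                selected = [np.mean(p < max_sqi) > min_pbr for p in (r.sqi_pixels for r in records)]
                err = selection_stats(truth, selected).misclassified
                oracle_cells.append(((float(max_sqi), float(min_pbr)), err))
                best = err if best is None else min(best, err)
        assert result.min_ter * 5 == pytest.approx(best)
        oracle_optima = sorted(cell for cell, err in oracle_cells if err == best)
        assert sorted(result.optimal_params) == oracle_optima
        assert result.chosen_params in result.optimal_params

    def test_separable_lot_reproduces_truth(self):
        records, truth = self.toy_lot()
        result = calibrate_dual(records)
        assert result.min_ter == 0.0
        selected = select_dual(records, *result.chosen_params)
        np.testing.assert_array_equal(selected, truth)

    def test_single_sound_seed(self):
        records = records_from_values([50.0], [True], pixels=[[10.0, 20.0, 30.0]])
        with pytest.warns(UserWarning, match="one truth class"):
            result = calibrate_dual(records)
        assert result.min_ter == 0.0

    def test_missing_pixel_maps_rejected(self):
        records = records_from_values([50.0, 60.0], [True, False])
        with pytest.raises(ValueError, match="SQI_pixel"):
            calibrate_dual(records)


class TestCrossValidate:
    def sj_like_lot(self):
        """180 seeds, 31 sound; under maxSQI 122 exactly 29 selected, 27 sound."""
        values, truth = [], []
        values += [100.0] * 27 + [150.0] * 4  # sound: 27 below, 4 above
        truth += [True] * 31
        values += [110.0] * 2 + [200.0] * 147  # unsound: 2 below, 147 above
        truth += [False] * 149
        return records_from_values(values, truth)

    def calib_lot_at_122(self):
        """Separable lot whose midpoint optimum lands exactly at 122.0."""
        values = [90.0, 100.0, 121.0, 123.0, 150.0]
        truth = [True, True, True, False, False]
        return records_from_values(values, truth)

    def test_transferred_threshold_validation_error(self):
        report = cross_validate(self.calib_lot_at_122(), self.sj_like_lot(), method="single")
        assert report["chosen_params"] == (122.0,)
        assert report["calibration_stats"].ter == 0.0
        stats = report["validation_stats"]
        assert stats.N_get == 29 and stats.N_get_OK == 27
        assert stats.ter == pytest.approx(6 / 180)
        assert round(100 * stats.ter, 1) == 3.3

    def test_identical_lots_give_equal_errors(self):
        lot = self.sj_like_lot()
        report = cross_validate(lot, self.sj_like_lot(), method="single")
        assert report["calibration_stats"].ter == report["validation_stats"].ter

    def test_swapping_lots_transposes_the_report(self):
        a, b = self.calib_lot_at_122(), self.sj_like_lot()
        fwd = cross_validate(a, b, method="single")
        rev = cross_validate(b, a, method="single")
        assert fwd["calibration_stats"].as_dict() != rev["calibration_stats"].as_dict()
        # calibrating on a lot is independent of which side it sits on
        again = cross_validate(a, b, method="single")
        assert again["chosen_params"] == fwd["chosen_params"]
        assert rev["validation_stats"].N == fwd["calibration_stats"].N


class TestSweepMonotonicity:
    def test_n_get_sr_yr_monotone_along_max_sqi_sweep(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(10, 350, 40)
        truth = values < rng.uniform(100, 250)
        records = records_from_values(values, truth)
        sweep = np.linspace(0, 360, 200)
        n_get, sr, yr = [], [], []
        for t in sweep:
            stats = selection_stats(truth, select_single(records, t))
            n_get.append(stats.N_get)
            sr.append(stats.sr)
            yr.append(stats.yr)
        assert all(b >= a for a, b in zip(n_get, n_get[1:]))
        defined = [s for s in sr if s is not None]
        assert all(b <= a + 1e-12 for a, b in zip(defined, defined[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(yr, yr[1:]))
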