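"""Constant/non-constant clustering methods and the band post-processor."""

import re

import numpy as np
import pytest

from gaitphase.clustering import (
    METHOD_NAMES,
    cluster_bout,
    crop_labels,
    normalize_bout,
    postprocess_labels,
    split_into_bouts,
    threshold_labels,
)
from gaitphase.core import ParameterError


class TestBouts:
    def test_straight_runs_between_turns(self):
        bouts = split_into_bouts(6, [False, False, True, True, False, False])
        assert [b.stride_indices for b in bouts] == [[0, 1], [4, 5]]

    def test_no_turning_gives_one_bout(self):
        bouts = split_into_bouts(5, [False] * 5)
        assert len(bouts) == 1 and len(bouts[0]) == 5

    def test_synthetic_schedule_gives_four_bouts(self, ramp_schedule):
        flags = [p == "turning" for p in ramp_schedule.phases]
        assert len(split_into_bouts(len(flags), flags)) == 4


class TestNormalize:
    def test_divide_by_mean(self):
        np.testing.assert_allclose(normalize_bout([1, 2, 3]), [0.5, 1.0, 1.5])

    def test_constant_bout_normalizes_to_ones(self):
        np.testing.assert_allclose(normalize_bout([2.2] * 4), np.ones(4))

    def test_output_mean_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.5, 2.0, rng.integers(3, 30))
            assert np.mean(normalize_bout(v)) == pytest.approx(1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ParameterError):
            normalize_bout([-1.0, 1.0])


class TestCrop:
    def test_quarter_crop_of_twenty(self):
        nc = crop_labels(20, 25)
        assert nc[:5].all() and nc[-5:].all() and not nc[5:15].any()

    def test_half_up_rounding_can_crop_nothing(self):
        assert not crop_labels(9, 5).any()  # round(0.45) = 0

    def test_ten_strides_ten_percent(self):
        nc = crop_labels(10, 10)
        assert nc.tolist() == [True] + [False] * 8 + [True]

    def test_overlapping_crops_mark_everything(self):
        assert crop_labels(3, 25).sum() == 2  # k=1 each end
        assert crop_labels(2, 50).all()

    def test_empty_bout_rejected(self):
        with pytest.raises(ParameterError):
            crop_labels(0, 10)


class TestThresholdMethods:
    def test_median_flags_values_outside_five_percent(self):
        _, nc = threshold_labels([1.0, 1.02, 0.90], "median")
        assert nc.tolist() == [False, False, True]

    def test_distr_flags_ramp_ends(self):
        # bout shaped like the velocity profile: ramp up, plateau, ramp down
        values = np.array([0.7, 0.93, 1.17, 1.4, 1.4, 1.4, 1.4, 1.17, 0.93, 0.7])
        _, nc = threshold_labels(values, "distr")
        assert nc[0] and nc[-1]
        assert not nc[3:7].any()

    def test_kmeans_point_masses(self):
        values = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3], dtype=float)
        pair, nc = threshold_labels(values, "kmeans3", seed=0)
        mean = values.mean()
        assert pair.lower * mean == pytest.approx(1.0)
        assert pair.upper * mean == pytest.approx(3.0)
        # strict inequalities: only the middle cluster stays constant
        assert np.flatnonzero(~nc).tolist() == [3, 4, 5]

    def test_kmeans_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.5, 1.5, 25)
        a = threshold_labels(values, "kmeans3", seed=3)
        b = threshold_labels(values, "kmeans3", seed=3)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_kmeans_recovers_trimodal_centers(self):
        rng = np.random.default_rng(0)
        true_centers = np.array([0.7, 1.0, 1.3])
        values = np.concatenate([rng.normal(c, 0.01, 25) for c in true_centers])
        pair, _ = threshold_labels(values, "kmeans3", seed=1)
        mean = values.mean()
        assert pair.lower * mean == pytest.approx(0.7, rel=0.01)
        assert pair.upper * mean == pytest.approx(1.3, rel=0.01)

    def test_percentile_linear_interpolation(self):
        values = np.arange(1, 9, dtype=float)
        pair, nc = threshold_labels(values, "percentile")
        mean = values.mean()
        assert pair.lower * mean == pytest.approx(2.75)
        assert pair.upper * mean == pytest.approx(6.25)
        assert values[~nc].tolist() == [3, 4, 5, 6]

    def test_median_and_percentile_match_sorting_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            v = rng.uniform(0.4, 2.0, rng.integers(3, 40))
            pair, _ = threshold_labels(v, "median")
            s = np.sort(v)
            n = len(s)
            med = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
            assert (pair.lower, pair.upper) == (0.95, 1.05) and med == np.median(v)
            pair, _ = threshold_labels(v, "percentile")
            norm = np.sort(v / v.mean())
            for q, got in ((0.25, pair.lower), (0.75, pair.upper)):
                pos = q * (n - 1)
                lo = int(np.floor(pos))
                frac = pos - lo
                want = norm[lo] + frac * (norm[min(lo + 1, n - 1)] - norm[lo])
                assert got == want

    def test_too_few_strides_rejected(self):
        with pytest.raises(ParameterError):
            threshold_labels([1.0, 1.1], "median")


class TestPostprocess:
    def test_worked_twelve_stride_example(self):
        raw = np.zeros(12, dtype=bool)
        raw[[0, 2, 9, 11]] = True
        labels = postprocess_labels(raw)
        assert list(labels[:3]) == ["acceleration"] * 3
        assert list(labels[3:9]) == ["constant"] * 6
        assert list(labels[9:]) == ["deceleration"] * 3

    def test_all_constant_stays_constant(self):
        labels = postprocess_labels(np.zeros(10, dtype=bool))
        assert all(l == "constant" for l in labels)

    def test_non_constant_outside_bands_is_erased(self):
        raw = np.zeros(12, dtype=bool)
        raw[5] = True
        assert all(l == "constant" for l in postprocess_labels(raw))

    def test_automaton_pattern_and_band_confinement(self):
        import math

        pattern = re.compile(r"^a*c*d*$")
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            raw = rng.random(n) < 0.4
            labels = postprocess_labels(raw)
            code = "".join({"acceleration": "a", "constant": "c", "deceleration": "d"}[l] for l in labels)
            assert pattern.match(code)
            band = math.ceil(0.25 * n)
            nc_idx = [i for i, l in enumerate(labels) if l != "constant"]
            assert all(i < band or i >= n - band for i in nc_idx)

    def test_reversal_swaps_acceleration_and_deceleration(self):
        rng = np.random.default_rng(2)
        swap = {"acceleration": "deceleration", "deceleration": "acceleration", "constant": "constant"}
        for _ in range(200):
            raw = rng.random(int(rng.integers(1, 30))) < 0.3
            fwd = postprocess_labels(raw)
            rev = postprocess_labels(raw[::-1])
            assert [swap[l] for l in fwd[::-1]] == list(rev)


class TestClusterBout:
    def test_crop_dispatch(self):
        labels = cluster_bout(np.ones(20), np.ones(20), "25%crop")
        assert list(labels[:5]) == ["acceleration"] * 5
        assert list(labels[5:15]) == ["constant"] * 10
        assert list(labels[15:]) == ["deceleration"] * 5

    def test_distr_vel_marks_ramp_as_non_constant(self):
        vel = np.array([0.7, 0.93, 1.17, 1.4, 1.4, 1.4, 1.4, 1.4, 1.17, 0.7])
        labels = cluster_bout(vel, np.ones_like(vel), "distr vel")
        assert labels[0] == "acceleration" and labels[-1] == "deceleration"
        assert all(l == "constant" for l in labels[3:8])

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            cluster_bout([1, 2, 3], [1, 1, 1], "magic")

    def test_all_nine_method_names_dispatch(self):
        rng = np.random.default_rng(3)
        vel = rng.uniform(0.9, 1.1, 16)
        times = rng.uniform(0.9, 1.1, 16)
        assert len(METHOD_NAMES) == 13  # 5 crops + 4 threshold methods x 2 parameters
        for name in METHOD_NAMES:
            labels = cluster_bout(vel, times, name, seed=0)
            assert len(labels) == 16

    def test_kmeans_method_deterministic(self):
        rng = np.random.default_rng(4)
        vel = rng.uniform(0.7, 1.4, 18)
        a = cluster_bout(vel, np.ones_like(vel), "3means vel", seed=9)
        b = cluster_bout(vel, np.ones_like(vel), "3means vel", seed=9)
        assert np.array_equal(a, b)

    def test_raw_mode_skips_band_enforcement(self):
        vel = np.ones(12)
        vel[5] = 3.0
        labels = cluster_bout(vel, np.ones_like(vel), "distr vel", postprocess=False)
        assert labels[5] != "constant"
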