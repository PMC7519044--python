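"""Feature operators against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitwomac as gw
from gaitwomac.errors import UndefinedStatisticError, ValidationError
from gaitwomac.operators import periodogram_cycle

PM = gw.default_phase_map(60)


def brute_force_acf_min(x):
    x = np.asarray(x, dtype=float)
    d = x - x.mean()
    denom = (d**2).sum()
    rs = []
    for k in range(1, x.size):
        rs.append(sum(d[t] * d[t + k] for t in range(x.size - k)) / denom)
    return min(rs)


def dtw_paths_bruteforce(a, b):
    """Enumerate every monotone boundary-aligned warping path explicitly."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestSummaryStatistics:
    def test_two_point_closed_form(self):
        out = gw.summary_statistics([3, 4])
        assert out["rms"] == pytest.approx(np.sqrt(12.5))
        assert out["max_minus_min"] == 1.0
        assert out["mean"] == 3.5
        assert "kurtosis" not in out  # needs length >= 4

    def test_constant_sequence(self):
        out = gw.summary_statistics([7.0] * 10, stats=["peak2rms", "sd", "variance"])
        assert out["peak2rms"] == 1.0
        assert out["sd"] == 0.0
        with pytest.raises(UndefinedStatisticError):
            gw.summary_statistics([7.0] * 10, stats=["kurtosis"])

    def test_zero_signal_peak2rms_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            gw.summary_statistics([0.0] * 10, stats=["peak2rms"])

    def test_alternating_sequence_moment_oracle(self):
        x = np.tile([-1.0, 1.0], 50)
        out = gw.summary_statistics(x)
        assert out["kurtosis"] == pytest.approx(1.0)
        assert out["rms"] == pytest.approx(1.0)
        assert out["peak2rms"] == pytest.approx(1.0)

    def test_nonexcess_kurtosis_of_gaussian_sample_near_three(self, rng):
        x = rng.standard_normal(200_00)
        assert gw.summary_statistics(x, stats=["kurtosis"])["kurtosis"] == pytest.approx(3.0, abs=0.1)

    @given(
        x=st.lists(st.floats(-50, 50), min_size=4, max_size=30),
        c=st.floats(min_value=0.1, max_value=20),
    )
    def test_scale_and_shift_invariances(self, x, c):
        x = np.asarray(x)
        if np.ptp(x) < 1e-3 or np.abs(x).max() < 1e-3:
            return
        base = gw.summary_statistics(x)
        scaled = gw.summary_statistics(c * x)
        assert scaled["peak2rms"] == pytest.approx(base["peak2rms"], rel=1e-9)
        assert scaled["kurtosis"] == pytest.approx(base["kurtosis"], rel=1e-9)
        assert scaled["rms"] == pytest.approx(c * base["rms"], rel=1e-9)
        assert scaled["sd"] == pytest.approx(c * base["sd"], rel=1e-9)
        shifted = gw.summary_statistics(x + 100.0)
        assert shifted["kurtosis"] == pytest.approx(base["kurtosis"], rel=1e-6)


class TestAreaUnderCurve:
    def test_constant_over_full_cycle(self):
        wf = gw.GaitWaveform("knee_power", np.full(101, 2.0))
        assert gw.area_under_curve(wf, "full", PM) == pytest.approx(200.0)

    def test_constant_over_half_open_stance(self):
        wf = gw.GaitWaveform("knee_power", np.ones(101))
        assert gw.area_under_curve(wf, "stance", PM) == pytest.approx(59.0)

    def test_sign_linearity(self, rng):
        wf = gw.GaitWaveform("knee_power", rng.normal(size=101))
        neg = gw.GaitWaveform("knee_power", -wf.values)
        for window in ("full", "stance", "mid_swing"):
            assert gw.area_under_curve(neg, window, PM) == pytest.approx(
                -gw.area_under_curve(wf, window, PM)
            )


class TestPhaseExtremum:
    def test_ramp_extrema(self):
        wf = gw.GaitWaveform("hip_power", np.arange(101, dtype=float))
        assert gw.phase_extremum(wf, "terminal_swing", PM, "max") == 100.0
        assert gw.phase_extremum(wf, "loading_response", PM, "min") == 0.0

    def test_sine_min_matches_direct_evaluation(self):
        x = np.sin(2 * np.pi * np.arange(101) / 100.0)
        wf = gw.GaitWaveform("hip_power", x)
        idx = PM.window_indices("mid_stance")
        assert gw.phase_extremum(wf, "mid_stance", PM, "min") == x[idx].min()

    def test_compound_window(self):
        x = -np.abs(np.arange(101) - 55.0)
        wf = gw.GaitWaveform("pelvic_obliquity_angle", x)
        assert gw.phase_extremum(wf, ("terminal_stance", "pre_swing"), PM, "min") == x[30:60].min()

    def test_invalid_which(self):
        wf = gw.GaitWaveform("hip_power", np.zeros(101))
        with pytest.raises(ValidationError):
            gw.phase_extremum(wf, "full", PM, "median")


class TestPSDFeatures:
    def test_pure_sinusoid_band_brackets_tone(self):
        t = np.arange(101)
        for k in (3, 7, 20):
            f0 = k / 101.0
            x = np.sin(2 * np.pi * k * t / 101.0)
            out = gw.psd_features(x)
            df = 1.0 / 101.0
            assert out["bandwidth_lower"] <= f0 <= out["bandwidth_upper"]
            assert out["occupied_bandwidth"] <= 2 * df

    def test_quadratic_scaling(self, rng):
        x = rng.normal(size=101)
        a = gw.psd_features(x)["psd_auc"]
        b = gw.psd_features(2 * x)["psd_auc"]
        assert b == pytest.approx(4 * a, rel=1e-9)

    def test_parseval_on_smooth_signals(self, rng):
        t = np.arange(101) / 101.0
        for _ in range(5):
            coefs = rng.normal(size=6)
            x = sum(
                c * f(2 * np.pi * (k + 1) * t)
                for c, (k, f) in zip(coefs, itertools.product(range(3), (np.sin, np.cos)))
            )
            auc = gw.psd_features(x)["psd_auc"]
            assert auc == pytest.approx(np.var(x), rel=1e-6)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            gw.psd_features(np.full(101, 3.0))

    def test_periodogram_rectangle_sum_equals_variance(self, rng):
        x = rng.normal(size=101)
        freqs, pxx = periodogram_cycle(x)
        df = freqs[1] - freqs[0]
        assert np.sum(pxx) * df == pytest.approx(np.var(x), rel=1e-9)


class TestAutocorrLowerBound:
    def test_two_point_formula(self):
        assert gw.autocorr_lower_bound([1.0, -1.0]) == pytest.approx(-0.5)

    def test_matches_bruteforce_oracle(self, rng):
        t = np.arange(101)
        x = np.sin(2 * np.pi * 2 * t / 101.0)
        assert gw.autocorr_lower_bound(x) == pytest.approx(brute_force_acf_min(x), abs=1e-9)
        y = rng.normal(size=40)
        assert gw.autocorr_lower_bound(y) == pytest.approx(brute_force_acf_min(y), abs=1e-9)

    @given(x=st.lists(st.floats(-10, 10), min_size=8, max_size=40))
    def test_bounded_in_minus_one_one(self, x):
        x = np.asarray(x)
        if np.ptp(x) == 0:
            return
        r = gw.autocorr_lower_bound(x)
        assert -1.0 - 1e-9 <= r <= 1.0

    def test_constant_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            gw.autocorr_lower_bound(np.ones(20))


class TestMidReferenceLevel:
    def test_clean_square_wave(self):
        assert gw.mid_reference_level(np.tile([0.0, 10.0], 50)) == pytest.approx(5.0)

    def test_constant_is_its_own_level(self):
        assert gw.mid_reference_level(np.full(8, 7.0)) == 7.0

    def test_noisy_two_level_histogram_oracle(self, rng):
        levels = np.where(rng.random(1000) < 0.5, -3.0, 5.0)
        x = levels + rng.uniform(-0.1, 0.1, 1000)
        assert gw.mid_reference_level(x) == pytest.approx(1.0, abs=0.1)


class TestDTW:
    def test_identical_sequences_zero(self, rng):
        x = rng.normal(size=30)
        assert gw.dtw_distance(x, x) == 0.0

    def test_monotone_repetition_absorbed(self):
        assert gw.dtw_distance([1, 2, 3], [1, 2, 3, 3]) == 0.0

    def test_exhaustive_two_by_two(self):
        assert gw.dtw_distance([0, 0], [1, 1]) == 2.0

    def test_matches_path_enumeration_on_short_sequences(self, rng):
        for _ in range(60):
            a = rng.integers(0, 3, rng.integers(1, 6)).astype(float)
            b = rng.integers(0, 3, rng.integers(1, 6)).astype(float)
            assert gw.dtw_distance(a, b) == pytest.approx(dtw_paths_bruteforce(a, b))

    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=6),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        d1 = gw.dtw_distance(np.array(a, float), np.array(b, float))
        d2 = gw.dtw_distance(np.array(b, float), np.array(a, float))
        assert d1 == pytest.approx(d2)
        assert d1 >= 0.0

    def test_stance_swing_distance_on_trial(self):
        x = np.ones(101)
        x[60:] = 2.0
        wf = gw.GaitWaveform("hip_power", x)
        # stance all 1 (60 samples), swing all 2 (41 samples): optimal path
        # cost is one unit per matched pair along the longer axis
        assert gw.dtw_stance_swing(wf, PM) == pytest.approx(60.0)

    def test_squared_cost_switch(self):
        assert gw.dtw_distance([0, 0], [2, 2], cost="squared") == 8.0
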