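"""ROI averaging, time-resolved fits, topographic maps, and fractional-area
latency."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import cumulative_trapezoid

from sgn400 import (TimecourseGeneratorSpec, draw_predictors,
                    fit_timepointwise, fit_topography, fractional_area_latency,
                    generate_timecourse, per_subject_latency_test, roi_average)


class TestRoiAverage:
    def test_mean_of_two_electrodes(self):
        eeg = pd.DataFrame({
            "subject": ["s0", "s0"], "word": ["w0", "w0"],
            "electrode": ["e1", "e2"], "time": [100.0, 100.0],
            "amplitude": [1.0, 3.0]})
        out = roi_average(eeg, ["e1", "e2"])
        assert len(out) == 1
        assert out["amplitude"].iloc[0] == 2.0

    def test_singleton_is_identity(self):
        eeg = pd.DataFrame({
            "subject": ["s0"], "word": ["w0"], "electrode": ["e1"],
            "time": [100.0], "amplitude": [1.7]})
        out = roi_average(eeg, ["e1"])
        assert out["amplitude"].iloc[0] == 1.7

    def test_matches_groupby_oracle(self, rng):
        n = 200
        eeg = pd.DataFrame({
            "subject": rng.choice(["s0", "s1"], n),
            "word": rng.choice(["w0", "w1", "w2"], n),
            "electrode": rng.choice(["e1", "e2", "e3"], n),
            "time": rng.choice([0.0, 50.0], n),
            "amplitude": rng.standard_normal(n)})
        eeg = eeg.drop_duplicates(["subject", "word", "electrode", "time"])
        out = roi_average(eeg, ["e1", "e3"])
        sub = eeg[eeg["electrode"].isin(["e1", "e3"])]
        for _, row in out.iterrows():
            mask = ((sub["subject"] == row["subject"])
                    & (sub["word"] == row["word"])
                    & (sub["time"] == row["time"]))
            assert np.isclose(row["amplitude"], sub.loc[mask, "amplitude"].mean())

    def test_empty_or_missing_electrodes(self):
        eeg = pd.DataFrame({"subject": [], "word": [], "electrode": [],
                            "time": [], "amplitude": []})
        with pytest.raises(ValueError):
            roi_average(eeg, [])
        with pytest.raises(ValueError):
            roi_average(eeg, ["nope"])


@pytest.fixture(scope="module")
def boxcar_data():
    spec = TimecourseGeneratorSpec(
        shape="boxcar", center=400.0, halfwidth=100.0, noise_sd=0.0,
        sd_subject=0.0, sd_word=0.0, n_subjects=6, n_words=40,
        times=np.arange(0.0, 651.0, 50.0), seed=21)
    eeg, trials, info = generate_timecourse(spec)
    return spec, eeg, trials, info


class TestTimepointwise:
    def test_boxcar_effect_localized(self, boxcar_data):
        spec, eeg, trials, _ = boxcar_data
        res = fit_timepointwise(eeg, trials, predictor="su", window=(0, 650))
        inside = np.abs(res.times - spec.center) <= spec.halfwidth
        assert (np.abs(res.beta[inside]) > 1e-6).all()
        np.testing.assert_allclose(res.beta[~inside], 0.0, atol=1e-8)

    def test_result_lengths_match_grid(self, boxcar_data):
        _, eeg, trials, _ = boxcar_data
        res = fit_timepointwise(eeg, trials, predictor="su", window=(100, 500))
        n_grid = ((np.arange(0.0, 651.0, 50.0) >= 100)
                  & (np.arange(0.0, 651.0, 50.0) <= 500)).sum()
        for arr in (res.beta, res.se, res.p, res.p_adj, res.mask):
            assert len(arr) == n_grid

    def test_empty_window_rejected(self, boxcar_data):
        _, eeg, trials, _ = boxcar_data
        with pytest.raises(ValueError):
            fit_timepointwise(eeg, trials, window=(9000, 9999))


class TestTopography:
    def test_window_count(self):
        spec = TimecourseGeneratorSpec(
            electrodes={"e1": 1.0}, noise_sd=0.3, n_subjects=4, n_words=20,
            times=np.arange(0.0, 601.0, 25.0), seed=5)
        eeg, trials, _ = generate_timecourse(spec)
        out = fit_topography(eeg, trials, predictor="su", window_width=50,
                             span=(0, 600))
        assert len(out) == 12

    def test_single_electrode_effect_localized(self):
        spec = TimecourseGeneratorSpec(
            shape="boxcar", center=425.0, halfwidth=75.0, noise_sd=0.0,
            electrodes={"on": 1.0, "off": 0.0}, sd_subject=0.0, sd_word=0.0,
            n_subjects=6, n_words=40, times=np.arange(0.0, 601.0, 25.0),
            seed=6)
        eeg, trials, _ = generate_timecourse(spec)
        out = fit_topography(eeg, trials, predictor="su", window_width=50,
                             span=(0, 600))
        hits = out[out["reject"]]
        assert len(hits) > 0
        assert (hits["electrode"] == "on").all()
        # rejected windows overlap the boxcar support [350, 500] ms
        assert (hits["win_end"] > 350.0).all()
        assert (hits["win_start"] <= 500.0).all()


class TestFractionalAreaLatency:
    def test_symmetric_triangle(self):
        t = np.arange(200.0, 601.0, 4.0)
        curve = np.clip(1.0 - np.abs(t - 400.0) / 150.0, 0.0, None)
        assert np.isclose(fractional_area_latency(t, curve), 400.0, atol=0.01)

    def test_constant_curve_gives_midpoint(self):
        t = np.arange(0.0, 601.0, 10.0)
        assert np.isclose(fractional_area_latency(t, np.ones_like(t)), 300.0)

    def test_matches_fine_grid_oracle(self, rng):
        t = np.arange(0.0, 651.0, 25.0)
        for _ in range(30):
            knots = rng.standard_normal(t.size)
            lat = fractional_area_latency(t, knots)
            fine = np.arange(0.0, 650.0001, 0.01)
            cfine = np.abs(np.interp(fine, t, knots))
            cum = cumulative_trapezoid(cfine, fine, initial=0.0)
            oracle = fine[np.searchsorted(cum, 0.5 * cum[-1])]
            assert abs(lat - oracle) <= 1.0

    def test_monotone_in_fraction(self, rng):
        t = np.arange(0.0, 501.0, 20.0)
        curve = rng.random(t.size) + 0.05
        lats = [fractional_area_latency(t, curve, fraction=f)
                for f in (0.2, 0.4, 0.6, 0.8)]
        assert all(a <= b for a, b in zip(lats, lats[1:]))

    def test_scale_invariance_and_reflection(self, rng):
        t = np.arange(0.0, 401.0, 10.0)
        curve = rng.random(t.size)
        lat = fractional_area_latency(t, curve)
        assert np.isclose(fractional_area_latency(t, 7.3 * curve), lat)
        lat_ref = fractional_area_latency(t, curve[::-1])
        assert np.isclose(lat_ref, t[0] + t[-1] - lat, atol=1e-6)

    def test_zero_area_is_error(self):
        t = np.arange(0.0, 101.0, 10.0)
        with pytest.raises(ValueError, match="area"):
            fractional_area_latency(t, np.zeros_like(t))


class TestPerSubjectLatencyTest:
    def test_identical_vectors(self):
        res = per_subject_latency_test([300.0, 400, 350], [300.0, 400, 350])
        assert res.t == 0.0 and res.p == 1.0

    def test_planted_shift_noise_free(self):
        b = np.linspace(300, 420, 12)
        res = per_subject_latency_test(b + 100.0, b)
        assert np.isclose(res.mean_a - res.mean_b, 100.0)
        assert res.p < 0.001

    def test_matches_paired_t_oracle(self, rng):
        a = 400 + 30 * rng.standard_normal(15)
        b = a - 20 + 25 * rng.standard_normal(15)
        res = per_subject_latency_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert np.isclose(res.t, t_oracle)

    def test_nan_subjects_excluded(self):
        a = [300.0, np.nan, 350, 390]
        b = [310.0, 320, 330, 400]
        res = per_subject_latency_test(a, b)
        assert res.n == 3 and res.excluded == 1
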