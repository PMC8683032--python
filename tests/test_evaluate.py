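import numpy as np
import pytest

from bprtool.evaluate import (
    Segment,
    TrialRecord,
    blink_rate_timecourse,
    classify_trials,
    compare_to_blink_free,
    discriminability,
    extract_segments,
    power_bootstrap,
    quantile_bpr_profiles,
    response_magnitudes,
)
from bprtool.model import SEGMENT_GRID
from bprtool.preprocess import BlinkTable
from bprtool.signal_io import EventTable

from conftest import make_trace


def flat_trace(duration, rate=100.0, level=0.0):
    return make_trace(np.full(int(duration * rate), level) + 3.0, rate=rate)


class TestExtractSegments:
    def test_close_blinks_not_isolated(self):
        trace = flat_trace(30.0)
        blinks = BlinkTable(onset=[10.0, 12.0], offset=[10.1, 12.1])
        segs = [s for s in extract_segments(trace, blinks) if s.kind == "blink_affected"]
        assert len(segs) == 2
        assert not segs[0].isolated and not segs[1].isolated
        assert segs[0].overlapping and segs[1].overlapping

    def test_interval_chunking_rule(self):
        # 13-s inter-blink interval: drop 3 s, then floor(10/3) = 3 chunks
        trace = flat_trace(40.0)
        blinks = BlinkTable(onset=[10.0, 23.5], offset=[10.5, 24.0])
        segs = extract_segments(trace, blinks, edge_exclusion=0.0)
        free = [s for s in segs if s.kind == "blink_free"]
        in_interval = [s for s in free if 10.5 <= s.anchor < 23.5]
        assert len(in_interval) == 3
        np.testing.assert_allclose(
            [s.anchor for s in in_interval], [13.5, 16.5, 19.5]
        )

    def test_isolated_blink_flagged(self):
        trace = flat_trace(30.0)
        blinks = BlinkTable(onset=[14.0], offset=[14.2])
        segs = [s for s in extract_segments(trace, blinks) if s.kind == "blink_affected"]
        assert len(segs) == 1 and segs[0].isolated

    def test_edge_exclusion_drops_boundary_segments(self):
        trace = flat_trace(20.0)
        blinks = BlinkTable(onset=[1.0], offset=[1.2])  # too close to the edge
        segs = [s for s in extract_segments(trace, blinks) if s.kind == "blink_affected"]
        assert len(segs) == 0


class TestClassifyTrials:
    def make(self, blink_trials, n=10):
        onsets = 2.0 * np.arange(n)
        trials = EventTable(onset=onsets, duration=np.full(n, 2.0),
                            condition=np.array(["c"] * n))
        b = np.array([onsets[k] + 0.3 for k in blink_trials])
        blinks = BlinkTable(onset=b, offset=b + 0.2)
        return trials, blinks

    def test_blink_in_one_back_marks_affected(self):
        trials, blinks = self.make([4])
        labels = classify_trials(trials, blinks)
        assert labels[5] == "blink_affected"

    def test_clean_history_marks_free(self):
        trials, blinks = self.make([0])
        labels = classify_trials(trials, blinks)
        assert labels[5] == "blink_free"

    def test_blink_three_back_is_free(self):
        trials, blinks = self.make([2])
        labels = classify_trials(trials, blinks)
        assert labels[5] == "blink_free"

    def test_first_two_trials_unlabeled(self):
        trials, blinks = self.make([])
        labels = classify_trials(trials, blinks)
        assert labels[0] is None and labels[1] is None

    def test_counts_match_brute_force_history_scan(self, rng):
        blink_trials = sorted(rng.choice(40, size=12, replace=False))
        trials, blinks = self.make(blink_trials, n=40)
        labels = classify_trials(trials, blinks)
        has = np.zeros(40, dtype=bool)
        has[list(blink_trials)] = True
        for i in range(2, 40):
            expected = "blink_affected" if has[i - 2 : i + 1].any() else "blink_free"
            assert labels[i] == expected


class TestBlinkRate:
    def trials(self, n=20, length=2.0):
        return EventTable(onset=length * np.arange(n),
                          duration=np.full(n, length),
                          condition=np.array(["c"] * n))

    def test_no_blinks_zero_rate(self):
        rate = blink_rate_timecourse(
            BlinkTable(onset=[], offset=[]), self.trials(), rate=100.0
        )
        np.testing.assert_array_equal(rate, 0.0)

    def test_fixed_latency_offset_pulse(self):
        trials = self.trials()
        offs = trials.onset + 1.0
        blinks = BlinkTable(onset=offs - 0.1, offset=offs)
        rate = blink_rate_timecourse(blinks, trials, rate=100.0, boxcar=0.1)
        t = np.arange(200) / 100.0
        at_latency = np.isclose(t, 1.0, atol=0.04)
        away = (t < 0.8) | (t > 1.2)
        assert rate[at_latency].max() == pytest.approx(10.0, rel=0.05)
        np.testing.assert_array_equal(rate[away], 0.0)

    def test_uniform_offsets_give_mean_rate(self, rng):
        n_trials, length = 400, 2.0
        trials = self.trials(n_trials, length)
        per_trial = 0.6
        lat = rng.uniform(0.0, length, size=int(n_trials * per_trial))
        which = rng.integers(0, n_trials, size=len(lat))
        offs = np.sort(trials.onset[which] + lat)
        offs = offs[np.diff(offs, prepend=-1) > 0.01]
        blinks = BlinkTable(onset=offs - 0.005, offset=offs)
        rate = blink_rate_timecourse(blinks, trials, rate=100.0)
        expected = len(offs) / (n_trials * length)
        assert rate.mean() == pytest.approx(expected, rel=0.05)


class TestResponseMagnitudes:
    def trials(self, n=10, length=2.0):
        return EventTable(onset=length * np.arange(1, n + 1),
                          duration=np.full(n, length),
                          condition=np.array(["c"] * n))

    def test_constant_trace_gives_zero_magnitudes(self):
        trace = flat_trace(30.0)
        recs = response_magnitudes(self.trials(), trace)
        assert all(r.magnitude == 0.0 for r in recs)

    def test_known_ramp_magnitude(self):
        rate = 100.0
        n = int(30 * rate)
        t = np.arange(n) / rate
        trials = self.trials()
        pupil = np.full(n, 3.0)
        for onset in trials.onset:
            w = (t >= onset) & (t < onset + 2.0)
            pupil[w] += 0.1 * (t[w] - onset)  # ramp, slope 0.1 mm/s
        trace = make_trace(pupil, rate=rate)
        recs = response_magnitudes(trials, trace, window={"fixed": (0.5, 2.0)})
        # analytic mean of the ramp over [0.5, 2): 0.1 * mean(t) over window
        expected = 0.1 * (0.5 + 2.0 - 1 / rate) / 2
        for r in recs:
            assert r.magnitude == pytest.approx(expected, abs=2e-3)

    def test_auto_window_matches_brute_force_threshold_scan(self):
        rate = 100.0
        n = int(40 * rate)
        t = np.arange(n) / rate
        trials = self.trials(n=12)
        pupil = np.full(n, 3.0)
        for onset in trials.onset:
            w = (t >= onset) & (t < onset + 2.0)
            rel = t[w] - onset
            pupil[w] += 0.2 * np.maximum(0, 1 - np.abs(rel - 1.2) / 0.8)
        trace = make_trace(pupil, rate=rate)
        recs = response_magnitudes(trials, trace, window={"auto_frac": 0.75})
        # oracle: rebuild courses, threshold the grand average by brute force
        courses = np.stack([
            pupil[int(o * rate): int(o * rate) + int(2 * rate)] for o in trials.onset
        ])
        courses = courses - courses[:, [0]]
        grand = courses.mean(axis=0)
        above = np.flatnonzero(grand >= 0.75 * grand.max())
        expected = courses[:, above[0]: above[-1] + 1].mean(axis=1)
        np.testing.assert_allclose([r.magnitude for r in recs], expected, atol=1e-12)

    def test_flat_grand_average_rejected_for_auto_window(self):
        trace = flat_trace(30.0)
        with pytest.raises(ValueError):
            response_magnitudes(self.trials(), trace, window={"auto_frac": 0.75})


class TestQuantileProfiles:
    def test_identical_segments_give_identical_quantiles(self):
        seg = -0.1 * np.exp(-((SEGMENT_GRID - 0.9) ** 2) / 0.3)
        segments = [seg.copy() for _ in range(25)]
        out = quantile_bpr_profiles({"stratum": segments}, smooth=False)
        for q in range(1, 5):
            np.testing.assert_allclose(out["profiles"][q], out["profiles"][0])

    def test_quantile_binning_matches_brute_force(self, rng):
        base = -np.exp(-((SEGMENT_GRID - 0.9) ** 2) / 0.3)
        amps = rng.uniform(0.02, 0.4, size=50)
        segments = [a * base for a in amps]
        out = quantile_bpr_profiles({"s": segments}, smooth=False)
        in_win = (SEGMENT_GRID >= 0.5) & (SEGMENT_GRID <= 1.2)
        seg_amps = np.array([s[in_win].min() for s in segments])
        order = np.argsort(seg_amps)
        bins = np.array_split(order, 5)
        for q, b in enumerate(bins):
            brute = np.mean([segments[i] for i in b], axis=0)
            np.testing.assert_allclose(out["profiles"][q], brute, atol=1e-10)
        ratio = out["profiles"][0].min() / out["profiles"][4].min()
        brute_ratio = (
            np.mean([segments[i] for i in bins[0]], axis=0).min()
            / np.mean([segments[i] for i in bins[4]], axis=0).min()
        )
        assert ratio == pytest.approx(brute_ratio, abs=1e-10)

    def test_trough_search_confined_to_window(self):
        # deepest dip outside 0.5-1.2 s must not drive the amplitude sort
        inside = -0.1 * np.exp(-((SEGMENT_GRID - 0.9) ** 2) / 0.05)
        outside = -0.5 * np.exp(-((SEGMENT_GRID - 2.4) ** 2) / 0.05)
        segments = [inside + 0.0 * outside, 0.5 * inside + outside]
        segments = segments * 5  # 10 segments
        out = quantile_bpr_profiles({"s": segments}, n_quantiles=2, smooth=False)
        in_win = (SEGMENT_GRID >= 0.5) & (SEGMENT_GRID <= 1.2)
        amps = [s[in_win].min() for s in segments]
        # the 'inside' segment is deeper within the window, so it defines Q1
        assert amps[0] < amps[1]
        np.testing.assert_allclose(out["profiles"][0], segments[0], atol=1e-12)

    def test_small_stratum_skipped_with_warning(self):
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                quantile_bpr_profiles({"s": [np.zeros(16)] * 3})


class TestCompareToBlinkFree:
    def test_identical_profiles_zero(self):
        assert compare_to_blink_free(np.ones(16), np.ones(16)) == 0.0

    def test_constant_offset(self):
        c = 0.37
        assert compare_to_blink_free(np.zeros(16), np.full(16, c)) == pytest.approx(4 * c)

    def test_matches_brute_force(self, rng):
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        brute = np.sqrt(np.sum((a - b) ** 2))
        assert compare_to_blink_free(a, b) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_to_blink_free(np.zeros(16), np.zeros(8))


class TestDiscriminability:
    def test_identical_samples_auc_half(self):
        x = np.array([1.0, 2.0, 3.0])
        assert discriminability(x, x)["AUC"] == 0.5

    def test_fully_separated_auc_one(self):
        out = discriminability([5.0, 6.0, 7.0], [1.0, 2.0])
        assert out["AUC"] == 1.0
        assert out["mean_diff"] == pytest.approx(4.5)

    def test_matches_mann_whitney_oracle(self, rng):
        a = rng.standard_normal(30) + 0.4
        b = rng.standard_normal(25)
        auc = discriminability(a, b)["AUC"]
        brute = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        ) / (len(a) * len(b))
        assert auc == pytest.approx(brute, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.standard_normal(30) + 0.5
        b = rng.standard_normal(30)
        auc1 = discriminability(a, b)["AUC"]
        f = lambda x: np.exp(2 * x) + 1  # strictly increasing
        auc2 = discriminability(f(a), f(b))["AUC"]
        assert auc1 == auc2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            discriminability([1.0], [2.0, 3.0])


def records_from(y, x, coding):
    inv = {v: k for k, v in coding.items()}
    return [TrialRecord(condition=inv[xi], blink_history=(), magnitude=yi)
            for yi, xi in zip(y, x)]


class TestPowerBootstrap:
    CODING = {"low": -0.5, "mid": 0.0, "high": 0.5}

    def test_type_one_error_calibrated(self, rng):
        """Zero effect: rejection fraction ~ alpha within 3 MC SDs."""
        x = np.tile([-0.5, 0.0, 0.5], 200)
        y = rng.standard_normal(600)
        # orthogonalize so the pool itself carries exactly zero slope;
        # otherwise the pool's chance correlation shifts every resample
        y = y - x * (x @ y) / (x @ x)
        recs = records_from(y, x, self.CODING)
        reps = 10_000
        out = power_bootstrap(recs, self.CODING, n_grid=[60], reps=reps,
                              alpha=0.01, seed=rng)
        frac = out["fraction_significant"][60]
        mc_sd = np.sqrt(0.01 * 0.99 / reps)
        assert abs(frac - 0.01) < 3 * mc_sd + 1e-3

    def test_huge_effect_saturates(self, rng):
        x = np.tile([-0.5, 0.5], 100)
        y = 10.0 * x + 0.01 * rng.standard_normal(200)
        recs = records_from(y, x, {"low": -0.5, "high": 0.5})
        out = power_bootstrap(recs, {"low": -0.5, "high": 0.5},
                              n_grid=[10], reps=500, seed=1)
        assert out["fraction_significant"][10] > 0.99

    def test_power_nondecreasing_in_n(self, rng):
        x = np.tile([-0.5, 0.0, 0.5], 200)
        y = 0.4 * x + rng.standard_normal(600)
        recs = records_from(y, x, self.CODING)
        reps = 2000
        out = power_bootstrap(recs, self.CODING, n_grid=[20, 80, 320],
                              reps=reps, seed=2)
        f = [out["fraction_significant"][n] for n in (20, 80, 320)]
        mc = 2 * np.sqrt(0.25 / reps)
        assert f[1] >= f[0] - mc and f[2] >= f[1] - mc

    def test_min_n_reported(self, rng):
        x = np.tile([-0.5, 0.5], 300)
        y = 1.0 * x + 0.5 * rng.standard_normal(600)
        recs = records_from(y, x, {"low": -0.5, "high": 0.5})
        out = power_bootstrap(recs, {"low": -0.5, "high": 0.5},
                              n_grid=[5, 20, 80], reps=1000, seed=3)
        assert out["min_n"] in (5, 20, 80)
        f = out["fraction_significant"]
        assert all(f[n] < 0.95 for n in (5, 20, 80) if n < out["min_n"])

    def test_single_condition_rejected(self):
        recs = records_from([1.0, 2.0], [0.5, 0.5], {"high": 0.5})
        with pytest.raises(ValueError):
            power_bootstrap(recs, {"high": 0.5}, n_grid=[2])
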