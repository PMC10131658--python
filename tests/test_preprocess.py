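"""Calibration, nonwear and AVM epoching."""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walkanchor import (
    CalibrationParams,
    TriaxialRecording,
    UsageError,
    autocalibrate,
    compute_avm,
    detect_nonwear,
    find_stationary_windows,
    reepoch,
)
from walkanchor.preprocess import AvmEpochSeries

from conftest import T0, make_recording, sinusoid_recording


def six_orientation_recording(offset=(0, 0, 0), gain=(1, 1, 1), noise=0.003,
                              seed=0, fs=50.0, per_s=30.0):
    """The classic calibration posture set: ±1 g on each axis in turn.

    The sensor's raw output is distorted so that offset + gain*raw equals
    the true acceleration.
    """
    rng = np.random.default_rng(seed)
    oris = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    n = int(per_s * fs)
    truth = np.concatenate([np.tile(o, (n, 1)) + rng.normal(0, noise, (n, 3))
                            for o in oris])
    raw = (truth - np.asarray(offset)) / np.asarray(gain)
    return make_recording(raw, fs=fs)


class TestStationaryWindows:
    def test_pure_gravity_all_windows(self, gravity_recording):
        wins = find_stationary_windows(gravity_recording)
        assert len(wins) == 6  # 60 s / 10 s windows
        for _, mean in wins:
            assert np.linalg.norm(mean) == pytest.approx(1.0, abs=1e-9)

    def test_continuous_motion_yields_none(self):
        rec = sinusoid_recording(0.1, freq_hz=1.0, duration_s=60)
        assert find_stationary_windows(rec, sd_threshold_g=0.013) == []

    def test_quiet_segments_found_within_one_window(self):
        rng = np.random.default_rng(2)
        fs, total = 50.0, 120.0
        t = np.arange(int(total * fs)) / fs
        samples = np.zeros((len(t), 3))
        samples[:, 2] = 1.0
        moving = (t >= 40) & (t < 80)
        samples[moving, 0] += 0.3 * np.sin(2 * np.pi * 1.3 * t[moving])
        samples += rng.normal(0, 0.002, samples.shape)
        wins = find_stationary_windows(make_recording(samples, fs=fs))
        starts = {s for s, _ in wins}
        # truth: [0,40) and [80,120) quiet; windows at 40..70 must be absent
        assert {0.0, 10.0, 20.0, 30.0, 80.0, 90.0, 100.0, 110.0} >= starts
        assert not starts & {50.0, 60.0}


class TestAutocalibrate:
    def test_already_calibrated_data_is_near_identity(self):
        cal = autocalibrate(six_orientation_recording())
        assert cal.calibrated
        assert np.all(np.abs(cal.offset) < 1e-3)
        assert np.all(np.abs(cal.gain - 1) < 1e-3)

    def test_recovers_injected_offset_and_gain(self):
        cal = autocalibrate(
            six_orientation_recording(offset=(0.05, -0.02, 0.0), gain=(1.03, 0.98, 1.0))
        )
        assert cal.calibrated
        np.testing.assert_allclose(cal.offset, [0.05, -0.02, 0.0], atol=0.005)
        np.testing.assert_allclose(cal.gain, [1.03, 0.98, 1.0], atol=0.005)

    def test_single_orientation_under_determined(self, gravity_recording):
        cal = autocalibrate(gravity_recording)
        assert not cal.calibrated
        np.testing.assert_array_equal(cal.offset, 0)
        np.testing.assert_array_equal(cal.gain, 1)

    def test_idempotent_within_tolerance(self):
        rec = six_orientation_recording(offset=(0.05, -0.02, 0.0), gain=(1.03, 0.98, 1.0))
        cal = autocalibrate(rec)
        again = autocalibrate(cal.apply(rec))
        assert np.all(np.abs(again.offset) < 1e-6)
        assert np.all(np.abs(again.gain - 1) < 1e-6)


class TestNonwear:
    def _active_day(self, still_spans, total_s=5 * 3600, fs=25.0, seed=3):
        """Movement everywhere except the given constant-orientation spans."""
        rng = np.random.default_rng(seed)
        t = np.arange(int(total_s * fs)) / fs
        samples = np.zeros((len(t), 3))
        samples[:, 2] = 1.0
        samples[:, 0] = 0.2 * np.sin(2 * np.pi * 0.7 * t)
        samples += rng.normal(0, 0.01, samples.shape)
        for s, e in still_spans:
            i0, i1 = int(s * fs), int(e * fs)
            samples[i0:i1] = [0.0, 1.0, 0.0]
        return make_recording(samples, fs=fs)

    def test_three_hour_block_recovered(self):
        rec = self._active_day([(3600, 3600 + 3 * 3600)])
        nw = detect_nonwear(rec)
        assert len(nw.intervals) == 1
        s, e = nw.intervals[0]
        assert abs(s - 3600) <= 120 and abs(e - (3600 + 3 * 3600)) <= 120

    def test_fully_active_recording_empty(self):
        assert detect_nonwear(self._active_day([])).intervals == ()

    def test_merge_rule_matches_direct_evaluation(self):
        # two 90-min still blocks separated by 3 min of movement
        spans = [(3600, 3600 + 90 * 60), (3600 + 93 * 60, 3600 + 183 * 60)]
        rec = self._active_day(spans)
        nw = detect_nonwear(rec)
        # oracle: evaluate the rule directly on 60-s windows
        merged = _nonwear_oracle(rec)
        assert [tuple(i) for i in nw.intervals] == merged
        assert len(nw.intervals) == 1  # 3-min gap < 5-min merge rule


def _nonwear_oracle(rec, window_s=60.0, sd=0.013, rng_g=0.05, min_min=60.0,
                    gap_min=5.0):
    n_win = int(window_s * rec.sample_rate_hz)
    flags = []
    for i in range(rec.n_samples // n_win):
        blk = rec.samples[i * n_win:(i + 1) * n_win]
        ok = sum(
            blk[:, a].std() < sd and np.ptp(blk[:, a]) < rng_g for a in range(3)
        )
        flags.append(ok >= 2)
    runs, cur = [], None
    for i, f in enumerate(flags):
        if f and cur is None:
            cur = i
        if not f and cur is not None:
            runs.append((cur * window_s, i * window_s))
            cur = None
    if cur is not None:
        runs.append((cur * window_s, len(flags) * window_s))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_min * 60:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_min * 60]


class TestComputeAvm:
    def test_gravity_only_is_zero(self, gravity_recording):
        ep = compute_avm(gravity_recording, epoch_length_s=1)
        assert ep.n_epochs == 60
        np.testing.assert_allclose(ep.values, 0.0, atol=1e-9)

    def test_matches_per_sample_oracle_without_filter(self):
        rec = sinusoid_recording(0.1, freq_hz=2.0, duration_s=30)
        # lowpass at Nyquist disables the filter, so the oracle is exact
        ep = compute_avm(rec, epoch_length_s=1, lowpass_hz=25.0)
        oracle = _avm_oracle(rec, 1.0)
        np.testing.assert_allclose(ep.values, oracle, atol=1e-9)

    def test_filtered_agrees_within_passband_error(self):
        rec = sinusoid_recording(0.1, freq_hz=2.0, duration_s=30)
        filtered = compute_avm(rec, epoch_length_s=1)  # 20 Hz cutoff
        oracle = _avm_oracle(rec, 1.0)
        np.testing.assert_allclose(filtered.values, oracle, rtol=0.01, atol=0.5)

    def test_doubling_amplitude_increases_every_epoch(self):
        lo = compute_avm(sinusoid_recording(0.1, 2.0, 30, axis=2), epoch_length_s=1)
        hi = compute_avm(sinusoid_recording(0.2, 2.0, 30, axis=2), epoch_length_s=1)
        assert np.all(hi.values > lo.values)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        rec = sinusoid_recording(0.2, 1.5, duration_s=20)
        base = compute_avm(rec, epoch_length_s=1)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            rot = make_recording(rec.samples @ q.T, fs=rec.sample_rate_hz)
            ep = compute_avm(rot, epoch_length_s=1)
            np.testing.assert_allclose(ep.values, base.values, atol=1e-9)

    def test_epoch_longer_than_recording_rejected(self, gravity_recording):
        with pytest.raises(UsageError, match="exceeds"):
            compute_avm(gravity_recording, epoch_length_s=120)

    def test_calibration_is_applied(self):
        rec = make_recording(np.tile([0.0, 0.0, 1.1], (100, 1)))
        cal = CalibrationParams(
            offset=np.zeros(3), gain=np.array([1, 1, 1 / 1.1]), calibrated=True,
            n_stationary_windows=9,
        )
        ep = compute_avm(rec, cal, epoch_length_s=1, lowpass_hz=25.0)
        np.testing.assert_allclose(ep.values, 0.0, atol=1e-9)


def _avm_oracle(rec, epoch_s):
    """Brute-force per-sample ENMO epoch means (no filtering)."""
    n_ep = int(rec.n_samples // (epoch_s * rec.sample_rate_hz))
    k = int(epoch_s * rec.sample_rate_hz)
    out = []
    for i in range(n_ep):
        vm = np.sqrt((rec.samples[i * k:(i + 1) * k] ** 2).sum(axis=1))
        out.append(np.maximum(vm - 1, 0).mean() * 1000)
    return np.array(out)


class TestReepoch:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return AvmEpochSeries(1.0, T0, values, np.ones(len(values)))

    def test_constant_series(self):
        out = reepoch(self._series([30.0] * 15), 15.0)
        assert out.n_epochs == 1 and out.values[0] == 30.0

    def test_arithmetic_mean(self):
        out = reepoch(self._series(np.arange(1, 16)), 15.0)
        assert out.values[0] == 8.0

    def test_trailing_epochs_dropped(self):
        out = reepoch(self._series(np.arange(47)), 15.0)
        assert out.n_epochs == 3

    def test_non_multiple_target_rejected(self):
        with pytest.raises(UsageError, match="multiple"):
            reepoch(self._series(np.arange(30)), 7.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0, 500, allow_nan=False), min_size=15, max_size=90),
        st.sampled_from([3, 5, 15]),
    )
    def test_sum_conservation(self, values, k):
        src = self._series(values)
        out = reepoch(src, float(k))
        retained = out.n_epochs * k
        assert np.sum(out.values) * k == pytest.approx(
            np.sum(src.values[:retained]), rel=1e-12, abs=1e-9
        )
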