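"""Re-referencing, filtering, epoching, screening and ERP averaging."""

import numpy as np
import pandas as pd
import pytest

from perceptgamma import preprocess as pre
from perceptgamma import simulate as sim
from perceptgamma.containers import (
    BehaviourLog, EventTable, EpochSet, InvariantError, Recording,
)

from conftest import SEED


def _rec(data, kinds=None, sr=500.0, events=None):
    data = np.asarray(data, float)
    n = data.shape[0]
    labels = [f"C{i}" for i in range(n)]
    return Recording(
        data=data, sr=sr, channel_labels=labels,
        channel_kinds=kinds or ["EEG"] * n,
        positions=np.zeros((n, 2)),
        events=events or EventTable(),
    )


def _epochs(data, labels=None, sr=500.0, tmin=0.0, kinds=None):
    data = np.asarray(data, float)
    n_tr, n_ch, n_t = data.shape
    return EpochSet(
        data=data, sr=sr, tmin=tmin, tmax=tmin + (n_t - 1) / sr,
        lock="response", labels=labels or ["perceived"] * n_tr,
        channel_labels=[f"C{i}" for i in range(n_ch)],
        channel_kinds=kinds or ["EEG"] * n_ch,
    )


class TestAverageReference:
    def test_two_channel_mean_removal(self):
        rec = _rec([[1.0, 5.0], [3.0, 7.0]])
        out = pre.rereference_average(rec)
        np.testing.assert_allclose(out.data, [[-1.0, -1.0], [1.0, 1.0]])

    def test_zero_mean_data_unchanged(self):
        rng = np.random.default_rng(SEED)
        d = rng.standard_normal((3, 100))
        d -= d.mean(axis=0)
        out = pre.rereference_average(_rec(d))
        np.testing.assert_allclose(out.data, d, atol=1e-12)

    def test_bad_channel_excluded_from_mean(self):
        # hand computation: good channels [1, 3] -> mean 2 -> [-1, 1]; the
        # BAD channel (value 10) must neither shift the mean nor change
        rec = _rec([[1.0], [3.0], [10.0]], kinds=["EEG", "EEG", "BAD"])
        out = pre.rereference_average(rec)
        np.testing.assert_allclose(out.data[:, 0], [-1.0, 1.0, 10.0])

    def test_pairwise_differences_preserved(self):
        rng = np.random.default_rng(SEED)
        d = rng.standard_normal((4, 200))
        out = pre.rereference_average(_rec(d))
        np.testing.assert_allclose(out.data[0] - out.data[2], d[0] - d[2],
                                   atol=1e-12)

    def test_needs_two_good_channels(self):
        rec = _rec(np.zeros((2, 10)), kinds=["EEG", "BAD"])
        with pytest.raises(InvariantError):
            pre.rereference_average(rec)


class TestBandpass:
    def _tone(self, f, sr=500.0, dur=30.0):
        t = np.arange(0, dur, 1 / sr)
        return _rec(np.sin(2 * np.pi * f * t)[None, :], sr=sr), t

    def test_sub_band_tone_attenuated(self):
        rec, _ = self._tone(0.1)
        out = pre.bandpass(rec, 1.0, 100.0)
        mid = slice(5000, -5000)
        assert out.data[0, mid].std() < 0.1 * rec.data[0, mid].std()

    def test_in_band_tone_preserved(self):
        rec, _ = self._tone(40.0)
        out = pre.bandpass(rec, 1.0, 100.0)
        mid = slice(5000, -5000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.1

    def test_dc_offset_removed(self):
        rec = _rec(np.full((1, 15000), 50.0))
        out = pre.bandpass(rec, 1.0, 100.0)
        assert np.abs(out.data[0, 5000:-5000]).mean() < 1.0

    def test_cutoff_above_nyquist_rejected(self):
        rec = _rec(np.zeros((1, 5000)))
        with pytest.raises(InvariantError):
            pre.bandpass(rec, 1.0, 300.0)


class TestEpoch:
    def _rec_with_responses(self, times, sr=500.0, dur=30.0):
        rng = np.random.default_rng(SEED)
        ev = EventTable.from_rows(
            [(int(t * sr), "response", i) for i, t in enumerate(times)])
        return _rec(rng.standard_normal((2, int(dur * sr))), sr=sr, events=ev)

    def test_epoch_count_and_length(self):
        rec = self._rec_with_responses(np.linspace(3, 27, 10))
        ep = pre.epoch(rec, "response", -1.5, 0.5)
        assert ep.n_trials == 10
        assert ep.data.shape[2] == int(round(2.0 * rec.sr)) + 1

    def test_edge_epoch_dropped_and_logged(self):
        rec = self._rec_with_responses([0.1, 10.0])
        ep = pre.epoch(rec, "response", -0.2, 0.8)
        assert ep.n_trials == 1
        assert any("dropped=1" in s for s in ep.provenance)

    def test_unperceived_locks_to_movie_midpoint(self):
        """Movie onset at 10 s -> unperceived lock sample at 16 s."""
        sr = 500.0
        ev = EventTable.from_rows([(int(10 * sr), "movie_onset", 0),
                                   (int(22 * sr), "trial_end", 0)])
        rng = np.random.default_rng(SEED)
        data = rng.standard_normal((2, int(30 * sr)))
        marker = int(16 * sr)
        data[:, marker] = 999.0
        rec = _rec(data, sr=sr, events=ev)
        beh = BehaviourLog(pd.DataFrame({
            "trial": [0], "response_time": [np.nan],
            "perceived": [False], "correct": [False]}))
        ep = pre.epoch_rotation(rec, beh, -1.5, 0.5)
        assert ep.labels == ["unperceived"]
        t0_idx = int(round(1.5 * sr))  # epoch time 0
        assert ep.data[0, 0, t0_idx] == 999.0


class TestRejectAmplitude:
    def test_single_hot_sample_removes_trial(self):
        data = np.zeros((5, 2, 100))
        data[2, 0, 50] = 80.0
        ep = _epochs(data)
        out, log = pre.reject_amplitude(ep, 75.0)
        assert out.n_trials == 4
        assert log[0]["trial_id"] == 2 and log[0]["channel"] == "C0"

    def test_infinite_thresholds_are_identity(self):
        ep = _epochs(np.random.default_rng(SEED).normal(0, 50, (4, 2, 100)))
        out, log = pre.reject_amplitude(ep, np.inf, np.inf)
        assert out.n_trials == 4 and not log

    def test_idempotent(self):
        rng = np.random.default_rng(SEED)
        ep = _epochs(rng.normal(0, 22, (10, 3, 100)))
        once, _ = pre.reject_amplitude(ep, 75.0)
        twice, log = pre.reject_amplitude(once, 75.0)
        assert twice.n_trials == once.n_trials and not log

    def test_all_rejected_is_error(self):
        ep = _epochs(np.full((3, 2, 10), 200.0))
        with pytest.raises(InvariantError, match="threshold"):
            pre.reject_amplitude(ep, 75.0)

    def test_synthetic_blinks_drive_rejection(self):
        """Exactly the blink-containing trials are rejected, per the
        generator's ground-truth blink times."""
        cfg = sim.SynthConfig(seed=SEED, n_trials=8, n_perceived=0,
                              blink_rate=0.05, blink_amplitude=150.0)
        rec, events, beh, truth = sim.generate_rotation_dataset(
            cfg, return_truth=True)
        ep = pre.epoch_movie_end(rec, beh, tmin=-12.0, tmax=0.0)
        out, log = pre.reject_amplitude(ep, np.inf, 100.0)
        rejected = {e["trial_id"] for e in log}
        onsets = np.asarray(truth["movie_onsets"])
        blink_trials = set()
        for bt in truth["blink_times"]:
            hit = np.flatnonzero((onsets <= bt) & (bt < onsets + 12.0))
            blink_trials.update(int(h) for h in hit)
        assert rejected == blink_trials
        assert len(rejected) > 0


class TestOcularRegression:
    def test_exact_linear_contamination_removed(self):
        rng = np.random.default_rng(SEED)
        clean = rng.standard_normal((6, 1, 200))
        eog = rng.standard_normal((6, 1, 200)) * 50
        data = np.concatenate([clean + 0.3 * eog, eog], axis=1)
        ep = _epochs(data, kinds=["EEG", "EOG"])
        out = pre.correct_ocular_regression(ep)
        r = np.corrcoef(out.data[:, 0].ravel(), eog.ravel())[0, 1]
        assert abs(r) < 0.01
        np.testing.assert_array_equal(out.data[:, 1], eog[:, 0])  # EOG untouched

    def test_flat_eog_rejected(self):
        data = np.zeros((3, 2, 50))
        data[:, 0] = np.random.default_rng(SEED).standard_normal((3, 50))
        ep = _epochs(data, kinds=["EEG", "EOG"])
        with pytest.raises(InvariantError, match="flat|zero"):
            pre.correct_ocular_regression(ep)

    def test_blink_window_rms_reduced(self):
        """With the generator's frontal decay profile, post-correction EEG
        RMS inside blink windows drops by at least 80 %."""
        cfg = sim.SynthConfig(seed=SEED + 1, n_trials=6, n_perceived=0,
                              noise_rms=1.0, blink_rate=0.15,
                              blink_amplitude=200.0)
        rec, events, beh, truth = sim.generate_rotation_dataset(
            cfg, return_truth=True)
        ep = pre.epoch_movie_end(rec, beh, tmin=-12.0, tmax=0.0)
        out = pre.correct_ocular_regression(ep)
        frontal = ep.channel_labels.index("FP1")
        onsets = np.asarray(truth["movie_onsets"])
        before, after = [], []
        for bt in truth["blink_times"]:
            tr = np.flatnonzero((onsets <= bt) & (bt < onsets + 12.0))
            if not len(tr):
                continue
            rel = bt - onsets[tr[0]] - 12.0  # epoch time of blink start
            s = slice(int((rel + 12.0) * rec.sr),
                      int((rel + 12.3) * rec.sr))
            before.append(np.sqrt((ep.data[tr[0], frontal, s] ** 2).mean()))
            after.append(np.sqrt((out.data[tr[0], frontal, s] ** 2).mean()))
        assert len(before) > 0
        assert np.mean(after) < 0.2 * np.mean(before)


class TestSelectTrials:
    def _beh(self, rts, perceived=None, correct=None):
        n = len(rts)
        return BehaviourLog(pd.DataFrame({
            "trial": np.arange(n), "response_time": rts,
            "perceived": perceived if perceived is not None else [True] * n,
            "correct": correct if correct is not None else [True] * n}))

    def test_response_window_rule(self):
        ep = _epochs(np.zeros((4, 2, 50)))
        beh = self._beh([0.5, 2.0, 5.0, 11.5])
        out = pre.select_trials(ep, beh, {"response_window": (1.0, 11.0)})
        assert list(out.trial_ids) == [1, 2]

    def test_all_correct_is_identity(self):
        ep = _epochs(np.zeros((3, 2, 50)))
        out = pre.select_trials(ep, self._beh([2.0, 3.0, 4.0]),
                                {"require_correct": True})
        assert out.n_trials == 3

    def test_combined_rules_intersect(self):
        """Enumeration over 8 toy trials: intersection semantics."""
        rts = [0.5, 2, 2, 2, 12, 2, 0.5, 2]
        correct = [True, True, False, True, True, True, False, False]
        ep = _epochs(np.zeros((8, 2, 50)))
        out = pre.select_trials(
            ep, self._beh(rts, correct=correct),
            {"response_window": (1.0, 11.0), "require_correct": True})
        expected = [i for i in range(8)
                    if 1.0 <= rts[i] <= 11.0 and correct[i]]
        assert list(out.trial_ids) == expected


class TestERPAverage:
    def test_identical_trials_average_to_one_trial(self):
        rng = np.random.default_rng(SEED)
        one = rng.standard_normal((1, 2, 100))
        ep = _epochs(np.repeat(one, 5, axis=0), tmin=-0.1)
        erp = pre.erp_average(ep, (-0.1, 0.0))
        base = one[0] - one[0][:, :51].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(erp.data, base, atol=1e-12)

    def test_trial_plus_negation_cancels(self):
        rng = np.random.default_rng(SEED)
        one = rng.standard_normal((1, 2, 100))
        ep = _epochs(np.concatenate([one, -one]), tmin=-0.1)
        erp = pre.erp_average(ep, (-0.1, 0.0))
        np.testing.assert_allclose(erp.data, 0.0, atol=1e-12)

    def test_evoked_peak_latency_recovered(self):
        """A deflection injected at 220 ms peaks within ±10 ms of truth."""
        sr = 500.0
        rng = np.random.default_rng(SEED)
        n_t = int(sr * 1.0) + 1
        times = -0.2 + np.arange(n_t) / sr
        bump = -8.0 * np.exp(-0.5 * ((times - 0.220) / 0.02) ** 2)
        data = rng.standard_normal((40, 1, n_t)) + bump[None, None, :]
        ep = _epochs(data, tmin=-0.2)
        erp = pre.erp_average(ep, (-0.2, 0.0))
        peak = times[np.argmin(erp.data[0])]
        assert abs(peak - 0.220) <= 0.010


def test_pipeline_order_recorded(rotation_small):
    _, rec, _, behaviour, _ = rotation_small
    ep = pre.preprocess_recording(rec, "rotation", behaviour=behaviour)
    assert ep.provenance[-1] == \
        "order=rereference>bandpass>epoch>reject>correct>select"
    assert any(s.startswith("epoch_rotation") for s in ep.provenance)
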