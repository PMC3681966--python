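"""Synthetic EEG generator: spectra, bursts, coupling, paradigm structure."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import i0, i1

import perceptgamma as pg
from perceptgamma import simulate as sim
from perceptgamma.containers import InvariantError

from conftest import SEED


def _spectral_slope(x, sr, fmin=2.0, fmax=200.0):
    f, P = sps.welch(x, fs=sr, nperseg=4096)
    m = (f >= fmin) & (f <= min(fmax, sr / 2 - 10))
    return np.polyfit(np.log(f[m]), np.log(P[m]), 1)[0]


class TestBackground:
    def test_white_noise_has_flat_spectrum(self):
        rec = sim.generate_background(1, 60, 500, 0.0, 10.0, seed=SEED,
                                      channel_labels=["CZ"])
        assert abs(_spectral_slope(rec.data[0], 500)) < 0.1

    def test_pink_noise_slope_and_rms(self):
        rec = sim.generate_background(2, 60, 500, 1.0, 10.0, seed=SEED,
                                      channel_labels=["CZ", "PZ"])
        for ch in rec.data:
            assert -1.2 < _spectral_slope(ch, 500) < -0.8
            assert abs(ch.std() - 10.0) / 10.0 < 0.1

    def test_determinism(self):
        a = sim.generate_background(2, 5, 500, 1.0, 10.0, seed=SEED,
                                    channel_labels=["CZ", "PZ"])
        b = sim.generate_background(2, 5, 500, 1.0, 10.0, seed=SEED,
                                    channel_labels=["CZ", "PZ"])
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_exponent_rejected(self):
        with pytest.raises(InvariantError):
            sim.generate_background(1, 1, 500, -0.5, 10.0, seed=0,
                                    channel_labels=["CZ"])


def _phase_at(rec, ch, sample):
    analytic = sps.hilbert(rec.data[ch])
    return np.angle(analytic[sample])


class TestInjectBurst:
    def _plv_between(self, kappa, n_trials=400, seed=SEED, n_jittered=8):
        """Anchor/other PLV at burst centres, averaged over jittered channels.

        The non-anchor channels carry independent von Mises jitter, so the
        per-pair PLV estimates are independent and their mean tightens the
        Monte-Carlo spread around the Bessel-ratio expectation.
        """
        sr, trial = 250.0, 0.4
        labels = ["O1"] + [f"O{k + 2}" for k in range(n_jittered)]
        dur = n_trials * trial + 1.0
        rec = sim.generate_background(len(labels), dur, sr, 0.0, 1e-4,
                                      seed=seed, channel_labels=labels)
        onsets = 0.2 + np.arange(n_trials) * trial
        spec = sim.BurstSpec(channels=tuple(labels), freq=40.0, onset=0.0,
                             duration=0.2, amplitude=10.0, kappa=kappa)
        rec = sim.inject_burst(rec, onsets, spec, seed=seed + 1)
        centres = ((onsets + 0.1) * sr).astype(int)
        u = sps.hilbert(rec.data, axis=1)[:, centres]
        u /= np.abs(u)
        plvs = [abs((u[0] * np.conj(u[j])).mean())
                for j in range(1, len(labels))]
        return float(np.mean(plvs))

    def test_locked_phases_give_unit_plv(self):
        assert self._plv_between(kappa=1e9, n_trials=100) > 0.99

    def test_uniform_phases_give_null_plv(self):
        # expected null level is sqrt(pi / (4 N)) ~ 0.044 at N = 400
        assert self._plv_between(kappa=0.0) < 0.12

    def test_von_mises_coupling_matches_bessel_ratio(self):
        target = i1(2.0) / i0(2.0)
        assert abs(self._plv_between(kappa=2.0) - target) < 0.05

    def test_burst_outside_recording_rejected(self):
        rec = sim.generate_background(1, 1.0, 250, 0.0, 1.0, seed=0,
                                      channel_labels=["O1"])
        spec = sim.BurstSpec(channels=("O1",), freq=40.0, onset=0.9,
                             duration=0.5, amplitude=1.0)
        with pytest.raises(InvariantError, match="outside"):
            sim.inject_burst(rec, [0.0], spec, seed=0)


class TestMixing:
    def test_identity_is_noop(self, rotation_small):
        _, rec, _, _, _ = rotation_small
        out = sim.apply_mixing(rec, np.eye(rec.n_channels))
        np.testing.assert_allclose(out.data, rec.data)

    def test_single_source_gains(self):
        rec = sim.generate_background(1, 1.0, 250, 1.0, 10.0, seed=SEED,
                                      channel_labels=["CZ"])
        out = sim.apply_mixing(rec, np.array([[1.0], [0.5]]))
        np.testing.assert_allclose(out.data[1], 0.5 * out.data[0])

    def test_dimension_mismatch_rejected(self):
        rec = sim.generate_background(2, 1.0, 250, 1.0, 10.0, seed=0,
                                      channel_labels=["CZ", "PZ"])
        with pytest.raises(InvariantError):
            sim.apply_mixing(rec, np.ones((2, 3)))


class TestOcularArtifacts:
    def _rec(self):
        cfg = sim.SynthConfig(seed=SEED, n_trials=2)
        rec, _, _ = sim.generate_rotation_dataset(cfg)
        return rec

    def test_zero_rate_is_noop(self):
        rec = self._rec()
        out, times = sim.add_ocular_artifacts(rec, 0.0, 150.0, seed=SEED)
        np.testing.assert_array_equal(out.data, rec.data)
        assert len(times) == 0

    def test_blinks_exceed_rejection_threshold_on_eog(self):
        rec = self._rec()
        out, times = sim.add_ocular_artifacts(rec, 0.2, 150.0, seed=SEED)
        assert len(times) > 0
        eog = out.picks("EOG")[0]
        for t in times:
            seg = slice(int(t * rec.sr), int((t + 0.3) * rec.sr))
            assert np.abs(out.data[eog, seg]).max() > 100.0

    def test_zero_decay_leaves_eeg_unchanged(self):
        rec = self._rec()
        out, times = sim.add_ocular_artifacts(
            rec, 0.2, 150.0, decay_profile=np.zeros(rec.n_channels),
            seed=SEED)
        assert len(times) > 0
        for i in rec.picks("EEG"):
            np.testing.assert_array_equal(out.data[i], rec.data[i])

    def test_requires_eog_channels(self):
        rec = sim.generate_background(2, 1.0, 250, 1.0, 10.0, seed=0,
                                      channel_labels=["CZ", "PZ"])
        with pytest.raises(InvariantError, match="EOG"):
            sim.add_ocular_artifacts(rec, 0.1, 150.0, seed=0)


class TestRSVPDataset:
    def test_frame_structure_one_target_29_frequent(self, rsvp_small):
        _, _, events, _, _ = rsvp_small
        df = events.df
        for tr, g in df[df["code"] != "trial_end"].groupby("trial"):
            counts = g["code"].value_counts()
            n_target = counts.get("target_face", 0) + counts.get(
                "target_guitar", 0)
            assert n_target == 1
            assert counts.get("frequent", 0) == 29

    def test_target_onsets_inside_window(self, rsvp_small):
        cfg, rec, events, _, truth = rsvp_small
        onsets = np.asarray(truth["target_onsets"])
        trial_starts = np.array(sorted(
            events.df[events.df["code"] != "trial_end"]
            .groupby("trial")["sample"].min())) / rec.sr
        rel = onsets - trial_starts
        assert np.all((rel >= 1.5) & (rel <= 3.0))

    def test_determinism(self):
        cfg = sim.SynthConfig(paradigm="rsvp", seed=SEED, n_trials=3)
        _, e1, b1 = sim.generate_rsvp_dataset(cfg)
        _, e2, b2 = sim.generate_rsvp_dataset(cfg)
        assert e1 == e2 and b1 == b2


class TestRotationDataset:
    def test_response_latencies_within_selection_window(self, rotation_small):
        _, _, _, behaviour, _ = rotation_small
        rt = behaviour.df["response_time"].dropna()
        assert len(rt) == 20
        assert np.all((rt >= 1.0) & (rt <= 11.0))

    def test_detection_time_matches_truncated_normal_oracle(self):
        cfg = sim.SynthConfig(seed=SEED, n_trials=10_000,
                              perceived_probability=1.0)
        rng = np.random.default_rng(SEED)
        draws = sim._truncnorm_rvs(cfg.detection_mean, cfg.detection_sd,
                                   1.0, 11.0, 10_000, rng)
        oracle = sim.truncnorm_mean(4.30, 2.95, 1.0, 11.0)
        assert abs(draws.mean() - oracle) < 0.1

    def test_all_perceived_trials_carry_sustained_burst(self):
        """With perceived probability 1 the end-of-movie gamma elevation is
        present on every trial (band power up vs. an unperceived run)."""
        on = sim.SynthConfig(seed=SEED, n_trials=6, n_perceived=6)
        off = sim.SynthConfig(seed=SEED, n_trials=6, n_perceived=0)
        rec_on, ev, _ = sim.generate_rotation_dataset(on)
        rec_off, _, _ = sim.generate_rotation_dataset(off)
        sos = sps.butter(4, (60, 75), btype="bandpass", fs=500, output="sos")
        ch = rec_on.channel_index("OZ")
        for _, row in ev.df[ev.df["code"] == "movie_onset"].iterrows():
            s = int(row["sample"])
            seg = slice(s + int(9.5 * 500), s + int(11.5 * 500))
            p_on = sps.sosfiltfilt(sos, rec_on.data[ch, seg]).std()
            p_off = sps.sosfiltfilt(sos, rec_off.data[ch, seg]).std()
            assert p_on > 1.4 * p_off

    def test_byte_identical_under_same_config(self):
        cfg = sim.SynthConfig(seed=SEED, n_trials=3)
        r1, _, _ = sim.generate_rotation_dataset(cfg)
        r2, _, _ = sim.generate_rotation_dataset(cfg)
        assert r1.data.tobytes() == r2.data.tobytes()
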