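"""Synthetic EEG with the statistical structure the analysis assumes.

The generator produces continuous multi-channel recordings made of

* 1/f^alpha background noise (independent across channels; inter-channel
  correlation enters only through an explicit zero-lag mixing matrix),
* transient narrow-band oscillatory bursts with a raised-cosine (Hann)
  envelope, controllable inter-trial phase coupling (von Mises
  concentration kappa) and per-channel phase lags,
* band-limited noise bursts (sustained oscillatory state without a single
  coherent phase), used for the perception-state gamma elevation,
* instantaneous volume-conduction mixing,
* ocular (blink) artifacts on dedicated EOG channels with a frontal decay
  onto EEG channels,

organized into the two experimental paradigms: rapid serial visual
presentation (150 ms frames, rare targets between 1.5 and 3.0 s of each
4.5 s trial) and 12 s rotating-stimulus movies with variable response
latency (truncated normal on [1, 11] s).

Phase-coupling convention: the first channel of a burst is the *anchor*
and carries the per-trial reference phase exactly; every other burst
channel adds an independent von Mises(0, kappa) jitter (plus its fixed
lag).  The expected PLV between the anchor and any jittered channel is
then the Bessel ratio I1(kappa)/I0(kappa); between two jittered channels
it is that ratio squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .containers import BehaviourLog, EventTable, InvariantError, Recording
from . import montage as _montage

EOG_LABELS = ("VEOG", "HEOG")


@dataclass(frozen=True)
class BurstSpec:
    """A transient narrow-band oscillatory burst.

    ``onset`` is in seconds relative to the trial's alignment point (the
    event the burst is injected at).  ``kappa`` controls inter-trial phase
    coupling (0 = uniform phase, large = perfectly phase-locked);
    ``lag`` is the per-channel phase step in radians (channel k of
    ``channels`` is offset by k * lag).
    """

    channels: tuple[str, ...]
    freq: float
    onset: float
    duration: float
    amplitude: float
    kappa: float = 0.0
    lag: float = 0.0

    def __post_init__(self):
        if self.kappa < 0:
            raise InvariantError("kappa must be >= 0")
        if self.amplitude < 0:
            raise InvariantError("amplitude must be >= 0")
        if self.duration <= 0:
            raise InvariantError("duration must be > 0")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic datasets.

    Defaults are the desk-scale conditions exercised throughout the test
    suite: 16 EEG channels at 500 Hz, 1/f background of 10 µV RMS, and the
    two paradigms' published trial structures (150 ms frames with one
    target per 30-frame trial between 1.5 and 3.0 s; 12 s movies rotating
    over 9 s with responses truncated to [1, 11] s, detection times with
    mean 4.30 s and SD 2.95 s before truncation).
    """

    n_channels: int = 16
    sr: float = 500.0
    noise_exponent: float = 1.0
    noise_rms: float = 10.0
    bursts: tuple[BurstSpec, ...] | None = None
    mixing: np.ndarray | None = None
    blink_rate: float = 0.0
    blink_amplitude: float = 150.0
    paradigm: str = "rotation"
    # rapid-serial-presentation parameters
    frame_duration: float = 0.150
    target_probability: float = 1.0 / 30.0
    target_window: tuple[float, float] = (1.5, 3.0)
    rsvp_trial_duration: float = 4.5
    rsvp_isi: float = 2.0
    hit_probability: float = 0.90
    # rotating-stimulus parameters
    movie_duration: float = 12.0
    rotation_span: float = 9.0
    rotation_isi: float = 3.0
    detection_mean: float = 4.30
    detection_sd: float = 2.95
    detection_range: tuple[float, float] = (1.0, 11.0)
    perceived_probability: float = 2.0 / 3.0
    n_perceived: int | None = None
    # perception-state sustained gamma (rotation paradigm)
    sustained_band: tuple[float, float] = (60.0, 75.0)
    sustained_window: tuple[float, float] = (9.0, 12.0)
    sustained_amplitude: float = 2.0
    #: "auto" = posterior 70 Hz burst ending at the response (gamma rises
    #: before the perceptual report); None disables; or a custom BurstSpec
    response_burst: BurstSpec | str | None = "auto"
    n_trials: int = 90
    seed: int = 0

    def __post_init__(self):
        if self.noise_exponent < 0:
            raise InvariantError("noise exponent must be >= 0")
        for p in (self.target_probability, self.hit_probability,
                  self.perceived_probability):
            if not 0 <= p <= 1:
                raise InvariantError("probabilities must lie in [0, 1]")
        if self.paradigm not in ("rsvp", "rotation"):
            raise InvariantError(f"unknown paradigm {self.paradigm!r}")

    def posterior_channels(self) -> tuple[str, ...]:
        labels = [str(x) for x in _montage.standard_montage(self.n_channels)["label"]]
        post = [c for c in labels if c[0] in "OP" and not c.startswith("F")]
        return tuple(post) if post else tuple(labels[-4:])


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def generate_background(
    n_channels: int, duration_s: float, sr: float, alpha: float,
    rms: float, seed: int, channel_labels: list[str] | None = None,
) -> Recording:
    """Independent 1/f^alpha noise channels, scaled to a target RMS.

    White Gaussian noise is shaped in the frequency domain by f^(-alpha/2)
    (DC removed), giving a log-log spectral slope of -alpha, then scaled
    per channel so the RMS matches ``rms`` µV.
    """
    if alpha < 0:
        raise InvariantError("alpha must be >= 0")
    if duration_s <= 0:
        raise InvariantError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sr))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1 / sr)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    data = np.fft.irfft(spec * shape[None, :], n=n, axis=1)
    cur = data.std(axis=1, keepdims=True)
    data = data / np.where(cur > 0, cur, 1.0) * rms
    if channel_labels is None:
        mont = _montage.standard_montage(n_channels)
        channel_labels = [str(x) for x in mont["label"]]
    pos = _montage.positions_for(channel_labels)
    kinds = ["EOG" if "EOG" in lab.upper() else "EEG" for lab in channel_labels]
    # non-standard labels get a synthetic ring layout so topographic
    # exports still have coordinates
    missing = [i for i, k in enumerate(kinds)
               if k == "EEG" and not np.all(np.isfinite(pos[i]))]
    for j, i in enumerate(missing):
        ang = 2 * np.pi * j / max(len(missing), 1)
        pos[i] = [0.5 * np.cos(ang), 0.5 * np.sin(ang)]
    return Recording(
        data=data, sr=sr, channel_labels=channel_labels,
        channel_kinds=kinds, positions=pos,
    )


def _with_eog(rec: Recording, seed: int, rms: float = 5.0) -> Recording:
    """Append quiet VEOG/HEOG channels to a background recording."""
    rng = np.random.default_rng(seed)
    eog = rng.standard_normal((len(EOG_LABELS), rec.n_samples)) * rms
    data = np.vstack([rec.data, eog])
    labels = rec.channel_labels + list(EOG_LABELS)
    kinds = rec.channel_kinds + ["EOG"] * len(EOG_LABELS)
    pos = np.vstack([rec.positions, np.full((len(EOG_LABELS), 2), np.nan)]) \
        if rec.positions is not None else None
    return Recording(data=data, sr=rec.sr, channel_labels=labels,
                     channel_kinds=kinds, positions=pos, events=rec.events)


# ---------------------------------------------------------------------------
# Bursts
# ---------------------------------------------------------------------------

def sample_burst_phases(
    n_trials: int, n_channels: int, kappa: float, rng: np.random.Generator,
) -> np.ndarray:
    """Per-trial, per-channel burst phases under the anchor convention."""
    ref = rng.uniform(0.0, 2 * np.pi, size=n_trials)
    ph = np.tile(ref[:, None], (1, n_channels))
    if n_channels > 1 and kappa < 1e6:
        if kappa == 0:
            jit = rng.uniform(-np.pi, np.pi, size=(n_trials, n_channels - 1))
        else:
            jit = rng.vonmises(0.0, kappa, size=(n_trials, n_channels - 1))
        ph[:, 1:] += jit
    return ph


def inject_burst(
    rec: Recording, trial_onsets, burst_spec: BurstSpec, seed: int,
) -> Recording:
    """Add a Hann-enveloped tone burst to the target channels of each trial.

    The per-trial phase structure follows the anchor convention described
    in the module docstring, so the expected anchor/other PLV equals
    I1(kappa)/I0(kappa).
    """
    spec = burst_spec
    out = rec.copy()
    sr = rec.sr
    onsets = np.asarray(trial_onsets, float)
    n_b = int(round(spec.duration * sr))
    env = np.hanning(n_b)
    t_rel = np.arange(n_b) / sr
    rng = np.random.default_rng(seed)
    phases = sample_burst_phases(len(onsets), len(spec.channels), spec.kappa, rng)
    ch_idx = [rec.channel_index(c) for c in spec.channels]
    for ti, t0 in enumerate(onsets):
        start = int(round((t0 + spec.onset) * sr))
        if start < 0 or start + n_b > rec.n_samples:
            raise InvariantError(
                f"burst at trial onset {t0:.3f} s extends outside the recording"
            )
        for k, ci in enumerate(ch_idx):
            ph = phases[ti, k] + k * spec.lag
            out.data[ci, start:start + n_b] += (
                spec.amplitude * env * np.cos(2 * np.pi * spec.freq * t_rel + ph)
            )
    return out


def inject_band_noise_burst(
    rec: Recording, trial_onsets, channels, band: tuple[float, float],
    duration: float, amplitude_rms: float, seed: int, ramp: float = 0.5,
) -> Recording:
    """Add a band-limited noise burst (sustained oscillatory state).

    Unlike :func:`inject_burst` this carries no single coherent phase: white
    noise is band-passed to ``band`` and applied with a Tukey envelope
    (``ramp`` seconds of cosine taper each side) so band power is elevated
    throughout the window, independently per channel and trial.
    """
    out = rec.copy()
    sr = rec.sr
    n_b = int(round(duration * sr))
    alpha = min(1.0, 2 * ramp / duration)
    env = sps.windows.tukey(n_b, alpha=alpha)
    sos = sps.butter(4, band, btype="bandpass", fs=sr, output="sos")
    rng = np.random.default_rng(seed)
    ch_idx = [rec.channel_index(c) for c in channels]
    for t0 in np.asarray(trial_onsets, float):
        start = int(round(t0 * sr))
        if start < 0 or start + n_b > rec.n_samples:
            raise InvariantError("band-noise burst extends outside the recording")
        noise = sps.sosfiltfilt(sos, rng.standard_normal((len(ch_idx), n_b)), axis=1)
        noise = noise / noise.std(axis=1, keepdims=True) * amplitude_rms
        for k, ci in enumerate(ch_idx):
            out.data[ci, start:start + n_b] += env * noise[k]
    return out


# ---------------------------------------------------------------------------
# Mixing and ocular artifacts
# ---------------------------------------------------------------------------

def apply_mixing(rec: Recording, mixing_matrix: np.ndarray) -> Recording:
    """Instantaneous (zero-lag) mixing: output = M @ sources.

    With a square matrix, channel metadata is preserved; otherwise new
    generic labels are created.
    """
    M = np.asarray(mixing_matrix, float)
    if M.ndim != 2 or M.shape[1] != rec.n_channels:
        raise InvariantError(
            f"mixing matrix columns ({M.shape}) must equal source count "
            f"({rec.n_channels})"
        )
    data = M @ rec.data
    if M.shape[0] == rec.n_channels:
        return rec.copy(data=data)
    labels = [f"MX{i + 1}" for i in range(M.shape[0])]
    return Recording(
        data=data, sr=rec.sr, channel_labels=labels,
        channel_kinds=["EEG"] * M.shape[0],
        positions=np.zeros((M.shape[0], 2)), events=rec.events,
    )


def frontal_decay(rec: Recording, peak_gain: float = 0.4) -> np.ndarray:
    """Default blink propagation gains: strongest frontally, fading posteriorly."""
    gains = np.zeros(rec.n_channels)
    front = np.array([0.0, 0.95])  # just behind the nasion on the unit circle
    for i, kind in enumerate(rec.channel_kinds):
        if kind != "EEG" or rec.positions is None:
            continue
        d = np.linalg.norm(rec.positions[i] - front)
        gains[i] = peak_gain * np.exp(-2.5 * d)
    return gains


def add_ocular_artifacts(
    rec: Recording, blink_rate: float, amplitude: float,
    decay_profile: np.ndarray | None = None, seed: int = 0,
    blink_duration: float = 0.300,
) -> tuple[Recording, np.ndarray]:
    """Add half-sine blink deflections; returns the recording and blink times.

    Blinks appear at Poisson times, at full ``amplitude`` on EOG channels
    and scaled by ``decay_profile`` (per-channel gains, default a frontal
    exponential falloff) on EEG channels.
    """
    eog = rec.picks("EOG")
    if len(eog) == 0:
        raise InvariantError("recording has no EOG channels")
    out = rec.copy()
    if blink_rate <= 0:
        return out, np.empty(0)
    rng = np.random.default_rng(seed)
    duration = rec.duration
    n_blinks = rng.poisson(blink_rate * duration)
    times = np.sort(rng.uniform(0, duration - blink_duration, size=n_blinks))
    if decay_profile is None:
        decay_profile = frontal_decay(rec)
    decay_profile = np.asarray(decay_profile, float)
    n_b = int(round(blink_duration * rec.sr))
    shape = np.sin(np.pi * np.arange(n_b) / n_b)
    for t in times:
        s = int(round(t * rec.sr))
        seg = slice(s, s + n_b)
        for i in eog:
            out.data[i, seg] += amplitude * shape
        for i in out.picks("EEG"):
            if decay_profile[i] != 0:
                out.data[i, seg] += amplitude * decay_profile[i] * shape
    return out, times


# ---------------------------------------------------------------------------
# Paradigm datasets
# ---------------------------------------------------------------------------

def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                                 random_state=rng)


def truncnorm_mean(mean, sd, lo, hi) -> float:
    """Mean of the truncated normal detection-time law (oracle helper)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(spstats.truncnorm.mean(a, b, loc=mean, scale=sd))


def default_response_burst(cfg: SynthConfig) -> BurstSpec:
    """Posterior high-gamma burst ending at the perceptual report.

    Emulates the rise of gamma activity before the response, with moderate
    inter-trial phase coupling (kappa = 2) so pre-report synchrony is also
    elevated.
    """
    return BurstSpec(channels=cfg.posterior_channels(), freq=70.0,
                     onset=-0.8, duration=0.8, amplitude=6.0, kappa=2.0)


def _default_rsvp_bursts(cfg: SynthConfig) -> tuple[BurstSpec, ...]:
    post = cfg.posterior_channels()
    return (
        BurstSpec(channels=post, freq=40.0, onset=0.37, duration=0.31,
                  amplitude=6.0, kappa=0.0),
        BurstSpec(channels=post, freq=70.0, onset=0.17, duration=0.45,
                  amplitude=5.0, kappa=0.0),
    )


def generate_rsvp_dataset(
    cfg: SynthConfig, return_truth: bool = False,
):
    """Rapid-serial-presentation dataset: rare targets among 150 ms frames.

    Each 4.5 s trial holds 30 frames (one target, 29 frequent); the target
    frame onset is drawn uniformly from the frame grid inside the
    [1.5, 3.0] s window.  Correct (hit) trials receive the configured
    target-locked gamma bursts.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.rsvp_trial_duration / cfg.frame_duration))
    pre = 2.0
    trial_len = cfg.rsvp_trial_duration + cfg.rsvp_isi
    duration = pre + cfg.n_trials * trial_len + 2.0
    rec = generate_background(
        cfg.n_channels, duration, cfg.sr, cfg.noise_exponent, cfg.noise_rms,
        seed=int(rng.integers(2 ** 31)),
    )
    rec = _with_eog(rec, seed=int(rng.integers(2 ** 31)))

    lo, hi = cfg.target_window
    frame_grid = np.arange(n_frames) * cfg.frame_duration
    eligible = np.flatnonzero((frame_grid >= lo) & (frame_grid <= hi))
    rows, beh_rows = [], []
    target_onsets = []
    target_codes = []
    for tr in range(cfg.n_trials):
        t0 = pre + tr * trial_len
        tgt_frame = int(rng.choice(eligible))
        code = "target_face" if rng.random() < 0.5 else "target_guitar"
        for fr in range(n_frames):
            s = int(round((t0 + fr * cfg.frame_duration) * cfg.sr))
            rows.append((s, code if fr == tgt_frame else "frequent", tr))
        rows.append((int(round((t0 + cfg.rsvp_trial_duration) * cfg.sr)),
                     "trial_end", tr))
        target_onsets.append(t0 + frame_grid[tgt_frame])
        target_codes.append(code)
        beh_rows.append((tr, np.nan, True, bool(rng.random() < cfg.hit_probability)))
    events = EventTable.from_rows(rows)
    behaviour = BehaviourLog(pd.DataFrame(
        beh_rows, columns=["trial", "response_time", "perceived", "correct"]))

    bursts = cfg.bursts if cfg.bursts is not None else _default_rsvp_bursts(cfg)
    correct = behaviour.df["correct"].to_numpy()
    hit_onsets = np.asarray(target_onsets)[correct]
    for bi, spec in enumerate(bursts):
        rec = inject_burst(rec, hit_onsets, spec,
                           seed=int(rng.integers(2 ** 31)))
    blink_times = np.empty(0)
    if cfg.blink_rate > 0:
        rec, blink_times = add_ocular_artifacts(
            rec, cfg.blink_rate, cfg.blink_amplitude,
            seed=int(rng.integers(2 ** 31)))
    if cfg.mixing is not None:
        rec = apply_mixing(rec, cfg.mixing)
    rec = rec.copy(events=events)
    truth = {
        "target_onsets": list(map(float, target_onsets)),
        "target_codes": target_codes,
        "bursts": [vars(b) | {"channels": list(b.channels)} for b in bursts],
        "blink_times": blink_times.tolist(),
    }
    if return_truth:
        return rec, events, behaviour, truth
    return rec, events, behaviour


def generate_rotation_dataset(
    cfg: SynthConfig, return_truth: bool = False,
):
    """Rotating-stimulus dataset: 12 s movies, variable perceptual reports.

    Perceived trials get a response event at a truncated-normal latency in
    [1, 11] s, an optional tone burst leading the response, and a sustained
    band-limited gamma elevation over the configured end-of-movie window.
    Unperceived trials get neither.
    """
    rng = np.random.default_rng(cfg.seed)
    pre = 3.0
    trial_len = cfg.movie_duration + cfg.rotation_isi
    duration = pre + cfg.n_trials * trial_len + 2.0
    rec = generate_background(
        cfg.n_channels, duration, cfg.sr, cfg.noise_exponent, cfg.noise_rms,
        seed=int(rng.integers(2 ** 31)),
    )
    rec = _with_eog(rec, seed=int(rng.integers(2 ** 31)))

    if cfg.n_perceived is not None:
        if cfg.n_perceived > cfg.n_trials:
            raise InvariantError("n_perceived exceeds n_trials")
        perceived = np.zeros(cfg.n_trials, bool)
        perceived[rng.choice(cfg.n_trials, cfg.n_perceived, replace=False)] = True
    else:
        perceived = rng.random(cfg.n_trials) < cfg.perceived_probability
    lo, hi = cfg.detection_range
    rts = np.full(cfg.n_trials, np.nan)
    rts[perceived] = _truncnorm_rvs(
        cfg.detection_mean, cfg.detection_sd, lo, hi, int(perceived.sum()), rng)

    rows, beh_rows = [], []
    movie_onsets = []
    for tr in range(cfg.n_trials):
        t0 = pre + tr * trial_len
        movie_onsets.append(t0)
        rows.append((int(round(t0 * cfg.sr)), "movie_onset", tr))
        if perceived[tr]:
            rows.append((int(round((t0 + rts[tr]) * cfg.sr)), "response", tr))
        rows.append((int(round((t0 + cfg.movie_duration) * cfg.sr)),
                     "trial_end", tr))
        beh_rows.append((tr, rts[tr], bool(perceived[tr]), bool(perceived[tr])))
    events = EventTable.from_rows(rows)
    behaviour = BehaviourLog(pd.DataFrame(
        beh_rows, columns=["trial", "response_time", "perceived", "correct"]),
        trial_duration=cfg.movie_duration)

    movie_onsets = np.asarray(movie_onsets)
    perc_onsets = movie_onsets[perceived]
    spec = cfg.response_burst
    if spec == "auto":
        spec = default_response_burst(cfg)
    if spec is not None:
        # onset is interpreted relative to each trial's response
        per_trial = perc_onsets + rts[perceived] + spec.onset
        rec = inject_burst(rec, per_trial, replace_onset(spec, 0.0),
                           seed=int(rng.integers(2 ** 31)))
    if cfg.sustained_amplitude > 0:
        w0, w1 = cfg.sustained_window
        rec = inject_band_noise_burst(
            rec, perc_onsets + w0, cfg.posterior_channels(),
            cfg.sustained_band, w1 - w0, cfg.sustained_amplitude,
            seed=int(rng.integers(2 ** 31)),
        )
    blink_times = np.empty(0)
    if cfg.blink_rate > 0:
        rec, blink_times = add_ocular_artifacts(
            rec, cfg.blink_rate, cfg.blink_amplitude,
            seed=int(rng.integers(2 ** 31)))
    if cfg.mixing is not None:
        rec = apply_mixing(rec, cfg.mixing)
    rec = rec.copy(events=events)
    truth = {
        "movie_onsets": movie_onsets.tolist(),
        "perceived": perceived.tolist(),
        "response_times": rts.tolist(),
        "sustained_window": list(cfg.sustained_window),
        "sustained_band": list(cfg.sustained_band),
        "blink_times": blink_times.tolist(),
    }
    if return_truth:
        return rec, events, behaviour, truth
    return rec, events, behaviour


def replace_onset(spec: BurstSpec, onset: float) -> BurstSpec:
    return BurstSpec(channels=spec.channels, freq=spec.freq, onset=onset,
                     duration=spec.duration, amplitude=spec.amplitude,
                     kappa=spec.kappa, lag=spec.lag)


def generate_dataset(cfg: SynthConfig, return_truth: bool = False):
    """Dispatch on ``cfg.paradigm``."""
    fn = generate_rsvp_dataset if cfg.paradigm == "rsvp" else generate_rotation_dataset
    return fn(cfg, return_truth=return_truth)
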