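"""From continuous recordings to artifact-screened, labelled epochs.

Stage order is enforced and recorded in each epoch set's provenance:
average re-reference → zero-phase FIR band-pass → epoching →
amplitude-based trial rejection → (optional EOG regression) → trial
selection.  The two paradigms use their published epoch windows: target
frames (−0.2, 0.8) s for rapid presentation, (−1.5, 0.5) s locked to the
response (perceived) or the movie midpoint (unperceived) for the rotating
stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import BehaviourLog, EpochSet, InvariantError, Recording


@dataclass
class PreprocConfig:
    highpass: float = 1.0
    lowpass: float = 100.0
    eeg_reject: float = 75.0
    eog_reject: float = 100.0
    epoch_window: tuple[float, float] = (-0.2, 0.8)
    ocular_correction: str = "off"  # off | regression
    response_window: tuple[float, float] = (1.0, 11.0)
    require_correct: bool = True

    def __post_init__(self):
        if not 0 < self.highpass < self.lowpass:
            raise InvariantError("need 0 < highpass < lowpass")
        if self.eeg_reject <= 0 or self.eog_reject <= 0:
            raise InvariantError("rejection thresholds must be positive")


# ---------------------------------------------------------------------------
# Continuous-data stages
# ---------------------------------------------------------------------------

def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean of the good EEG channels from them.

    EOG and BAD channels neither contribute to the mean nor are changed,
    so pairwise differences between EEG channels are preserved exactly.
    """
    picks = rec.picks("EEG")
    if len(picks) < 2:
        raise InvariantError("average reference needs >= 2 good EEG channels")
    out = rec.copy()
    mean = out.data[picks].mean(axis=0)
    out.data[picks] -= mean
    return out


def bandpass(rec: Recording, highpass: float, lowpass: float) -> Recording:
    """Zero-phase FIR band-pass (Hamming window, 25% transition width).

    The odd-length symmetric FIR is applied by centred FFT convolution,
    which cancels the group delay (zero-phase in a single pass).
    """
    sr = rec.sr
    if lowpass >= sr / 2:
        raise InvariantError(f"lowpass {lowpass} Hz >= Nyquist ({sr / 2} Hz)")
    if not 0 < highpass < lowpass:
        raise InvariantError("need 0 < highpass < lowpass")
    trans = 0.25 * highpass
    numtaps = int(np.ceil(3.3 * sr / trans)) | 1
    max_taps = (rec.n_samples // 3) | 1
    numtaps = min(numtaps, max_taps)
    if numtaps < 11:
        raise InvariantError("recording too short for the requested filter")
    taps = sps.firwin(numtaps, [highpass, lowpass], pass_zero=False,
                      window="hamming", fs=sr)
    out = rec.copy()
    out.data = sps.fftconvolve(out.data, taps[None, :], mode="same", axes=1)
    return out


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def _cut_epochs(rec, lock_samples, tmin, tmax):
    sr = rec.sr
    n_pre = int(round(-tmin * sr))
    n_post = int(round(tmax * sr))
    n_t = n_pre + n_post + 1
    kept, data, dropped = [], [], 0
    for k, s in enumerate(lock_samples):
        a, b = s - n_pre, s + n_post + 1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        kept.append(k)
        data.append(rec.data[:, a:b])
    if not data:
        raise InvariantError("no epochs inside the recording bounds")
    return np.stack(data), kept, dropped, n_t


def epoch(
    rec: Recording, lock_code: str, tmin: float, tmax: float,
    label_rule=None,
) -> EpochSet:
    """One epoch per event with ``lock_code``; time 0 at the lock sample.

    ``label_rule`` maps an event row (pandas Series) to a condition label;
    a plain string assigns that label to every epoch.  Epochs running past
    the recording edges are dropped (count recorded in provenance).
    """
    ev = rec.events.select(lock_code)
    if not len(ev):
        raise InvariantError(f"no events with code {lock_code!r}")
    data, kept, dropped, _ = _cut_epochs(rec, ev["sample"].to_numpy(), tmin, tmax)
    ev_kept = ev.iloc[kept]
    if label_rule is None:
        label_rule = "target" if lock_code.startswith("target") else "perceived"
    if isinstance(label_rule, str):
        labels = [label_rule] * len(ev_kept)
    else:
        labels = [label_rule(row) for _, row in ev_kept.iterrows()]
    return EpochSet(
        data=data, sr=rec.sr, tmin=tmin, tmax=tmax, lock=lock_code,
        labels=labels, channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds), positions=rec.positions,
        trial_ids=ev_kept["trial"].to_numpy(),
        provenance=[f"epoch(lock={lock_code}, window=({tmin},{tmax}), "
                    f"dropped={dropped})"],
    )


def epoch_rotation(
    rec: Recording, behaviour: BehaviourLog,
    tmin: float = -1.5, tmax: float = 0.5,
    movie_duration: float = 12.0,
) -> EpochSet:
    """Rotating-stimulus epochs: response-locked (perceived) or
    midpoint-locked (unperceived, movie onset + half the movie)."""
    onsets = rec.events.select("movie_onset")
    if not len(onsets):
        raise InvariantError("no movie_onset events")
    responses = rec.events.select("response").set_index("trial")["sample"]
    lock_samples, labels, trial_ids = [], [], []
    half = int(round(movie_duration / 2 * rec.sr))
    for _, row in onsets.iterrows():
        tr = int(row["trial"])
        perceived = bool(
            behaviour.df.loc[behaviour.df["trial"] == tr, "perceived"].any())
        if perceived and tr in responses.index:
            lock_samples.append(int(responses.loc[tr]))
            labels.append("perceived")
        else:
            lock_samples.append(int(row["sample"]) + half)
            labels.append("unperceived")
        trial_ids.append(tr)
    data, kept, dropped, _ = _cut_epochs(rec, lock_samples, tmin, tmax)
    return EpochSet(
        data=data, sr=rec.sr, tmin=tmin, tmax=tmax, lock="response|midpoint",
        labels=[labels[k] for k in kept],
        channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds), positions=rec.positions,
        trial_ids=np.asarray([trial_ids[k] for k in kept]),
        provenance=[f"epoch_rotation(window=({tmin},{tmax}), dropped={dropped})"],
    )


def epoch_movie_end(
    rec: Recording, behaviour: BehaviourLog,
    tmin: float = -3.5, tmax: float = 0.0,
) -> EpochSet:
    """Epochs locked to the movie end (classifier feature window)."""
    ends = rec.events.select("trial_end")
    if not len(ends):
        raise InvariantError("no trial_end events")
    perc = behaviour.df.set_index("trial")["perceived"]
    data, kept, dropped, _ = _cut_epochs(rec, ends["sample"].to_numpy(), tmin, tmax)
    ev_kept = ends.iloc[kept]
    labels = ["perceived" if bool(perc.get(int(t), False)) else "unperceived"
              for t in ev_kept["trial"]]
    return EpochSet(
        data=data, sr=rec.sr, tmin=tmin, tmax=tmax, lock="trial_end",
        labels=labels, channel_labels=list(rec.channel_labels),
        channel_kinds=list(rec.channel_kinds), positions=rec.positions,
        trial_ids=ev_kept["trial"].to_numpy(),
        provenance=[f"epoch_movie_end(window=({tmin},{tmax}), dropped={dropped})"],
    )


# ---------------------------------------------------------------------------
# Trial screening
# ---------------------------------------------------------------------------

def reject_amplitude(
    ep: EpochSet, eeg_thresh: float, eog_thresh: float | None = None,
) -> tuple[EpochSet, list[dict]]:
    """Drop trials whose peak amplitude exceeds the thresholds.

    A trial is removed if any EEG sample exceeds ±``eeg_thresh`` µV or any
    EOG sample exceeds ±``eog_thresh`` µV.  The log records each removed
    trial and the first offending channel.  Idempotent.
    """
    if eeg_thresh <= 0 or (eog_thresh is not None and eog_thresh <= 0):
        raise InvariantError("thresholds must be positive")
    eog_thresh = eog_thresh if eog_thresh is not None else np.inf
    log = []
    keep = np.ones(ep.n_trials, bool)
    thresh = np.full(ep.n_channels, np.inf)
    thresh[ep.picks("EEG")] = eeg_thresh
    thresh[ep.picks("EOG")] = eog_thresh
    peaks = np.abs(ep.data).max(axis=2)  # (trials, channels)
    for t in range(ep.n_trials):
        over = np.flatnonzero(peaks[t] > thresh)
        if len(over):
            keep[t] = False
            log.append({
                "trial_id": int(ep.trial_ids[t]),
                "channel": ep.channel_labels[over[0]],
                "peak": float(peaks[t, over[0]]),
            })
    if not keep.any():
        raise InvariantError(
            "all trials rejected; review the amplitude thresholds")
    out = ep.subset(keep).with_provenance(
        f"reject_amplitude(eeg={eeg_thresh}, eog={eog_thresh}, "
        f"rejected={int((~keep).sum())})")
    return out, log


def correct_ocular_regression(ep: EpochSet, eog_channels=None) -> EpochSet:
    """Remove EOG-explained variance from EEG channels by least squares.

    Propagation coefficients are estimated on the epoch data (all trials
    concatenated); EOG channels are left untouched.
    """
    if eog_channels is None:
        eog_idx = ep.picks("EOG")
    else:
        eog_idx = np.array([ep.channel_labels.index(c) for c in eog_channels])
    if len(eog_idx) == 0:
        raise InvariantError("no EOG channels for regression")
    eeg_idx = ep.picks("EEG")
    n_tr, _, n_t = ep.data.shape
    E = ep.data[:, eog_idx, :].transpose(1, 0, 2).reshape(len(eog_idx), -1)
    if np.any(E.var(axis=1) == 0):
        raise InvariantError("flat (zero-variance) EOG channel")
    Y = ep.data[:, eeg_idx, :].transpose(1, 0, 2).reshape(len(eeg_idx), -1)
    E0 = E - E.mean(axis=1, keepdims=True)
    Y0 = Y - Y.mean(axis=1, keepdims=True)
    B = (Y0 @ E0.T) @ np.linalg.pinv(E0 @ E0.T)  # (n_eeg, n_eog)
    data = ep.data.copy()
    corrected = (Y - B @ E).reshape(len(eeg_idx), n_tr, n_t).transpose(1, 0, 2)
    data[:, eeg_idx, :] = corrected
    out = ep.subset(np.arange(n_tr))
    out.data = data
    return out.with_provenance("correct_ocular_regression")


def select_trials(
    ep: EpochSet, behaviour: BehaviourLog | None, rules: dict,
) -> EpochSet:
    """Keep trials satisfying all rules (intersection semantics).

    Supported rules: ``response_window=(lo, hi)`` s (perceived trials must
    respond inside it; unperceived trials pass), ``require_correct=True``,
    ``labels=[...]`` (condition whitelist).  Per-rule removal counts go to
    provenance.
    """
    keep = np.ones(ep.n_trials, bool)
    counts = {}
    beh = None if behaviour is None else behaviour.df.set_index("trial")
    if "response_window" in rules and beh is not None:
        lo, hi = rules["response_window"]
        m = np.ones(ep.n_trials, bool)
        for k, tr in enumerate(ep.trial_ids):
            if tr in beh.index and bool(beh.loc[tr, "perceived"]):
                rt = float(beh.loc[tr, "response_time"])
                m[k] = bool(np.isfinite(rt) and lo <= rt <= hi)
        counts["response_window"] = int((~m & keep).sum())
        keep &= m
    if rules.get("require_correct") and beh is not None:
        m = np.array([
            bool(beh.loc[tr, "correct"]) if tr in beh.index else False
            for tr in ep.trial_ids])
        counts["require_correct"] = int((~m & keep).sum())
        keep &= m
    if "labels" in rules:
        allowed = set(rules["labels"])
        m = np.array([lab in allowed for lab in ep.labels])
        counts["labels"] = int((~m & keep).sum())
        keep &= m
    out = ep.subset(keep).with_provenance(f"select_trials(removed={counts})")
    return out


# ---------------------------------------------------------------------------
# ERP
# ---------------------------------------------------------------------------

@dataclass
class ERPAverage:
    data: np.ndarray       # (channels, time) mean across trials
    sd: np.ndarray         # (channels, time) across-trial dispersion
    times: np.ndarray
    n_trials: int
    channel_labels: list[str]


def erp_average(ep: EpochSet, baseline_window: tuple[float, float]) -> ERPAverage:
    """Across-trial average after per-trial baseline-mean subtraction."""
    b0, b1 = baseline_window
    times = ep.times
    mask = (times >= b0) & (times <= b1)
    if not mask.any():
        raise InvariantError("baseline window outside the epoch")
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    centred = ep.data - base
    return ERPAverage(
        data=centred.mean(axis=0), sd=centred.std(axis=0), times=times,
        n_trials=ep.n_trials, channel_labels=list(ep.channel_labels),
    )


# ---------------------------------------------------------------------------
# Orchestrated pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: Recording, paradigm: str, config: PreprocConfig | None = None,
    behaviour: BehaviourLog | None = None,
    epoch_kind: str = "analysis",
) -> EpochSet:
    """Run the full stage order for one paradigm.

    ``epoch_kind='analysis'`` uses the published analysis windows;
    ``'movie_end'`` (rotation only) locks to the end of the movie for
    classifier features.  The rotating-stimulus variant applies the
    ±100 µV all-channel rejection rule; rapid presentation uses ±75 µV EEG
    with ±100 µV EOG.
    """
    if config is None:
        config = PreprocConfig(
            epoch_window=(-0.2, 0.8) if paradigm == "rsvp" else (-1.5, 0.5))
    rec = rereference_average(rec)
    rec = bandpass(rec, config.highpass, config.lowpass)
    if paradigm == "rsvp":
        face = epoch(rec, "target_face", *config.epoch_window, "target")
        guitar = epoch(rec, "target_guitar", *config.epoch_window, "target")
        data = np.concatenate([face.data, guitar.data])
        ep = EpochSet(
            data=data, sr=rec.sr, tmin=config.epoch_window[0],
            tmax=config.epoch_window[1], lock="target",
            labels=face.labels + guitar.labels,
            channel_labels=face.channel_labels, channel_kinds=face.channel_kinds,
            positions=face.positions,
            trial_ids=np.concatenate([face.trial_ids, guitar.trial_ids]),
            provenance=face.provenance,
        )
        ep, _ = reject_amplitude(ep, config.eeg_reject, config.eog_reject)
        if config.ocular_correction == "regression":
            ep = correct_ocular_regression(ep)
        if behaviour is not None and config.require_correct:
            ep = select_trials(ep, behaviour, {"require_correct": True})
    elif paradigm == "rotation":
        if behaviour is None:
            raise InvariantError("rotation preprocessing needs a behaviour log")
        if epoch_kind == "movie_end":
            ep = epoch_movie_end(rec, behaviour)
        else:
            ep = epoch_rotation(rec, behaviour, *config.epoch_window)
        ep, _ = reject_amplitude(ep, 100.0, 100.0)
        if config.ocular_correction == "regression":
            ep = correct_ocular_regression(ep)
        ep = select_trials(ep, behaviour,
                           {"response_window": config.response_window})
    else:
        raise InvariantError(f"unknown paradigm {paradigm!r}")
    return ep.with_provenance(
        "order=rereference>bandpass>epoch>reject>correct>select")
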