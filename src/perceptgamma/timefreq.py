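"""Per-trial amplitude and phase on a 15–90 Hz grid.

Energy comes from a smoothed pseudo Wigner–Ville distribution (PWVD) of the
analytic signal:

    W(t, f) = h(0) r_0(t) + 2 Re sum_{m>0} h(m) r_m(t) exp(-i 4 pi f m / sr)

with r_m(t) = <x(t+m) x*(t-m)>_g, h a Hamming lag (frequency-smoothing)
window of ~sr/4 samples (≈4 Hz smoothing) and g a 50 ms Hamming
time-smoothing window.  The smoothing suppresses the quadratic transform's
oscillatory cross-terms at the cost of some time-frequency resolution.

The PWVD is real-valued and therefore carries no phase.  Phase (and the
complex coefficients used for coherency) come from an auxiliary complex
narrow-band decomposition: convolution with Gaussian-windowed complex
exponentials of 4-cycle support centred on each frequency bin.

Both maps share a common, optionally decimated, time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, InvariantError


# ---------------------------------------------------------------------------
# Band definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandSpec:
    """Ordered, non-overlapping half-open frequency bands [lo, hi) in Hz."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        prev_hi = -np.inf
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise InvariantError(f"band {name}: lo must be < hi")
            if lo < prev_hi:
                raise InvariantError(f"band {name} overlaps its predecessor")
            prev_hi = hi

    @classmethod
    def default(cls) -> "BandSpec":
        """The four 15-Hz gamma-range analysis bands."""
        return cls((
            ("15-30", 15.0, 30.0),
            ("30-45", 30.0, 45.0),
            ("45-60", 45.0, 60.0),
            ("60-75", 60.0, 75.0),
        ))

    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def edges(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)

    def members(self, name: str, freqs: np.ndarray) -> np.ndarray:
        lo, hi = self.edges(name)
        return np.flatnonzero((freqs >= lo) & (freqs < hi))


DEFAULT_FREQS = np.arange(15.0, 91.0, 1.0)


@dataclass
class TFR:
    """Time-frequency representation: trials × channels × freqs × times.

    ``power`` holds PWVD energy (non-negative before normalization;
    z-units after), ``coeffs`` the complex narrow-band coefficients whose
    angle is the instantaneous phase.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    labels: list[str]
    coeffs: np.ndarray | None = None
    normalized: bool = False
    baseline: tuple[float, float] | None = None
    clip_fraction: float = 0.0
    positions: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.power = np.asarray(self.power)
        if self.power.ndim != 4:
            raise InvariantError("power must be (trials, channels, freqs, times)")
        self.freqs = np.asarray(self.freqs, float)
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.freqs) <= 0):
            raise InvariantError("freqs must be strictly increasing")
        nt, nc, nf, ns = self.power.shape
        if nf != len(self.freqs) or ns != len(self.times):
            raise InvariantError("power shape inconsistent with freqs/times")
        if len(self.channel_labels) != nc:
            raise InvariantError("channel_labels length mismatch")
        if len(self.labels) != nt:
            raise InvariantError("labels length must equal trial count")
        if self.coeffs is not None and self.coeffs.shape != self.power.shape:
            raise InvariantError("coeffs shape must match power")

    @property
    def phase(self) -> np.ndarray:
        if self.coeffs is None:
            raise InvariantError("phase requested but coefficients not computed")
        return np.angle(self.coeffs)

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def trial_mask(self, label: str) -> np.ndarray:
        return np.array([lab == label for lab in self.labels])

    def subset(self, trial_mask) -> "TFR":
        idx = np.flatnonzero(np.asarray(trial_mask)) \
            if np.asarray(trial_mask).dtype == bool else np.asarray(trial_mask)
        return replace(
            self,
            power=self.power[idx],
            coeffs=None if self.coeffs is None else self.coeffs[idx],
            labels=[self.labels[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# Analytic signal
# ---------------------------------------------------------------------------

def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic (one-sided-spectrum) signal via the Hilbert transform.

    Works on the last axis.  Real part equals the input.
    """
    x = np.asarray(x, float)
    if x.shape[-1] < 8:
        raise InvariantError("signal too short for an analytic decomposition")
    if not np.all(np.isfinite(x)):
        raise InvariantError("non-finite values in signal")
    return sps.hilbert(x, axis=-1)


# ---------------------------------------------------------------------------
# Pseudo Wigner-Ville
# ---------------------------------------------------------------------------

def _lag_products(z: np.ndarray, L: int) -> np.ndarray:
    """r_m(n) = z(n+m) conj(z(n-m)) for m = 0..L; zero outside the record."""
    T = z.shape[-1]
    R = np.zeros((L + 1, T), dtype=complex)
    R[0] = z * np.conj(z)
    for m in range(1, L + 1):
        R[m, m:T - m] = z[2 * m:] * np.conj(z[:T - 2 * m])
    return R


def pwvd_power(
    epoch_channel: np.ndarray,
    sr: float,
    freqs: np.ndarray,
    time_smoothing: float = 0.05,
    freq_window: int | None = None,
    decim: int = 1,
    _return_clip: bool = False,
):
    """Smoothed pseudo Wigner-Ville energy of one analytic signal.

    Parameters
    ----------
    epoch_channel : complex ndarray (n_times,)
        Analytic signal (see :func:`analytic_signal`).
    sr : float
        Sampling rate (Hz).
    freqs : array
        Frequency grid (Hz); must lie below the Nyquist frequency.
    time_smoothing : float
        Length of the Hamming time-smoothing window g, seconds (50 ms
        nulls cross-term beats at multiples of 20 Hz).
    freq_window : int, optional
        Total length of the Hamming lag window h in samples
        (default ``round(sr / 4)``, ≈4 Hz of frequency smoothing).
    decim : int
        Keep every ``decim``-th output time sample.

    Returns
    -------
    ndarray (n_freqs, n_times_out)
        Non-negative energy map (negative PWVD values clipped to zero).
    """
    z = np.asarray(epoch_channel)
    if not np.iscomplexobj(z):
        z = analytic_signal(z)
    freqs = np.asarray(freqs, float)
    if freqs.max() >= sr / 2:
        raise InvariantError(
            f"frequency grid reaches {freqs.max()} Hz >= Nyquist ({sr / 2} Hz)"
        )
    if freq_window is None:
        freq_window = max(int(round(sr / 4)) | 1, 5)
    L = max(freq_window // 2, 2)
    h = np.hamming(2 * L + 1)[L:]

    R = _lag_products(z, L)
    n_g = max(int(round(time_smoothing * sr)) | 1, 1)
    if n_g > 1:
        g = np.hamming(n_g)
        g /= g.sum()
        R = sps.fftconvolve(R, g[None, :], mode="same", axes=1)
    if decim > 1:
        R = R[:, ::decim]
    m = np.arange(L + 1)
    E = (h * np.exp(-4j * np.pi * np.outer(freqs, m) / sr)).astype(complex)
    W = 2.0 * (E @ R).real - h[0] * R[0].real
    neg = W < 0
    clip_fraction = float(neg.mean())
    W[neg] = 0.0
    if _return_clip:
        return W, clip_fraction
    return W


# ---------------------------------------------------------------------------
# Narrow-band complex decomposition (phase)
# ---------------------------------------------------------------------------

def _narrowband_kernel(f: float, sr: float, n_cycles: float = 4.0) -> np.ndarray:
    """Gaussian-windowed complex exponential of ``n_cycles`` support."""
    n = int(round(n_cycles / f * sr)) | 1
    t = (np.arange(n) - n // 2) / sr
    sigma = (n / sr) / 6.0
    k = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma) ** 2)
    return (k / np.abs(k).sum()).astype(np.complex128)


def narrowband_coeffs(
    data: np.ndarray, sr: float, freqs: np.ndarray, decim: int = 1
) -> np.ndarray:
    """Complex coefficients (..., n_freqs, n_times_out) for each frequency."""
    data = np.asarray(data, float)
    lead = data.shape[:-1]
    T = data.shape[-1]
    flat = data.reshape(-1, T)
    n_out = len(range(0, T, decim))
    out = np.empty(lead + (len(freqs), n_out), dtype=np.complex64)
    out_flat = out.reshape(-1, len(freqs), n_out)
    for fi, f in enumerate(np.asarray(freqs, float)):
        k = _narrowband_kernel(f, sr)
        c = sps.fftconvolve(flat, k[None, :], mode="same", axes=1)
        out_flat[:, fi, :] = c[:, ::decim]
    return out


# ---------------------------------------------------------------------------
# Epoch-level decomposition
# ---------------------------------------------------------------------------

def tfr_decompose(
    ep: EpochSet,
    freqs: np.ndarray = DEFAULT_FREQS,
    decim: int = 1,
    compute_phase: bool = True,
    induced: bool = False,
    time_smoothing: float = 0.05,
    freq_window: int | None = None,
) -> TFR:
    """Decompose an epoch set into a per-trial :class:`TFR`.

    Power comes from the smoothed pseudo Wigner-Ville transform, phase from
    the Gaussian narrow-band decomposition, both on the same (decimated)
    time grid.  With ``induced=True`` the across-trial average (the evoked
    response) is subtracted per channel before decomposition, isolating
    non-phase-locked activity.
    """
    freqs = np.asarray(freqs, float)
    picks = ep.picks("EEG")
    if len(picks) == 0:
        raise InvariantError("no good EEG channels to decompose")
    n_t = ep.data.shape[2]
    if n_t / ep.sr < 4.0 / freqs.min():
        raise InvariantError(
            f"epoch of {n_t / ep.sr:.3f} s is shorter than 4 cycles "
            f"of {freqs.min()} Hz"
        )
    data = ep.data[:, picks, :]
    if induced:
        data = data - data.mean(axis=0, keepdims=True)
    z = analytic_signal(data)
    n_trials, n_ch, _ = data.shape
    times = ep.times[::decim]
    power = np.empty((n_trials, n_ch, len(freqs), len(times)), dtype=np.float32)
    clip_total = 0.0
    for tr in range(n_trials):
        for ch in range(n_ch):
            W, cf = pwvd_power(
                z[tr, ch], ep.sr, freqs,
                time_smoothing=time_smoothing, freq_window=freq_window,
                decim=decim, _return_clip=True,
            )
            power[tr, ch] = W
            clip_total += cf
    coeffs = None
    if compute_phase:
        coeffs = narrowband_coeffs(data, ep.sr, freqs, decim=decim)
    return TFR(
        power=power,
        coeffs=coeffs,
        freqs=freqs,
        times=times,
        channel_labels=[ep.channel_labels[i] for i in picks],
        labels=list(ep.labels),
        clip_fraction=clip_total / (n_trials * n_ch),
        positions=None if ep.positions is None else ep.positions[picks],
    )


# ---------------------------------------------------------------------------
# Baseline normalization and band averaging
# ---------------------------------------------------------------------------

def _baseline_stats(avg_power: np.ndarray, mask: np.ndarray):
    mu = avg_power[..., mask].mean(axis=-1)
    sd = avg_power[..., mask].std(axis=-1)
    return mu, sd


def baseline_normalize(tfr: TFR, baseline_window: tuple[float, float]) -> TFR:
    """Z-score power against a baseline window, per channel and frequency.

    Statistics are computed on the across-trial-average power within the
    window (so the *average* map has baseline mean 0 / SD 1) and applied to
    every trial.  Phase coefficients are untouched.
    """
    b0, b1 = baseline_window
    mask = (tfr.times >= b0) & (tfr.times <= b1)
    if not mask.any():
        raise InvariantError("baseline window outside the epoch")
    avg = tfr.power.mean(axis=0)  # (ch, f, t)
    mu, sd = _baseline_stats(avg, mask)
    bad = ~(sd > 0)
    if bad.any():
        ch, f = np.argwhere(bad)[0]
        raise InvariantError(
            f"zero baseline SD at channel {tfr.channel_labels[ch]}, "
            f"{tfr.freqs[f]:g} Hz"
        )
    power = (tfr.power - mu[None, :, :, None]) / sd[None, :, :, None]
    return replace(
        tfr, power=power.astype(np.float32), normalized=True,
        baseline=(float(b0), float(b1)),
    )


def normalize_to_reference(tfr: TFR, reference: TFR) -> TFR:
    """Z-score power against a reference condition's map.

    Statistics are the across-time mean/SD of the reference's
    across-trial-average power, per channel and frequency — the
    no-perception state serves as the baseline for perception maps in the
    rotating-stimulus paradigm.
    """
    if reference.power.shape[1:3] != tfr.power.shape[1:3]:
        raise InvariantError("reference TFR has incompatible channels/freqs")
    avg = reference.power.mean(axis=0)
    mu = avg.mean(axis=-1)
    sd = avg.std(axis=-1)
    if not np.all(sd > 0):
        raise InvariantError("zero SD in reference map")
    power = (tfr.power - mu[None, :, :, None]) / sd[None, :, :, None]
    return replace(
        tfr, power=power.astype(np.float32), normalized=True, baseline=None,
    )


def band_average(
    tfr: TFR,
    bands: BandSpec | None = None,
    channels: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Average power over each band's frequency bins and a channel subset.

    Returns ``{band name: (n_trials, n_times) array}``.  Bin membership is
    half-open ``lo <= f < hi``.
    """
    bands = bands or BandSpec.default()
    if channels is None:
        ch_idx = np.arange(len(tfr.channel_labels))
    else:
        ch_idx = np.array([tfr.channel_index(c) for c in channels])
        if len(ch_idx) == 0:
            raise InvariantError("empty channel subset")
    out = {}
    for name in bands.names():
        fidx = bands.members(name, tfr.freqs)
        if len(fidx) == 0:
            raise InvariantError(f"band {name} has no frequency bins")
        sub = tfr.power[:, ch_idx][:, :, fidx, :]
        out[name] = sub.mean(axis=(1, 2))
    return out
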