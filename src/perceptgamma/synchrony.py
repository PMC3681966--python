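"""Inter-trial phase synchrony across all electrode pairs.

Two complementary measures:

* **PLV** — magnitude of the across-trial mean unit phasor of the phase
  difference between two channels.  Sensitive to any consistent phase
  relation, including the spurious zero-lag relations produced by volume
  conduction.
* **ImCoh** — imaginary part of the normalized cross-spectrum (coherency),
  estimated across trials at each time-frequency bin.  Instantaneous
  (zero-lag) mixing of a common source produces a purely real coherency,
  so a nonzero ImCoh indicates a time-lagged, genuinely interacting pair.

Both are computed from the complex narrow-band coefficients of a
:class:`~perceptgamma.timefreq.TFR`, so they share its time-frequency grid.
Bins where a channel has zero power are undefined and propagate as NaN,
excluded (with counts) from summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import InvariantError
from .timefreq import TFR, BandSpec


@dataclass
class PairSyncMap:
    """Channel-pair × frequency × time synchrony values."""

    values: np.ndarray                 # (n_pairs, n_freqs, n_times)
    pairs: list[tuple[int, int]]       # unordered (i < j) channel indices
    measure: str                       # "PLV" | "ImCoh" | "normalized-PLV"
    n_trials: int
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]

    def __post_init__(self):
        n_ch = len(self.channel_labels)
        if len(self.pairs) != n_ch * (n_ch - 1) // 2:
            raise InvariantError("pair count must be C(n_channels, 2)")
        finite = self.values[np.isfinite(self.values)]
        if self.measure == "PLV" and finite.size and (
            finite.min() < -1e-9 or finite.max() > 1 + 1e-6
        ):
            raise InvariantError("PLV out of [0, 1]")
        if self.measure == "ImCoh" and finite.size and (
            np.abs(finite).max() > 1 + 1e-6
        ):
            raise InvariantError("ImCoh out of [-1, 1]")

    def pair_index(self, i: int, j: int) -> int:
        a, b = (i, j) if i < j else (j, i)
        return self.pairs.index((a, b))

    def get(self, i: int, j: int) -> np.ndarray:
        """Values for a pair requested in either order (sign-aware for ImCoh)."""
        v = self.values[self.pair_index(i, j)]
        if self.measure == "ImCoh" and i > j:
            return -v
        return v


@dataclass
class ChannelConnectivity:
    """Per-channel, per-band connectivity strength summaries."""

    channel_labels: list[str]
    band_names: list[str]
    matrix: dict[str, np.ndarray]        # signed (n_ch, n_ch) per band
    channel_mean: dict[str, np.ndarray]  # mean |value| to all partners

    def __post_init__(self):
        for name in self.band_names:
            if (self.channel_mean[name] < 0).any():
                raise InvariantError("connectivity strength must be non-negative")


def _unit_phasors(tfr: TFR) -> np.ndarray:
    c = tfr.coeffs
    if c is None:
        raise InvariantError("TFR has no phase coefficients")
    mag = np.abs(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mag > 0, c / mag, np.nan + 0j)
    return u


def _all_pairs(n_ch: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]


def plv(tfr: TFR, pair: tuple[int, int]) -> np.ndarray:
    """PLV(f, t) = |mean_trials exp(i (phi_i - phi_j))| for one pair."""
    if tfr.n_trials < 2:
        raise InvariantError("PLV needs at least 2 trials")
    i, j = pair
    u = _unit_phasors(tfr.subset(np.arange(tfr.n_trials)))
    d = u[:, i] * np.conj(u[:, j])
    return np.abs(np.nanmean(d, axis=0))


def plv_all_pairs(tfr: TFR) -> PairSyncMap:
    """PLV for every unordered channel pair (i < j), in documented order."""
    if tfr.n_trials < 2:
        raise InvariantError("PLV needs at least 2 trials")
    u = _unit_phasors(tfr)
    n_ch = u.shape[1]
    pairs = _all_pairs(n_ch)
    vals = np.empty((len(pairs), u.shape[2], u.shape[3]))
    for k, (i, j) in enumerate(pairs):
        vals[k] = np.abs(np.nanmean(u[:, i] * np.conj(u[:, j]), axis=0))
    return PairSyncMap(
        values=vals, pairs=pairs, measure="PLV", n_trials=tfr.n_trials,
        freqs=tfr.freqs, times=tfr.times, channel_labels=list(tfr.channel_labels),
    )


def normalize_plv(m: PairSyncMap, baseline_window: tuple[float, float]) -> PairSyncMap:
    """Z-score a PLV map against its baseline-window time bins, per pair/frequency."""
    b0, b1 = baseline_window
    mask = (m.times >= b0) & (m.times <= b1)
    if not mask.any():
        raise InvariantError("baseline window outside the map")
    mu = m.values[..., mask].mean(axis=-1, keepdims=True)
    sd = m.values[..., mask].std(axis=-1, keepdims=True)
    if not np.all(sd > 0):
        raise InvariantError("zero baseline SD in PLV map")
    return replace(m, values=(m.values - mu) / sd, measure="normalized-PLV")


def coherency(tfr: TFR, pair: tuple[int, int]) -> np.ndarray:
    """Across-trial coherency C_ij(f, t) = S_ij / sqrt(S_ii S_jj), complex."""
    if tfr.n_trials < 2:
        raise InvariantError("coherency needs at least 2 trials")
    c = tfr.coeffs
    if c is None:
        raise InvariantError("TFR has no phase coefficients")
    i, j = pair
    a, b = c[:, i].astype(complex), c[:, j].astype(complex)
    s_ij = (a * np.conj(b)).mean(axis=0)
    s_ii = (np.abs(a) ** 2).mean(axis=0)
    s_jj = (np.abs(b) ** 2).mean(axis=0)
    denom = np.sqrt(s_ii * s_jj)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, s_ij / denom, np.nan + 0j)
    return out


def imcoh(tfr: TFR, pair: tuple[int, int]) -> np.ndarray:
    """Imaginary part of coherency for one pair (antisymmetric in the pair)."""
    return np.imag(coherency(tfr, pair))


def imcoh_all_pairs(tfr: TFR) -> PairSyncMap:
    """ImCoh for every unordered channel pair (i < j)."""
    if tfr.n_trials < 2:
        raise InvariantError("coherency needs at least 2 trials")
    c = tfr.coeffs.astype(np.complex128)
    n_ch = c.shape[1]
    power = (np.abs(c) ** 2).mean(axis=0)  # (ch, f, t)
    pairs = _all_pairs(n_ch)
    vals = np.empty((len(pairs), c.shape[2], c.shape[3]))
    for k, (i, j) in enumerate(pairs):
        s_ij = (c[:, i] * np.conj(c[:, j])).mean(axis=0)
        denom = np.sqrt(power[i] * power[j])
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[k] = np.where(denom > 0, np.imag(s_ij) / denom, np.nan)
    return PairSyncMap(
        values=vals, pairs=pairs, measure="ImCoh", n_trials=tfr.n_trials,
        freqs=tfr.freqs, times=tfr.times, channel_labels=list(tfr.channel_labels),
    )


def imcoh_shuffle_null(
    tfr: TFR, pair: tuple[int, int], n_shuffles: int, seed: int,
) -> np.ndarray:
    """Trial-shuffle null distribution of |ImCoh| for one pair.

    The trial correspondence of the second channel is permuted, destroying
    any genuine across-trial phase relation while preserving each channel's
    marginal statistics.  Returns (n_shuffles, n_freqs, n_times).
    """
    rng = np.random.default_rng(seed)
    c = tfr.coeffs.astype(np.complex128)
    i, j = pair
    a, b = c[:, i], c[:, j]
    s_ii = (np.abs(a) ** 2).mean(axis=0)
    s_jj = (np.abs(b) ** 2).mean(axis=0)
    denom = np.sqrt(s_ii * s_jj)
    out = np.empty((n_shuffles,) + a.shape[1:])
    n = a.shape[0]
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        s_ij = (a * np.conj(b[perm])).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[s] = np.where(denom > 0, np.abs(np.imag(s_ij) / denom), np.nan)
    return out


def connectivity_summary(
    m: PairSyncMap,
    bands: BandSpec | None = None,
    time_window: tuple[float, float] | None = None,
) -> ChannelConnectivity:
    """Band- and window-averaged per-channel connectivity strengths.

    Averages over the time window and each band's frequency bins (signed,
    so condition differences stay linear), then summarizes each channel by
    the mean absolute value over its partners.  NaN (undefined) bins are
    excluded from the averages.
    """
    bands = bands or BandSpec.default()
    if time_window is None:
        tmask = np.ones(len(m.times), bool)
    else:
        tmask = (m.times >= time_window[0]) & (m.times <= time_window[1])
        if not tmask.any():
            raise InvariantError("time window outside the map")
    n_ch = len(m.channel_labels)
    matrix: dict[str, np.ndarray] = {}
    channel_mean: dict[str, np.ndarray] = {}
    for name in bands.names():
        fidx = bands.members(name, m.freqs)
        mat = np.zeros((n_ch, n_ch))
        sub = m.values[:, fidx][:, :, tmask]
        with np.errstate(invalid="ignore"):
            pair_vals = np.nanmean(sub, axis=(1, 2))
        for k, (i, j) in enumerate(m.pairs):
            v = pair_vals[k]
            mat[i, j] = v
            mat[j, i] = -v if m.measure == "ImCoh" else v
        matrix[name] = mat
        off = ~np.eye(n_ch, dtype=bool)
        channel_mean[name] = np.array(
            [np.abs(mat[i, off[i]]).mean() for i in range(n_ch)]
        )
    return ChannelConnectivity(
        channel_labels=list(m.channel_labels), band_names=bands.names(),
        matrix=matrix, channel_mean=channel_mean,
    )
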