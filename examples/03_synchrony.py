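"""Phase-locking vs. imaginary coherency under volume conduction.

Two demonstrations: (1) the inter-trial PLV of von-Mises-coupled channels
converges to the Bessel ratio I1(k)/I0(k); (2) a common source mixed
instantaneously into two electrodes produces high PLV but essentially no
imaginary coherency — ImCoh ignores zero-lag (volume-conducted) coupling.
"""

import numpy as np
from scipy.special import i0, i1

from perceptgamma import simulate as sim
from perceptgamma import synchrony as sy
from perceptgamma import timefreq as tf
from perceptgamma.containers import EpochSet

# --- 1: PLV calibration against the Bessel-ratio oracle -------------------
rng = np.random.default_rng(42)
print("kappa   empirical PLV   I1(k)/I0(k)")
for kappa in (0.0, 1.0, 2.0, 5.0):
    phases = sim.sample_burst_phases(400, 33, kappa, rng)
    coeffs = np.exp(1j * phases)[:, :, None, None].astype(np.complex64)
    t = tf.TFR(power=np.abs(coeffs) ** 2, coeffs=coeffs,
               freqs=np.array([40.0]), times=np.array([0.0]),
               channel_labels=[f"c{i}" for i in range(33)],
               labels=["perceived"] * 400)
    plv = np.mean([float(sy.plv(t, (0, j)).squeeze()) for j in range(1, 33)])
    oracle = 0.0 if kappa == 0 else i1(kappa) / i0(kappa)
    print(f"{kappa:5.1f}   {plv:13.3f}   {oracle:11.3f}")

# --- 2: zero-lag mixing -----------------------------------------------------
sr, n_trials = 500.0, 80
dur = n_trials * 0.6 + 1.0
src = sim.generate_background(1, dur, sr, 1.0, 5.0, seed=1,
                              channel_labels=["CZ"])
onsets = 0.5 + np.arange(n_trials) * 0.6
src = sim.inject_burst(src, onsets, sim.BurstSpec(
    channels=("CZ",), freq=40.0, onset=0.05, duration=0.3,
    amplitude=20.0, kappa=1e9), seed=2)
mixed = sim.apply_mixing(src, np.array([[1.0], [0.6]]))
mixed.data += sim.generate_background(2, dur, sr, 0.0, 1.0, seed=3,
                                      channel_labels=["N1", "N2"]).data
n_t = int(0.5 * sr) + 1
data = np.stack([mixed.data[:, int(o * sr):int(o * sr) + n_t]
                 for o in onsets])
ep = EpochSet(data=data, sr=sr, tmin=0.0, tmax=0.5, lock="trial_end",
              labels=["perceived"] * n_trials,
              channel_labels=["MX1", "MX2"], channel_kinds=["EEG", "EEG"])
t = tf.tfr_decompose(ep, decim=2)
fsel = (t.freqs >= 38) & (t.freqs <= 42)
tsel = (t.times >= 0.1) & (t.times <= 0.3)
plv_mix = sy.plv(t, (0, 1))[np.ix_(fsel, tsel)].mean()
imcoh_mix = np.abs(sy.imcoh(t, (0, 1))[np.ix_(fsel, tsel)]).mean()
print()
print(f"zero-lag mixed source at 40 Hz: PLV = {plv_mix:.3f}, "
      f"|ImCoh| = {imcoh_mix:.3f}")
print()
print("High PLV with near-zero ImCoh is the signature of volume")
print("conduction; a genuinely lagged interaction would show both.")
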