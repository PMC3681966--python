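# perceptgamma

EEG analysis of **emergent perceptual states**: when does an ambiguous
stimulus turn into a coherent percept, and what does gamma-band activity do
at that moment?  `perceptgamma` is a reusable Python pipeline for the
analysis style used in holistic-perception EEG studies with two-tone
(Mooney) stimuli — rapid serial presentation of rare, short-lived targets,
and slowly rotating faces whose recognition moment varies from trial to
trial — together with a synthetic EEG generator that emulates both
paradigms so every stage can be validated end to end against known ground
truth.

It is aimed at EEG researchers and methods developers who want a tested,
scriptable implementation of this analysis chain without a MATLAB
toolchain.

## What it computes

* **Time–frequency (15–90 Hz, 1 Hz steps).**  Per-trial energy from a
  smoothed **pseudo Wigner–Ville distribution** of the analytic signal,

  `W(t,f) = h(0) r₀(t) + 2 Re Σ_{m>0} h(m) r_m(t) e^{−i4πfm/sr}`,
  `r_m(t) = ⟨x(t+m) x*(t−m)⟩_g`,

  with a Hamming lag window `h` (≈4 Hz smoothing) and a 50 ms Hamming time
  window `g` to suppress cross-terms; per-trial phase from a Gaussian
  narrow-band decomposition on the same grid.  Power is z-scored against a
  baseline: `z = (P − μ_base)/σ_base` per channel and frequency.
* **Synchrony.**  Inter-trial **phase-locking value**
  `PLV_ij(f,t) = |N⁻¹ Σ_n e^{i(φ_i − φ_j)}|` for all electrode pairs, and
  the **imaginary part of coherency**
  `ImCoh_ij = Im(S_ij / √(S_ii S_jj))`, which is blind to instantaneous
  volume-conduction mixing.
* **Statistics.**  Wilcoxon signed-rank / rank-sum and paired *t*
  contrasts per time point and per 15 Hz band (15–30, 30–45, 45–60,
  60–75 Hz), Holm step-down correction, contiguous significant-window
  extraction, and behaviour summaries (hit rate, detection time, report
  angle at 20°/s).
* **Decoding.**  A linear SVM on band- and channel-averaged normalized
  power over occipito-parietal channels, 30 repetitions of stratified
  3-fold cross-validation with inner selection of the regularization
  constant, metrics from pooled confusion matrices, and label-permutation
  significance with leave-one-out scoring.
* **Synthetic data.**  1/f^α background, Hann-enveloped tone bursts with
  von Mises inter-trial phase coupling (expected PLV = I₁(κ)/I₀(κ)),
  band-limited sustained gamma states, zero-lag mixing, blinks, and both
  paradigms' event/behaviour structure — fully seeded and byte-reproducible.

## Worked example

`examples/05_decode_perception.py` builds a rotating-stimulus dataset
(90 trials, 60 perceived; perceived trials carry a sustained 60–75 Hz
elevation of ≈3 baseline SD over the final 3 s), runs preprocessing,
time-frequency normalization and the decoder:

```text
features: 88 trials x 31 time points (2 trials excluded for responses inside the feature window)
accuracy:          100.00 +/- 0.00 %
sensitivity:       100.00 +/- 0.00 %
specificity:       100.00 +/- 0.00 %
balanced accuracy: 100.00 +/- 0.00 %
permutation p (199 label permutations, leave-one-out): 0.005
```

A ≈3 SD band-limited power difference is linearly separable, so the
decoder saturates; the permutation p of 0.005 (= 1/200, no permutation
beat the true labels) confirms the score is not a small-sample artifact.
The other examples print the behaviour summary (mean report angle ≈ 90°
from inverted), the localization of an injected 70 Hz burst (peak at
70 Hz, 390 ms for a 200–600 ms injection), the PLV-vs-Bessel-ratio
calibration, the volume-conduction contrast (PLV 0.999 vs |ImCoh| 0.003),
and the four-band contrast table in which only the burst-carrying 60–75 Hz
band survives Holm correction (z = −4.83).

A thin CLI mirrors the stages
(`perceptgamma run --config cfg.yaml`, `perceptgamma simulate ...`); see
`examples/06_full_pipeline.py` for the config schema and run manifest.

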