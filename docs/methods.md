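# Methods

This note documents the models, estimators and default parameters
implemented in `perceptgamma`, the reasoning behind the genuinely open
design choices, and the limits of what the synthetic-data validation can
show.

## Signal model of the generator

The generator produces continuous multi-channel EEG in µV as a sum of
independent components:

* **Background**: per-channel 1/f^α noise, made by shaping white Gaussian
  noise in the frequency domain with f^(−α/2) (DC removed) and rescaling
  to a target RMS.  Defaults: α = 1, RMS = 10 µV — a broadly realistic
  resting-EEG spectrum at desk scale.  Channels are independent by
  construction; any inter-channel correlation must come from the explicit
  mixing matrix, which keeps the noise model and the volume-conduction
  model separable.
* **Tone bursts**: `A · w(t) · cos(2πf t + φ_trial + k·lag)` with a Hann
  (raised-cosine) envelope `w` — a smooth, leakage-limited standard choice
  for transient oscillations.  Inter-trial phase coupling uses an
  **anchor convention**: the first burst channel carries the per-trial
  reference phase exactly, every other channel adds independent von
  Mises(0, κ) jitter.  The expected PLV between the anchor and a jittered
  channel is then the Bessel ratio I₁(κ)/I₀(κ) (κ = 0 gives uniform
  phases, κ ≥ 10⁶ is treated as perfect locking); between two jittered
  channels it is that ratio squared.  Calibration tests therefore measure
  anchor pairs.
* **Sustained band-limited states**: for the perception condition of the
  rotating-stimulus paradigm, band-passed (60–75 Hz) Gaussian noise with a
  Tukey envelope (0.5 s ramps) over the final 3 s of the movie,
  independent across channels and trials.  This models a sustained
  elevation of gamma power without a single coherent phase.  The default
  amplitude of 2.0 µV RMS was calibrated once against the generator's own
  baseline statistics so the band-averaged normalized power of perceived
  trials sits at ≈3 baseline SD under the default background, and then
  frozen.
* **Pre-report burst**: by default, perceived trials also receive a
  posterior 70 Hz tone burst (6 µV, 0.8 s) ending at the button press with
  κ = 2 coupling, modelling the rise of gamma activity and synchrony
  before the perceptual report.  It can be disabled or replaced.
* **Ocular artifacts**: 300 ms half-sine deflections at Poisson times,
  full amplitude on the two EOG channels and scaled on EEG channels by a
  frontal exponential decay profile over the unit-circle montage.
* **Paradigms**: rapid serial presentation (4.5 s trials of thirty 150 ms
  frames, exactly one target per trial drawn uniformly from the frame grid
  inside [1.5, 3.0] s, 2 s inter-trial gap) and rotating movies (12 s
  movies, 3 s gaps, 9 s rotation span; detection times truncated-normal
  with mean 4.30 s and SD 2.95 s on [1, 11] s, matching the
  trial-selection rule downstream).  Desk-scale defaults: 16 channels,
  500 Hz, 90 trials (60 perceived).  All randomness flows from one seed;
  identical configs are byte-identical.

What the generator does **not** emulate: biophysical forward models
(dipoles, lead fields, realistic channel covariance), muscle and saccadic
spike artifacts, non-stationary background (drowsiness, alpha bursts),
subject-to-subject variability beyond what callers script themselves.
Passing the validation suite therefore shows the *estimators and pipeline
plumbing* are correct on data satisfying their assumptions; it does not
show the assumptions hold for any particular real recording.

## Time–frequency estimation

Power comes from a **smoothed pseudo Wigner–Ville distribution** of the
analytic (Hilbert) signal, evaluated on a 15–90 Hz grid at 1 Hz steps:
lag products `r_m(t) = x(t+m)x*(t−m)` are smoothed along time with a
Hamming window `g`, weighted with a Hamming lag window `h` of `sr/4`
samples (≈4 Hz frequency smoothing), and transformed at the requested
frequencies.  The quadratic transform's oscillatory cross-terms are
attenuated by `g`: a cross-term between components at f₁ and f₂ beats at
|f₁ − f₂|.  We use **g of 50 ms**, whose spectral zeros fall at multiples
of 20 Hz, nulling the beats between bands spaced 20/40 Hz apart (a 25 ms
Hamming window passes ≈23 % of a 40 Hz beat, which left two-tone
cross-terms at ≈28 % of ridge energy; 50 ms brings this below 1 % while
still localizing a 400 ms burst to within one decimated sample).
Negative values, which the pseudo-WVD can produce off-ridge, are clipped
to zero with the clipped fraction logged (typically ≈0.3 for broadband
noise input, concentrated far off-ridge).

The pseudo-WVD is real and carries no phase, so phase (and the complex
coefficients used for coherency) comes from an auxiliary **Gaussian
narrow-band decomposition**: convolution with Gaussian-windowed complex
exponentials of 4-cycle support per frequency, on the same (decimated)
time grid.  The default decimation keeps every 10th sample (50 Hz frame
rate at the default 500 Hz), which oversamples the ≤15 Hz bandwidth of
every analysis band.

**Baseline z-normalization** computes, per channel and frequency, the mean
and SD of the across-trial-average power over the baseline window and
applies them to every trial, so the average map has baseline mean 0 / SD 1
by construction.  Baselines: pre-stimulus interval for the
rapid-presentation paradigm; for the rotating paradigm either the earliest
500 ms of the epoch or — for condition contrasts — the no-perception
condition's map (`normalize_to_reference`), which z-scores perception maps
against the across-time distribution of the unperceived state.  The
evoked (trial-average) component can be subtracted before decomposition
(`induced=True`); the default keeps it, since the lock events of interest
here are reports, not stimuli.

## Synchrony

PLV and coherency are estimated **across trials at each time-frequency
bin** (not by Welch averaging over time), so synchrony maps share the
TFR's time resolution.  Coherency uses the complex narrow-band
coefficients: `C_ij = ⟨a b*⟩ / √(⟨|a|²⟩⟨|b|²⟩)`; its imaginary part is
exactly zero for any instantaneous mixing of a common source, which is the
volume-conduction null the stress tests exercise (the observed band-
averaged |ImCoh| is compared against a trial-shuffle null).  Bins where a
channel has zero power are undefined and propagate as NaN, excluded from
summaries with counts logged.  The PLV estimator is positively biased
under independence (E ≈ √(π/4N), ≈0.044 at N = 400 trials); calibration
checks account for this by averaging many independently jittered pairs
rather than widening tolerances.

## Preprocessing

Order is fixed and recorded in provenance: average re-reference (good EEG
channels only; EOG/BAD excluded and untouched) → zero-phase FIR band-pass
(Hamming design, transition width 25 % of the high-pass cutoff, applied by
centred convolution so a single pass is zero-phase) → epoching →
amplitude-based trial rejection → optional EOG regression → rule-based
trial selection.  Amplitude rejection is per-trial (post-epoching) and
idempotent; the rapid-presentation variant uses ±75 µV on EEG with
±100 µV on EOG, the rotating-stimulus variant ±100 µV on all channels.
Ocular correction defaults to least-squares EOG regression — a
deterministic, testable substitute for manual independent-component
selection.  Unperceived rotation trials are locked to the movie midpoint
(onset + 6 s); epochs running past the recording edges are dropped and
counted, never zero-padded (padding would bias time-frequency baselines).

## Statistics

Per-timepoint maps use the Wilcoxon signed-rank test for paired data
(exact p for n ≤ 25, normal approximation with continuity correction
beyond; the reported z always carries the continuity correction) and the
rank-sum test for independent conditions.  Band-level contrasts use the
paired t-test with the sign convention that negative t on (no-perception −
perception) means perception was higher.  Exactly identical conditions
return the no-effect convention (statistic 0, p 1); constant non-zero
differences raise, since the t statistic is then infinite.  Holm's
step-down correction (via statsmodels) is applied over time points within
a band for maps and over the four-band family for band contrasts; the
family is configurable.  Significant windows are maximal runs of corrected
rejections with a minimum-duration filter.

Calibration of these tools is asserted by Monte-Carlo: the per-timepoint
type-I error must fall in [0.035, 0.065] at α = 0.05, and the
family-wise error of the Holm-corrected four-band contrast must not exceed
α over 500 null replicates.  The FWER check is a binomial estimate with
SD ≈ 0.01 at 500 replicates, so the assertion admits the one-sided 95 %
fluctuation of the estimator around α; the null generator gives band
differences a shared subject component (bands computed from the same
trials are correlated in practice), under which Holm is conservative.

## Decoding

Features are normalized power averaged over the occipito-parietal roster
(C1/Cz/C2, CP1/3/z/2/4, P1/z/4, PO9/7/5/3/z/4/6/8/10, O1/z/2 — intersected
with the montage in use) and over a band's frequency bins, keeping the
time axis (decimated to 10 Hz by default; a collapse-to-scalar mode
exists).  The feature window is the final 3 s of the movie; perceived
trials whose response falls inside that window are excluded so motor
activity cannot leak into the features.  The classifier is a linear SVM.
Per repetition, stratified 3-fold cross-validated predictions are pooled
into one confusion matrix per candidate C (log-spaced grid 10⁻³…10³), C is
chosen by balanced accuracy, and that C's pooled metrics are the
repetition's metrics; 30 repetitions with re-shuffled folds give the
reported mean ± SD.  Standardization is fit on training folds only (a
leakage canary test guards this).  The positive class is *perceived*, so
sensitivity is perceived-trial recall.  Class imbalance is handled by
stratification only — metrics are reported raw.

The permutation test scores both the observed and permuted labelings with
leave-one-out cross-validation at fixed C and reports
`p = (1 + #{permuted ≥ observed}) / (1 + n_permutations)`.  Its inner loop
runs tens of thousands of fits in calibration settings, so it uses a
numba-compiled dual coordinate-descent solver of the *same* objective as
`LinearSVC(dual=True)`; a test asserts the compiled solver's solution is
at least as optimal as the library's on random problems.  All other model
fitting uses scikit-learn directly.

## Numerical and interface choices

* Sample indexing is 0-based; epoch time zero is the first sample at or
  after the lock event; epoch windows are inclusive of both endpoints
  (`round((tmax−tmin)·sr)+1` samples).
* Container invariants (unique labels, event bounds, label counts,
  PLV/ImCoh ranges) are enforced at construction, not at use.
* Continuous data travel as EDF (16-bit interchange; quantization step =
  physical range / 32767 per channel) or as a lossless HDF5 container with
  a JSON metadata block; events and behaviour logs are CSV.
* Montages are derived from the standard 10-05 electrode system by
  azimuthal-equidistant projection to a unit head circle (vertex at the
  origin).  The 128-channel layout is a best-effort extension of the
  64-channel 10-10 set with the nearest additional 10-05 sites, since no
  canonical 128-label list exists for this cap family.
* Pipeline configs are YAML with a mandatory seed; every stage output is
  content-hashed into a run manifest, and a rerun with the same config
  reproduces identical hashes.

## Problem sizes

The validation suite and the reproduction script run the full pipeline at
desk scale — 16 channels, 500 Hz, 90 rotating-stimulus trials (or 20–40
rapid-presentation trials), TFR decimation 10 — which keeps any single
check under a minute while leaving every estimator mathematically
identical to its full-scale form (all analyses are sampling-rate- and
channel-count-agnostic).

## Known limitations

* The pseudo-WVD clip fraction is substantial for broadband noise input;
  clipped energy is off-ridge but the logged fraction should be monitored
  when changing smoothing windows.
* EOG regression removes any EEG genuinely correlated with EOG, and the
  optional ICA hook is intentionally not the default; neither reproduces
  manual component selection.
* ImCoh's blindness to zero-lag coupling also hides genuinely
  instantaneous neural coupling, and its magnitude depends on the phase
  lag, not only the coupling strength.
* The generator's decoding problem is easier than real single-trial EEG at
  matched normalized effect size because its noise is stationary and its
  artifact model is minimal; saturated accuracies on synthetic data should
  be read as "the pipeline recovers the injected effect", not as a
  forecast of real-data performance.
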