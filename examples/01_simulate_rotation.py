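"""Generate a rotating-stimulus dataset and summarize its behaviour.

The paradigm: two-tone face movies rotate from inverted to upright over
9 s (then hold for 3 s); the observer presses a button on recognizing the
face.  Detection times follow a truncated normal on [1, 11] s, so the
mean report angle sits near the orthogonal position.
"""

from perceptgamma import simulate as sim
from perceptgamma.stats import behaviour_summary

cfg = sim.SynthConfig(seed=42, n_trials=60, perceived_probability=0.9)
recording, events, behaviour = sim.generate_rotation_dataset(cfg)

print(f"recording: {recording.n_channels} channels x "
      f"{recording.duration:.0f} s at {recording.sr:.0f} Hz")
summary = behaviour_summary(behaviour)
print(f"hit rate: {summary['hit_rate_pct']:.1f} %")
print(f"detection time: {summary['detection_mean_s']:.2f} "
      f"+/- {summary['detection_sd_s']:.2f} s")
print(f"mean report angle: {summary['mean_angle_deg']:.0f} deg from inverted")
print()
print("The report angle is detection time x 20 deg/s (capped at 180 deg):")
print("a value near 90 deg means faces were recognized only once the")
print("stimulus approached the upright-half of its rotation.")
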