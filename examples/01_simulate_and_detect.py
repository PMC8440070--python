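"""Simulate a noisy single-lead record, clean it, and find the heartbeats.

Builds a 60-beat record with all five beat classes and the default noise
(baseline wander, 50 Hz hum, white noise), removes the noise, runs the
difference-threshold QRS detector and compares against the simulator's
ground truth.
"""

import numpy as np

import ecgfuse as ef

mix = {c: 0.2 for c in ef.CLASSES}
record = ef.generate_record(n_beats=60, class_mix=mix, rng_seed=0)
clean = ef.preprocess(record.signal)
detected = ef.detect_r_peaks(clean)

hits = [int(np.min(np.abs(detected - t))) for t in record.true_r_indices]
print(f"simulated beats : {record.true_r_indices.size}")
print(f"detected peaks  : {detected.size}")
print(f"sensitivity     : {np.mean([h <= 10 for h in hits]):.3f}")
print(f"median |error|  : {np.median(hits):.1f} samples")
# sensitivity is the fraction of true beats matched within 10 samples
# (~28 ms at 360 Hz); the median timing error shows detector precision.
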