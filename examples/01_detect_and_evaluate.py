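"""Detect pulse onsets in a clean synthetic CBFV scan and score them.

Generates five minutes of normal-morphology beats at ~70 bpm, runs the
full detection pipeline (band-pass -> moving difference filter ->
adaptive thresholding -> beat-length repair -> alignment), and compares
the detected onsets against the generator's ground truth.
"""

import numpy as np

from pulseonset import detect_pulses, evaluate, generate_scan

scan = generate_scan(
    duration_s=300.0, hr_mean_bpm=70.0, hr_sd_bpm=3.0,
    morphology="normal", sampling_rate=125.0, seed=7,
)
result = detect_pulses(scan.signal)
report = evaluate(scan.truth.onsets, result.onsets, scan.signal.sampling_rate)

print(f"beats in scan:        {len(scan.truth)}")
print(f"onsets detected:      {result.onsets.size}")
print(f"TP / FN / FP:         {report.tp} / {report.fn} / {report.fp}")
print(f"TPR / PPV:            {report.tpr:.5f} / {report.ppv:.5f}")
print(f"mean |dt|:            {report.mean_abs_offset_ms:.2f} ms")
print(f"max |dt|:             {np.abs(report.offsets_ms).max():.1f} ms")
print(f"onsets within 10 ms:  {report.proportion_within[10.0]:.4f}")

# TPR = TP/(TP+FN) and PPV = TP/(TP+FP); |dt| is the temporal offset
# between each detected onset and its paired true onset.  On clean data
# every beat should be found (TPR = PPV = 1) with offsets within one or
# two samples (8-16 ms at 125 Hz).
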