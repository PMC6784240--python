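"""Measure E/A waves and the profile spectrum from an extracted envelope.

Runs the full pipeline configuration (smoothing on, both methods averaged),
converts edge rows to cm/s with the display calibration (0.34 cm/s per
row, 1.9 ms per column), picks the per-beat E and A peaks, and shows the
high-frequency content of the velocity profile with and without smoothing.
"""

import numpy as np

from dopplertrace import (
    AxisCalibration, SmoothingParams, SynthSpec, ThresholdParams, average_profiles,
    crop_roi, detect_edges_method1, detect_edges_method2, generate, measure_waves,
    profile_spectrum, rows_to_velocity, smooth_image,
)

cal = AxisCalibration()
print(f"sampling frequency along the time axis: {cal.sampling_frequency():.1f} Hz")

img, gt = generate(SynthSpec(seed=1), cal)
roi = gt.roi
a = ThresholdParams().window_for(roi)

hf = {}
for smoothed in (False, True):
    work = crop_roi(img, roi)
    if smoothed:
        work = smooth_image(work, SmoothingParams(p=3, q=3))
    e1 = detect_edges_method1(work, roi, 0.3)
    e2 = detect_edges_method2(work, roi, 0.05, a)
    pos, neg = rows_to_velocity(average_profiles(e1, e2), roi, cal)
    f, m = profile_spectrum(pos)
    hf[smoothed] = float(np.sum(m[f > 20.0] ** 2))
    if smoothed:
        w = measure_waves(pos)
        print(f"detected {w.n_beats} beats on the smoothed averaged profile")
        print(f"E wave: {w.e_wave:.2f} cm/s (truth {gt.e_wave:.2f})")
        print(f"A wave: {w.a_wave:.2f} cm/s (truth {gt.a_wave:.2f})")

print(f"spectral power above 20 Hz: raw {hf[False]:.3g}, smoothed {hf[True]:.3g} "
      f"(ratio {hf[True] / hf[False]:.4f})")
print()
print("E and A are the early-diastolic and atrial-contraction peaks of mitral")
print("inflow; the sharp drop in >20 Hz power confirms that smoothing removes")
print("the sudden column-to-column jumps rather than the physiological waves.")
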