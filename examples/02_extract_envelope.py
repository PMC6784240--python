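"""Extract the peak-velocity envelope with both thresholding methods.

On a noise-free, hard-edged spectrogram both searches recover the true
envelope exactly; under moderate noise the border-inward search (method 1,
theta1 = 0.3) underestimates slightly and picks up occasional speckle
outliers, while the baseline-outward search (method 2, theta2 = 0.05)
overestimates slightly.  Averaging the two balances the envelopes.
"""

import numpy as np

from dopplertrace import (
    AxisCalibration, SynthSpec, ThresholdParams, average_profiles,
    detect_edges_method1, detect_edges_method2, generate,
)

cal = AxisCalibration()

for label, spec in (
    ("noise-free, hard edges", SynthSpec(noise_sd=0, speckle_density=0, decay=0, seed=0)),
    ("moderate noise + speckle", SynthSpec(seed=0)),
):
    img, gt = generate(spec, cal)
    a = ThresholdParams().window_for(gt.roi)
    e1 = detect_edges_method1(img, gt.roi, theta1=0.3)
    e2 = detect_edges_method2(img, gt.roi, theta2=0.05, a=a)
    avg = average_profiles(e1, e2)
    print(f"{label}:")
    for name, prof in (("method 1", e1), ("method 2", e2), ("averaged", avg)):
        err = np.nanmean(np.concatenate(
            [np.abs(prof.upper - gt.upper_row), np.abs(prof.lower - gt.lower_row)]))
        med = np.nanmedian(np.concatenate(
            [np.abs(prof.upper - gt.upper_row), np.abs(prof.lower - gt.lower_row)]))
        print(f"  {name}: mean |edge error| = {err:.3f} rows, median = {med:.1f} rows")
    print()

print("Mean error in rows; one row is 0.34 cm/s.  The raw mean error under")
print("noise is dominated by a few speckle-outlier columns (the median stays")
print("at zero), which is exactly the artifact smoothing is meant to remove.")
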