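"""Bland-Altman agreement between the two methods, before and after smoothing.

Quantifies how a (2p+1) x (2q+1) moving average changes the agreement of
the two thresholding searches: the SD of their per-column differences
drops sharply (speckle outliers are suppressed) while the bias magnitude
grows (smoothing pushes the two envelopes apart on the flanks).
"""

import numpy as np

from dopplertrace import (
    AxisCalibration, SmoothingParams, SynthSpec, ThresholdParams, bland_altman,
    crop_roi, detect_edges_method1, detect_edges_method2, generate, smooth_image,
)

cal = AxisCalibration()
img, gt = generate(SynthSpec(seed=0), cal)
roi = gt.roi
a = ThresholdParams().window_for(roi)

print("positive envelope, method 1 - method 2 differences (pixels):")
for smoothed in (False, True):
    work = crop_roi(img, roi)
    if smoothed:
        work = smooth_image(work, SmoothingParams(p=3, q=3))
    e1 = detect_edges_method1(work, roi, 0.3)
    e2 = detect_edges_method2(work, roi, 0.05, a)
    st = bland_altman(roi.y_base - e1.upper, roi.y_base - e2.upper)
    tag = "smoothed (p=q=3)" if smoothed else "raw image      "
    print(f"  {tag}: bias {st.bias:7.2f}  SD {st.sd:6.2f}  "
          f"95% limits [{st.loa_low:7.2f}, {st.loa_high:6.2f}]")

print()
print("One pixel is 0.34 cm/s.  Smoothing tightens the limits of agreement")
print("(smaller SD) but increases |bias|: the two methods' envelopes separate")
print("because the blur displaces each threshold crossing outward.")
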