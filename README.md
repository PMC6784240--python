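# dopplertrace

Automated extraction of **peak blood-velocity profiles** from pulsed-Doppler
echocardiography spectrograms.

A spectral Doppler display is an image whose columns are time, rows are
velocity, and brightness is the Doppler signal power at that velocity: the
zero-velocity baseline is a horizontal row, flow toward the transducer is
drawn above it, flow away below it. Clinicians read peak velocities and
cardiac time intervals off this display by hand; `dopplertrace` delineates
the bright Doppler region column by column so that the velocity envelope —
and quantities derived from it, such as the mitral-inflow **E** and **A**
peaks — can be measured automatically. The extracted envelopes are also
suitable as inlet boundary conditions for computational hemodynamics.

## The method

Within a user-supplied region of interest (rows `n_up … n_lo`, baseline
`Y_base`) each pixel column *X* is scanned with two complementary
intensity-thresholding searches, both relative to the column's maximum
intensity µ<sub>max,X</sub>:

* **Method 1** (border-inward, velocity *lower* limit): the upper edge is
  the smallest row Y and the lower edge the largest row Y with
  µ(X, Y) > θ₁ µ<sub>max,X</sub>. A relatively large θ₁ (default 0.3)
  resists artifacts near the ROI borders.
* **Method 2** (baseline-outward, velocity *upper* limit): anchor on the
  maximum intensity inside a window of *a* rows next to the baseline, walk
  from that maximum toward the ROI border, and stop at the first row with
  µ(X, Y) < θ₂ µ<sub>max,X</sub>; the edge is the last row still at or
  above the cutoff. A small θ₂ (default 0.05) follows the envelope out to
  its faint rim.

Averaging the two profiles, P<sub>avg</sub> = (P₁ + P₂)/2, combines the
under- and over-estimate. Optionally the image is first smoothed with a
(2p+1)×(2q+1) moving average (default p = q = 3),

µ<sub>smooth</sub>(X, Y) = Σ µ(i, j) / ((2p+1)(2q+1)),

which suppresses the speckle-driven outlier columns of the raw profiles.
Edge rows become physical velocities through the display calibration
(defaults: 0.34 cm/s per row, 1.9 ms per column, i.e. ≈526 Hz sampling).
Downstream analytics: per-beat E/A peak detection, Bland–Altman limits of
agreement (bias ± 1.96 SD) between the two methods, and magnitude spectra
of the profiles. Threshold choice is guided by the bimodal ROI histogram
(background mode at black, foreground mode near 175 of 255): any fraction
that puts θ·µ<sub>max</sub> between the modes separates signal from
background.

Unlike gradient detectors (e.g. Canny), which may fire any number of times
per column, these searches return **exactly one upper and one lower edge
per column** wherever signal exists — so the envelope is always a pair of
single-valued traces.

A synthetic-spectrogram generator (`dopplertrace.synth`) renders beats of
mitral-inflow shape (E and A lobes above the baseline, one systolic lobe
below, foreground level 175, Gaussian noise plus sparse bright speckle,
optional corner text artifact) with exact per-column ground-truth
envelopes, so every stage is testable without clinical images.

## Worked example

```python
import numpy as np
from dopplertrace import (AxisCalibration, SynthSpec, ThresholdParams,
                          average_profiles, detect_edges_method1,
                          detect_edges_method2, generate)

cal = AxisCalibration()                      # 0.34 cm/s, 1.9 ms per pixel
img, gt = generate(SynthSpec(seed=0), cal)   # 400 x 1280 px, 3 beats
a = ThresholdParams().window_for(gt.roi)
e1 = detect_edges_method1(img, gt.roi, theta1=0.3)
e2 = detect_edges_method2(img, gt.roi, theta2=0.05, a=a)
avg = average_profiles(e1, e2)
err = np.nanmean(np.abs(avg.upper - gt.upper_row))
print(f"mean |edge error| of the averaged profile: {err:.2f} rows")
```

The narrative scripts in `examples/` each run one capability end to end.
`python examples/04_waves_and_spectrum.py` prints, for a seeded synthetic
image:

```
sampling frequency along the time axis: 526.3 Hz
detected 3 beats on the smoothed averaged profile
E wave: 67.15 cm/s (truth 66.98)
A wave: 71.85 cm/s (truth 72.08)
spectral power above 20 Hz: raw 1.47e+07, smoothed 1.2e+05 (ratio 0.0082)
```

i.e. the early-diastolic and atrial peaks are recovered to a fraction of
a cm/s, and smoothing removes the high-frequency column-to-column jumps
without touching the physiological waves. `examples/03` prints the
Bland–Altman agreement between the two methods before and after smoothing
(SD 24.8 px → 4.8 px on the positive envelope, while |bias| grows), and
`examples/05` the Canny threshold sweep contrast.

A thin CLI wraps the same pipeline for shell use:

```bash
dopplertrace synth -o demo/                          # image + truth + config
dopplertrace extract demo/config.yaml demo/spectrogram.png -o demo/out --figures
dopplertrace suggest-thresholds demo/config.yaml demo/spectrogram.png
dopplertrace evaluate demo/config.yaml demo/spectrogram.png -o demo/eval
```

## Layout

- `src/dopplertrace/image_model.py` — image/ROI/calibration types, grayscale, histograms
- `src/dopplertrace/edges.py` — the two per-column thresholding searches, profile averaging
- `src/dopplertrace/smoothing.py` — moving-average filter
- `src/dopplertrace/analysis.py` — calibration to cm/s, E/A waves, Bland–Altman, spectra
- `src/dopplertrace/synth.py` — synthetic spectrograms with ground truth
- `src/dopplertrace/evaluation.py` — Canny baseline contrast, edges-per-column metric
- `src/dopplertrace/pipeline.py`, `config.py`, `io.py`, `plots.py`, `cli.py` — orchestration

See `docs/methods.md` for the full account of the model, parameters, and
design choices.
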