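# Methods

## The extraction model

A pulsed-Doppler spectrogram is treated as a scalar intensity function on
a raster: columns index time, rows index velocity, the operator supplies
the ROI rows `n_up < Y_base < n_lo` (inclusive borders) and the
zero-velocity baseline `Y_base`, all read off the machine display. Indices
are 0-based internally; published pseudo-code in this area is commonly
1-based, so a constant +1 maps between the conventions. Cropping records
the row offset so every reported edge row is in original-frame
coordinates.

Two per-column searches delineate the bright Doppler region, both
thresholding *relative to the column's maximum intensity* — which makes
the edges invariant to any positive rescaling of a column's intensities:

1. **Border-inward search** (`detect_edges_method1`, threshold θ₁): the
   upper/lower edge is the smallest/largest ROI row with
   µ > θ₁·µ_max strictly. The definition is order-free (no scan-direction
   dependence) and is implemented as a vectorised first/last `argmax` over
   the boolean exceedance mask. Because the search effectively begins at
   the ROI borders, any bright annotation inside the ROI (text overlays)
   captures it; an optional mask zeroes such pixels first. This method
   yields a velocity **lower limit**.
2. **Baseline-outward search** (`detect_edges_method2`, threshold θ₂,
   window *a*): the anchor µ_max is taken over the `a+1` rows next to the
   baseline (ties to the first row, as for every maximum here); the scan
   walks from the anchor row toward the ROI border and stops at the first
   row strictly below θ₂·µ_max; the edge is the last row at or above the
   cutoff, or the ROI border if the cutoff is never crossed. This yields a
   velocity **upper limit**. The published pseudo-code for this method
   contains a row-range expression inconsistent with its prose; this
   implementation follows the prose and the stated intent (an
   overestimating envelope anchored near zero velocity). The printed
   variant would take the first sub-threshold row itself — a one-row
   difference.

Columns (or half-columns for method 2) whose scanned range is entirely
zero carry no signal and are marked *missing* (NaN); downstream conversion
maps missing to 0 cm/s — the physiological null — with an explicit flag.
Averaging the two methods' profiles is a per-column arithmetic mean;
a present value paired with a missing one passes through unchanged.

The structural guarantee that distinguishes these searches from gradient
edge detection: each returns exactly one upper and one lower edge (or an
explicit missing marker) per column, never more.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| θ₁ | method-1 fraction of µ_max | 0.3 | large enough to resist border artifacts; reference operating point |
| θ₂ | method-2 fraction of µ_max | 0.05 | small, to follow the envelope to its faint rim |
| *a* | method-2 anchor window (rows) | 10% of ROI half-height | no published value exists; the window's purpose is only to anchor µ_max near zero velocity, so it should be small relative to the ROI |
| p, q | smoothing half-sizes (cols, rows) | 3, 3 | 7×7 window, the reference smoothing configuration |
| velocity_per_pixel | cm/s per row | 0.34 | display calibration of the reference acquisition |
| time_per_pixel | ms per column | 1.9 | display sweep of 75 mm/s at the reference pixel pitch |

The sampling frequency of extracted profiles is derived as
1000/`time_per_pixel` = 526.3 Hz rather than hard-coded: the reference
acquisition is variously described with a rounded 532 Hz, which is
inconsistent with 1.9 ms/pixel by ~1%; deriving from the pixel clock keeps
the two calibrations coherent.

Strict inequalities are used exactly as defined (µ > θ₁µ_max to keep a
pixel in method 1; µ < θ₂µ_max to stop method 2); since θ₁ < 1, a column
with any non-zero pixel always yields an edge in method 1.

## Smoothing

`smooth_image` is the (2p+1)×(2q+1) arithmetic moving average, computed in
floating point. Near the borders the window shrinks to its intersection
with the image and the mean is taken over available pixels only — no pixel
values are invented, and a constant image is an exact fixed point. It is
implemented as a ratio of two uniform filters (sum over window / count in
window). Smoothing operates on the cropped ROI, not the full frame, so
display annotations outside the ROI cannot bleed in.

Two consequences, both visible in the test suite and acceptance numbers:

* smoothing crushes impulsive speckle (a 255 spike spreads to ≤ 255/49),
  removing the outlier columns of raw profiles — the Bland–Altman SD
  between the two methods drops several-fold and the spectral power of the
  profiles above 20 Hz drops by ~2 orders of magnitude;
* smoothing systematically displaces each threshold crossing *outward* by
  up to ~q rows on flat envelope stretches and by ~p×(envelope slope) rows
  on steep flanks (mitral E/A flanks are ~4–7 rows/column at this
  calibration). The two methods separate — |bias| between them grows —
  and the mean absolute edge error versus ground truth increases even as
  outliers vanish. Smoothing therefore trades accuracy of the edge
  *location* for robustness of the edge *trace*; the per-column median
  error is a fairer accuracy measure for raw profiles, the mean for
  smoothed ones.

## E/A wave measurement

No standard procedure comes with the extraction method, so a minimal
peak-picking scheme is used and flagged as an interpretation: local maxima
of the positive (inflow) trace with at least `min_prominence` (default
10 cm/s) and `min_separation` (default 0.12 s) are grouped into beats —
a new beat starts when the inter-peak interval exceeds `beat_gap`
(default 0.4 s, above the typical E-to-A interval and below the A-to-next-E
interval at resting heart rates). Within a beat the earlier peak is E and
the later is A (mitral-inflow order); a one-peak beat reports E with A
absent; more than two peaks keep the two most prominent. Fewer than two
qualifying peaks overall give an explicit "insufficient peaks" status.
Means and sample SDs across beats are reported alongside per-beat values.
Waves should be measured on the smoothed averaged profile — on raw
profiles, speckle-outlier peaks can defeat the beat grouping.

## Agreement and spectra

Bland–Altman agreement uses per-column differences of the two methods'
baseline-relative displacements (`Y_base − edge_row`, pixel units,
convertible to cm/s via the calibration), separately for the positive and
negative envelopes; pairs with a missing entry are dropped, the SD is the
sample (n−1) estimate, and the limits are bias ± 1.96 SD.

`profile_spectrum` returns the one-sided magnitude of the unnormalised DFT
of the mean-removed profile on a frequency grid up to 1/(2·dt). Mean
removal keeps the DC term from masking the fluctuation content of
interest. Parseval's relation for this convention,
|X₀|² + 2Σ₀<k<N/2|X_k|² + |X_{N/2}|² = N·Σx², is asserted in the tests.

## The synthetic-data generator

`generate` renders what the extraction stages need from a spectrogram and
nothing more: a dark background; a bright filled Doppler region at
foreground level 175 (the foreground mode of real ROI histograms); per
beat, a raised-cosine E lobe then A lobe above the baseline and one
systolic lobe below (defaults 67, 72 and 40 cm/s — mitral-inflow
magnitudes in the 65–75 cm/s range, with A > E); a two-row near-baseline
clutter band present throughout the cycle; an optional linear intensity
ramp over the outer `decay`-fraction of each lobe (default 0.02, an edge
transition of a few rows); additive Gaussian noise (default SD 12, ~7% of
foreground); sparse bright speckle spots (default density 2·10⁻⁴ of ROI
pixels, so a few percent of columns carry an impulsive artifact — the
feature that makes raw border-inward profiles show outlier columns); and
an optional bright dashed text block in the upper-left ROI corner, the
annotation artifact that derails the border-inward search. `beats` beat
periods exactly fill the image width (defaults: 3 beats across 1280
columns at 1.9 ms/column ≈ 0.81 s per beat). Everything is deterministic
per seed, and the exact discretised envelope rows and E/A peak values are
returned as ground truth.

What the generator does **not** emulate: physically realistic multiplicative
speckle statistics, spectral broadening that varies with velocity,
aliasing/wrap-around, ECG traces, beat-to-beat variability, or machine
color overlays. Passing tests therefore demonstrate the algorithmic
properties of the extractor (correct search semantics, structural
guarantees, calibration arithmetic, the qualitative smoothing trade-off),
not clinical-grade accuracy on real exams.

## Problem sizes and numerical choices

Synthetic images are 400×1280 (three beats at display calibration) in the
end-to-end tests and acceptance script; oracle-equivalence checks use one
hundred 64×64 random images against exhaustive per-column scans,
bit-exact. Intensity ties in any maximum resolve to the first (smallest)
row. Histogram bins round intensities to the nearest integer. Averaged
profiles may hold half-integer rows; rasterisation for edge-counting
rounds to the nearest row. The moving average is exact up to floating
error (~1 ulp), and window-larger-than-image is rejected rather than
clipped.

## Known limitations

* The baseline row and ROI are operator-supplied; no auto-detection of the
  machine's baseline overlay or annotations (masking is manual).
* One envelope pair per column: aliased (wrapped) Doppler traces are out
  of scope.
* The E/A procedure assumes resting-rate beat structure; fused E/A peaks
  (tachycardia) will be reported as a single wave.
* Frames of a video are processed independently; no stitching of the
  sweeping display across frames.
* The Canny comparison is metric-based (edges per column, pixel counts
  across a threshold sweep), not pixel-exact, since detector internals
  vary between library implementations.
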