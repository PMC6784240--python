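"""Synthetic pulsed-Doppler spectrograms with known ground-truth envelopes.

The generator emulates the structure of a mitral-inflow spectral Doppler
display: a dark background, a bright filled Doppler region whose intensity
histogram peaks near 175 of 255, an E lobe followed by an A lobe above the
zero-velocity baseline in each beat, one systolic lobe below it, additive
Gaussian noise plus sparse bright speckle spots (the impulsive display
noise that produces outlier columns in raw extracted profiles), and
(optionally) a bright text overlay in the upper-left ROI corner of the
kind that derails border-inward edge searches.  Every image carries its exact per-column envelope rows, so each
processing stage can be validated without clinical data.

Lobe shapes are raised cosines; the exact shape is immaterial because the
discretised envelope is stored as ground truth rather than assumed
downstream.  A thin two-row band of foreground around the baseline mimics
the near-zero-velocity clutter that real displays show throughout the
cardiac cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_model import AxisCalibration, GrayImage, RegionOfInterest

__all__ = ["SynthSpec", "GroundTruth", "generate"]

# rows of bright near-baseline clutter always present on each side
_CLUTTER_ROWS = 2

# lobe timing as fractions of the beat: (center, width)
_E_LOBE = (0.50, 0.20)
_A_LOBE = (0.78, 0.18)
_SYS_LOBE = (0.20, 0.30)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic spectrogram.

    Velocities are in cm/s and are converted to rows through the
    :class:`AxisCalibration` passed to :func:`generate`.  ``decay`` is the
    fraction of each column's lobe height over which the intensity ramps
    down toward the envelope edge (0 gives a hard edge); ``beats`` beat
    periods exactly fill the image width.
    """

    n_rows: int = 400
    n_cols: int = 1280
    baseline_row: int = 250
    beats: int = 3
    e_height: float = 67.0
    a_height: float = 72.0
    sys_height: float = 40.0
    foreground_level: float = 175.0
    noise_sd: float = 12.0
    decay: float = 0.02
    speckle_density: float = 2e-4
    text_artifact: bool = False
    seed: int = 0
    roi_margin: int = 10

    def __post_init__(self) -> None:
        if min(self.e_height, self.a_height, self.sys_height) < 0:
            raise ValueError("lobe heights must be >= 0")
        if not 0 < self.foreground_level <= 255:
            raise ValueError(f"foreground_level must be in (0, 255], got {self.foreground_level}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.speckle_density < 1:
            raise ValueError("speckle_density must be in [0, 1)")
        if not 0 <= self.decay < 1:
            raise ValueError(f"decay must be in [0, 1), got {self.decay}")
        if self.beats < 1:
            raise ValueError("need at least one beat")


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-column envelope of a generated image.

    ``upper_row``/``lower_row`` are the outermost foreground rows above and
    below the baseline, in image coordinates.  ``e_wave``/``a_wave`` are
    the discretised peak velocities actually drawn (cm/s), and ``roi`` is a
    region of interest enclosing the envelope with margin.
    """

    upper_row: np.ndarray
    lower_row: np.ndarray
    e_wave: float
    a_wave: float
    roi: RegionOfInterest


def _lobe(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of unit height on the beat-phase axis."""
    d = phase - center
    inside = np.abs(d) < width / 2
    out = np.zeros_like(phase)
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * d[inside] / width))
    return out


def generate(spec: SynthSpec, cal: AxisCalibration) -> tuple[GrayImage, GroundTruth]:
    """Render a spectrogram and its exact envelope; deterministic per seed."""
    vpp = cal.velocity_per_pixel
    period_cols = spec.n_cols / spec.beats
    phase = (np.arange(spec.n_cols) / period_cols) % 1.0

    v_pos = spec.e_height * _lobe(phase, *_E_LOBE) + spec.a_height * _lobe(phase, *_A_LOBE)
    v_neg = spec.sys_height * _lobe(phase, *_SYS_LOBE)

    band_pos = np.maximum(np.rint(v_pos / vpp).astype(int), _CLUTTER_ROWS)
    band_neg = np.maximum(np.rint(v_neg / vpp).astype(int), _CLUTTER_ROWS)
    upper_row = spec.baseline_row - band_pos
    lower_row = spec.baseline_row + band_neg

    m = spec.roi_margin
    roi = RegionOfInterest(n_up=m, n_lo=spec.n_rows - 1 - m, y_base=spec.baseline_row)
    if upper_row.min() <= roi.n_up or lower_row.max() >= roi.n_lo:
        raise ValueError(
            "envelope exceeds the ROI: reduce lobe heights or enlarge the image"
        )

    rr = np.arange(spec.n_rows)[:, None]
    nd_pos = np.ceil(spec.decay * band_pos).astype(int)
    nd_neg = np.ceil(spec.decay * band_neg).astype(int)

    # intensity factor ramps linearly over the outer nd rows of each span
    dist_up = rr - upper_row[None, :]
    in_up = (dist_up >= 0) & (rr <= spec.baseline_row)
    fac_up = np.minimum((dist_up + 1) / (nd_pos[None, :] + 1), 1.0)
    dist_lo = lower_row[None, :] - rr
    in_lo = (dist_lo >= 0) & (rr >= spec.baseline_row)
    fac_lo = np.minimum((dist_lo + 1) / (nd_neg[None, :] + 1), 1.0)

    field = np.maximum(fac_up * in_up, fac_lo * in_lo)
    img = spec.foreground_level * field

    if spec.text_artifact:
        _stamp_text(img, roi)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    if spec.speckle_density > 0:
        # sparse bright speckle spots inside the ROI band: the impulsive
        # display noise that throws the border-inward search off to an
        # outlier row until smoothing suppresses it
        band = img[roi.n_up : roi.n_lo + 1]
        hits = rng.random(band.shape) < spec.speckle_density
        band[hits] = rng.uniform(150.0, 255.0, size=int(hits.sum()))
    img = np.clip(img, 0.0, 255.0)

    # discretised truth of the drawn image, not the analytic lobe height
    e_mask = np.abs(phase - _E_LOBE[0]) < _E_LOBE[1] / 2
    a_mask = np.abs(phase - _A_LOBE[0]) < _A_LOBE[1] / 2
    e_wave = float(band_pos[e_mask].max() * vpp) if e_mask.any() else 0.0
    a_wave = float(band_pos[a_mask].max() * vpp) if a_mask.any() else 0.0

    gt = GroundTruth(
        upper_row=upper_row, lower_row=lower_row, e_wave=e_wave, a_wave=a_wave, roi=roi
    )
    return GrayImage(img), gt


def _stamp_text(img: np.ndarray, roi: RegionOfInterest) -> None:
    """Stamp a bright dashed block mimicking machine text in the ROI corner."""
    r0 = roi.n_up + 5
    r1 = min(roi.n_up + 25, img.shape[0] - 1)
    c1 = min(150, img.shape[1] - 1)
    rows = np.arange(r0, r1 + 1)[:, None]
    cols = np.arange(8, c1 + 1)[None, :]
    glyphs = ((cols // 6) % 2 == 0) & ((rows // 4) % 2 == 0)
    block = img[r0 : r1 + 1, 8 : c1 + 1]
    block[glyphs] = 250.0
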