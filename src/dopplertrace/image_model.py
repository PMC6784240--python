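"""Core data types and coordinate conventions for Doppler spectrogram images.

A pulsed-Doppler spectrogram is treated as an 8-bit grayscale raster in
which columns index time and rows index the velocity axis.  Rows increase
downward (standard raster convention); the zero-velocity baseline is a row
``y_base``, positive Doppler shifts (flow toward the transducer) are drawn
above it and negative shifts below it.  All indices are 0-based; published
pseudo-code for this family of algorithms is typically 1-based, so a
constant +1 maps our indices onto that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrayImage",
    "RegionOfInterest",
    "ThresholdParams",
    "SmoothingParams",
    "AxisCalibration",
    "to_grayscale",
    "crop_roi",
    "roi_histogram",
    "apply_mask",
]

# ITU-R BT.601 luminance weights, the classic "standard luminance" mapping.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A single-channel intensity image with values in [0, 255].

    Parameters
    ----------
    pixels
        2-D float array, shape ``(n_rows, n_cols)``.  Values may be
        non-integer (e.g. after smoothing) but must stay in [0, 255].
    row_offset
        Row index, in the original full-frame coordinate system, of this
        image's row 0.  Cropping to a region of interest records the offset
        here so that every edge row reported downstream can be expressed in
        original-image coordinates.
    """

    pixels: np.ndarray
    row_offset: int = 0

    def __post_init__(self) -> None:
        pix = np.asarray(self.pixels, dtype=float)
        if pix.ndim != 2:
            raise ValueError(f"expected a 2-D intensity matrix, got ndim={pix.ndim}")
        if pix.shape[0] < 3 or pix.shape[1] < 1:
            raise ValueError(f"image too small: shape {pix.shape} (need >= 3 rows, >= 1 column)")
        if not np.all(np.isfinite(pix)):
            raise ValueError("image contains non-finite intensities")
        if pix.min() < 0 or pix.max() > 255:
            raise ValueError(
                f"intensities outside [0, 255]: min={pix.min():g}, max={pix.max():g}"
            )
        object.__setattr__(self, "pixels", pix)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def local_row(self, original_row: int) -> int:
        """Map a row index given in original-frame coordinates to this image."""
        r = original_row - self.row_offset
        if not 0 <= r < self.n_rows:
            raise IndexError(
                f"row {original_row} (local {r}) outside image of {self.n_rows} rows "
                f"at offset {self.row_offset}"
            )
        return r


@dataclass(frozen=True)
class RegionOfInterest:
    """Row band of the display holding the spectrogram, plus the baseline row.

    ``n_up`` and ``n_lo`` are the upper and lower ROI border rows (both
    inclusive); ``y_base`` is the zero-velocity baseline row supplied by the
    operator (it is read off the machine display, e.g. the yellow baseline
    overlay, and is not auto-detected).
    """

    n_up: int
    n_lo: int
    y_base: int

    def __post_init__(self) -> None:
        for name in ("n_up", "n_lo", "y_base"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer row index, got {v!r}")
        if not self.n_up < self.y_base < self.n_lo:
            raise ValueError(
                f"require n_up < y_base < n_lo, got {self.n_up}, {self.y_base}, {self.n_lo}"
            )

    @property
    def n_roi_rows(self) -> int:
        return self.n_lo - self.n_up + 1

    @property
    def half_height(self) -> int:
        """Smaller of the two baseline-to-border distances, in rows."""
        return min(self.y_base - self.n_up, self.n_lo - self.y_base)

    def validate_for(self, img: GrayImage) -> None:
        lo = img.row_offset
        hi = img.row_offset + img.n_rows - 1
        if self.n_up < lo or self.n_lo > hi:
            raise IndexError(
                f"ROI rows [{self.n_up}, {self.n_lo}] outside image rows [{lo}, {hi}]"
            )


@dataclass(frozen=True)
class ThresholdParams:
    """Thresholds for the two per-column edge searches.

    ``theta1`` and ``theta2`` are fractions of the per-column maximum
    intensity; ``search_window`` is the row count *a* of the near-baseline
    window in which the baseline-outward search anchors its maximum.
    """

    theta1: float = 0.3
    theta2: float = 0.05
    search_window: int | None = None  # None -> 10% of ROI half-height

    def __post_init__(self) -> None:
        if not 0 < self.theta1 < 1:
            raise ValueError(f"theta1 must be in (0, 1), got {self.theta1}")
        if not 0 < self.theta2 < 1:
            raise ValueError(f"theta2 must be in (0, 1), got {self.theta2}")
        if self.search_window is not None and self.search_window < 1:
            raise ValueError(f"search_window must be >= 1, got {self.search_window}")

    def window_for(self, roi: RegionOfInterest) -> int:
        """Resolve the search window, defaulting to 10% of the ROI half-height."""
        if self.search_window is not None:
            return self.search_window
        return max(1, math.ceil(0.1 * roi.half_height))


@dataclass(frozen=True)
class SmoothingParams:
    """Half-sizes of the moving-average window: (2p+1) columns x (2q+1) rows."""

    p: int = 3
    q: int = 3

    def __post_init__(self) -> None:
        if not (isinstance(self.p, (int, np.integer)) and isinstance(self.q, (int, np.integer))):
            raise TypeError("p and q must be integers")
        if self.p < 0 or self.q < 0:
            raise ValueError(f"p and q must be >= 0, got p={self.p}, q={self.q}")


@dataclass(frozen=True)
class AxisCalibration:
    """Physical calibration of the display axes.

    ``velocity_per_pixel``: cm/s per row step (e.g. 0.34 cm/s).
    ``time_per_pixel``: ms per column step (e.g. 1.9 ms, set by the sweep
    speed and pixel pitch).  The sampling frequency of any extracted
    per-column series is 1000 / time_per_pixel Hz.
    """

    velocity_per_pixel: float = 0.34
    time_per_pixel: float = 1.9

    def __post_init__(self) -> None:
        for name in ("velocity_per_pixel", "time_per_pixel"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    def sampling_frequency(self) -> float:
        """Samples per second along the time (column) axis, in Hz."""
        return 1000.0 / self.time_per_pixel

    @property
    def dt(self) -> float:
        """Seconds per column."""
        return self.time_per_pixel / 1000.0


def to_grayscale(raster: np.ndarray) -> GrayImage:
    """Convert a raster (gray, RGB or RGBA) to a :class:`GrayImage`.

    RGB input is mapped by the BT.601 luminance weighting
    ``0.299 R + 0.587 G + 0.114 B``; an alpha channel, if present, is
    ignored.  Already-grayscale input passes through unchanged.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.size == 0:
        raise ValueError("empty raster")
    if arr.ndim == 2:
        return GrayImage(arr)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected 3 or 4 channels, got {arr.shape[2]}")
        gray = arr[:, :, :3] @ _LUMA_WEIGHTS
        return GrayImage(np.clip(gray, 0.0, 255.0))
    raise ValueError(f"expected a 2-D or 3-D raster, got ndim={arr.ndim}")


def crop_roi(img: GrayImage, roi: RegionOfInterest) -> GrayImage:
    """Remove pixels outside the ROI row band (all columns kept).

    Both border rows are inclusive; the returned image records the row
    offset so downstream indices remain reportable in original-frame
    coordinates.
    """
    roi.validate_for(img)
    lo = img.local_row(roi.n_up)
    hi = img.local_row(roi.n_lo)
    return GrayImage(img.pixels[lo : hi + 1].copy(), row_offset=roi.n_up)


def roi_histogram(img: GrayImage, roi: RegionOfInterest) -> np.ndarray:
    """256-bin intensity histogram of the ROI.

    Bin ``b`` counts ROI pixels whose intensity rounds to ``b``; the bins
    sum to the ROI pixel count.  On a spectrogram this histogram is
    bimodal — one mode at the black background (0) and one at the bright
    Doppler foreground — and the valley between the modes guides threshold
    choice.
    """
    cropped = crop_roi(img, roi)
    vals = np.clip(np.rint(cropped.pixels), 0, 255).astype(np.int64)
    return np.bincount(vals.ravel(), minlength=256)


def apply_mask(img: GrayImage, mask: np.ndarray) -> GrayImage:
    """Zero out pixels under a boolean mask (machine annotations, text).

    Bright annotation overlays inside the ROI (e.g. white text in a
    corner) defeat the border-inward edge search; masking them to
    intensity 0 before the search is the minimal fix.
    """
    m = np.asarray(mask, dtype=bool)
    if m.shape != img.pixels.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {img.pixels.shape}")
    out = img.pixels.copy()
    out[m] = 0.0
    return GrayImage(out, row_offset=img.row_offset)
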