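"""Per-column thresholding edge searches for Doppler envelope extraction.

Two complementary searches delineate the bright Doppler region in each
pixel column (each time instant):

* **Method 1** (border-inward): scan the whole ROI column; the upper edge
  is the smallest row, and the lower edge the largest row, whose intensity
  strictly exceeds ``theta1 * mu_max`` where ``mu_max`` is the column's
  maximum intensity.  Because the search starts at the ROI borders it
  tends to *underestimate* the velocity magnitude (a lower limit) and uses
  a relatively large threshold to resist artifacts near the borders.

* **Method 2** (baseline-outward): anchor on the maximum intensity inside
  a small window of ``a`` rows next to the baseline, then walk from that
  maximum toward the ROI border; the edge is the last pixel still at or
  above ``theta2 * mu_max_window`` before the first sub-threshold pixel.
  Starting at zero velocity with a small threshold makes this an
  *overestimate* (an upper limit) of the velocity magnitude.

Both searches return exactly one upper and one lower edge per column (or
an explicit missing marker, NaN, when a column holds no signal) — the
structural guarantee that distinguishes them from gradient edge detectors,
which may fire any number of times per column.

Averaging the two methods' profiles combines the under- and over-estimate
into a smoother envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import GrayImage, RegionOfInterest

__all__ = [
    "EdgeProfile",
    "ColumnMax",
    "column_max",
    "detect_edges_method1",
    "detect_edges_method2",
    "average_profiles",
]


@dataclass(frozen=True)
class ColumnMax:
    """Maximum intensity of one column over a scanned row range.

    ``row`` is the first (smallest) row attaining the maximum, in
    original-frame coordinates; ties break to the first occurrence so the
    result is independent of scan order.
    """

    value: float
    row: int


@dataclass(frozen=True)
class EdgeProfile:
    """Per-column upper and lower edge rows from one extraction method.

    ``upper`` and ``lower`` are float arrays of length ``n_cols`` holding
    row indices in original-frame coordinates; NaN marks a column (or
    half-column) where no edge exists because the scanned range held no
    signal.  Averaged profiles may hold half-integer rows.
    """

    upper: np.ndarray
    lower: np.ndarray
    method_tag: str

    def __post_init__(self) -> None:
        up = np.asarray(self.upper, dtype=float)
        lo = np.asarray(self.lower, dtype=float)
        if up.ndim != 1 or lo.ndim != 1 or up.shape != lo.shape:
            raise ValueError(
                f"upper/lower must be 1-D and equal length, got {up.shape} and {lo.shape}"
            )
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "lower", lo)

    @property
    def n_cols(self) -> int:
        return self.upper.shape[0]

    def missing_upper(self) -> np.ndarray:
        return np.isnan(self.upper)

    def missing_lower(self) -> np.ndarray:
        return np.isnan(self.lower)


def column_max(img: GrayImage, col: int, row_lo: int, row_hi: int) -> ColumnMax:
    """Maximum intensity of column ``col`` over rows ``[row_lo, row_hi]``.

    Rows are given and returned in original-frame coordinates; the range is
    closed at both ends.
    """
    if row_lo > row_hi:
        raise IndexError(f"empty row range [{row_lo}, {row_hi}]")
    if not 0 <= col < img.n_cols:
        raise IndexError(f"column {col} outside [0, {img.n_cols - 1}]")
    lo = img.local_row(row_lo)
    hi = img.local_row(row_hi)
    seg = img.pixels[lo : hi + 1, col]
    i = int(np.argmax(seg))  # argmax returns the first maximal index
    return ColumnMax(value=float(seg[i]), row=row_lo + i)


def _roi_block(img: GrayImage, roi: RegionOfInterest) -> tuple[np.ndarray, int]:
    """ROI sub-array (rows n_up..n_lo inclusive) and its top row (original coords)."""
    roi.validate_for(img)
    lo = img.local_row(roi.n_up)
    hi = img.local_row(roi.n_lo)
    return img.pixels[lo : hi + 1], roi.n_up


def detect_edges_method1(
    img: GrayImage,
    roi: RegionOfInterest,
    theta1: float,
    mask: np.ndarray | None = None,
) -> EdgeProfile:
    """Border-inward thresholding search (velocity lower limit).

    For each column the upper edge is the smallest ROI row and the lower
    edge the largest ROI row with intensity strictly greater than
    ``theta1 * mu_max`` of that column.  Columns with ``mu_max == 0`` carry
    no signal and are marked missing (NaN), never raised on.

    An optional boolean ``mask`` (full-image shape) zeroes annotation
    pixels — e.g. white text in the ROI corner — before the search, since
    this border-inward scan is the one such overlays derail.
    """
    if not 0 < theta1 < 1:
        raise ValueError(f"theta1 must be in (0, 1), got {theta1}")
    if mask is not None:
        from .image_model import apply_mask

        img = apply_mask(img, mask)
    block, top = _roi_block(img, roi)
    mu_max = block.max(axis=0)
    above = block > theta1 * mu_max[None, :]  # strict, as specified
    any_above = above.any(axis=0)  # equivalent to mu_max > 0 since theta1 < 1

    n_rows = block.shape[0]
    first = np.argmax(above, axis=0).astype(float)
    last = (n_rows - 1 - np.argmax(above[::-1], axis=0)).astype(float)
    upper = np.where(any_above, first + top, np.nan)
    lower = np.where(any_above, last + top, np.nan)
    return EdgeProfile(upper=upper, lower=lower, method_tag="method1")


def detect_edges_method2(
    img: GrayImage,
    roi: RegionOfInterest,
    theta2: float,
    a: int,
    mask: np.ndarray | None = None,
) -> EdgeProfile:
    """Baseline-outward thresholding search (velocity upper limit).

    For the upper half of each column, the anchor ``mu_max`` is the maximum
    intensity over the ``a + 1`` rows ``[y_base - a, y_base]``.  Starting at
    the (first) row attaining that maximum the scan walks upward; the edge
    is the last row whose intensity is still >= ``theta2 * mu_max`` before
    the first strictly sub-threshold row, or the ROI border ``n_up`` if the
    threshold is never crossed.  The lower half mirrors this over
    ``[y_base, y_base + a]`` walking downward toward ``n_lo``.  A half with
    a zero window maximum is marked missing (NaN).
    """
    if not 0 < theta2 < 1:
        raise ValueError(f"theta2 must be in (0, 1), got {theta2}")
    if a < 1:
        raise ValueError(f"search window a must be >= 1, got {a}")
    if a > roi.half_height:
        raise ValueError(
            f"search window a={a} exceeds ROI half-height {roi.half_height}"
        )
    if mask is not None:
        from .image_model import apply_mask

        img = apply_mask(img, mask)
    roi.validate_for(img)
    pix = img.pixels
    off = img.row_offset
    yb = roi.y_base - off
    n_up = roi.n_up - off
    n_lo = roi.n_lo - off
    n_cols = img.n_cols

    upper = np.full(n_cols, np.nan)
    lower = np.full(n_cols, np.nan)
    for x in range(n_cols):
        col = pix[:, x]
        # upper half: window [y_base - a, y_base], walk upward
        win = col[yb - a : yb + 1]
        mu = win.max()
        if mu > 0:
            i_up = (yb - a) + int(np.argmax(win))
            cut = theta2 * mu
            edge = i_up
            for r in range(i_up - 1, n_up - 1, -1):
                if col[r] < cut:  # strict, as specified
                    break
                edge = r
            upper[x] = edge + off
        # lower half: window [y_base, y_base + a], walk downward
        win = col[yb : yb + a + 1]
        mu = win.max()
        if mu > 0:
            i_lo = yb + int(np.argmax(win))
            cut = theta2 * mu
            edge = i_lo
            for r in range(i_lo + 1, n_lo + 1):
                if col[r] < cut:
                    break
                edge = r
            lower[x] = edge + off
    return EdgeProfile(upper=upper, lower=lower, method_tag="method2")


def average_profiles(e1: EdgeProfile, e2: EdgeProfile) -> EdgeProfile:
    """Column-wise arithmetic mean of two edge profiles.

    Where only one method found an edge the present value is used; where
    both are missing the averaged column is missing too.
    """
    if e1.n_cols != e2.n_cols:
        raise ValueError(f"column counts differ: {e1.n_cols} != {e2.n_cols}")

    def _mean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.where(np.isnan(a), b, np.where(np.isnan(b), a, (a + b) / 2.0))
        out[np.isnan(a) & np.isnan(b)] = np.nan
        return out

    return EdgeProfile(
        upper=_mean(e1.upper, e2.upper),
        lower=_mean(e1.lower, e2.lower),
        method_tag="averaged",
    )
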