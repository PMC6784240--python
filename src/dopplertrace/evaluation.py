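"""Comparison of the thresholding extractor against a gradient edge detector.

A Canny detector (library implementation) serves as the comparison
baseline: it may fire any number of times per column — extra firings are
artifacts, fewer than two mean a lost envelope — whereas the per-column
thresholding searches return exactly one upper and one lower edge wherever
signal exists.  The comparison here is metric-based (edges per column,
edge-pixel counts across a threshold sweep), not pixel-exact, since Canny
internals differ between implementations.
"""

from __future__ import annotations

import math

import numpy as np
from skimage import feature

from .edges import EdgeProfile
from .image_model import GrayImage

__all__ = [
    "canny_edge_map",
    "edges_per_column",
    "profile_to_edge_map",
    "edge_count_histogram",
]


def canny_edge_map(
    img: GrayImage, threshold: float, sigma: float = math.sqrt(2.0)
) -> np.ndarray:
    """Binary Canny edge map at a given high-threshold fraction.

    ``threshold`` is the high hysteresis threshold as a fraction of the
    intensity range; the low threshold is 0.4x the high one (the customary
    ratio).  ``sigma`` is the Gaussian derivative scale in pixels.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return feature.canny(
        img.pixels / 255.0,
        sigma=sigma,
        low_threshold=0.4 * threshold,
        high_threshold=threshold,
    )


def edges_per_column(edge_map: np.ndarray) -> np.ndarray:
    """Count distinct edge segments (vertical runs of edge pixels) per column."""
    m = np.asarray(edge_map, dtype=bool)
    if m.ndim != 2:
        raise ValueError("edge map must be 2-D")
    starts = np.vstack([m[:1], m[1:] & ~m[:-1]])
    return starts.sum(axis=0)


def edge_count_histogram(counts: np.ndarray) -> np.ndarray:
    """Histogram of per-column segment counts (index = segment count)."""
    return np.bincount(np.asarray(counts, dtype=int))


def profile_to_edge_map(edges: EdgeProfile, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise an edge profile to a binary map of the given image shape.

    Each non-missing upper and lower edge row (rounded) becomes one edge
    pixel in its column, so a column where both edges exist and differ
    holds exactly two segments.
    """
    out = np.zeros(shape, dtype=bool)
    cols = np.arange(edges.n_cols)
    for rows in (edges.upper, edges.lower):
        ok = ~np.isnan(rows)
        r = np.rint(rows[ok]).astype(int)
        if np.any((r < 0) | (r >= shape[0])) or edges.n_cols > shape[1]:
            raise ValueError("profile rows or columns outside the target shape")
        out[r, cols[ok]] = True
    return out
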