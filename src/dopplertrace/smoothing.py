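"""Moving-average (box) smoothing of spectrogram intensities.

Each output pixel is the arithmetic mean of the (2p+1) x (2q+1) rectangle
of input pixels centred on it — 2p+1 columns wide, 2q+1 rows tall.  Near
the image border the window shrinks to its intersection with the image and
the mean is taken over the available pixels only, so no pixel values are
invented and a constant image is a fixed point of the filter.

Smoothing is intended to run on the cropped ROI, before edge extraction,
to suppress speckle-driven outliers and sudden jumps in the extracted
velocity profiles.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image_model import GrayImage, SmoothingParams

__all__ = ["smooth_image"]


def smooth_image(img: GrayImage, params: SmoothingParams) -> GrayImage:
    """Apply the (2p+1) x (2q+1) moving-average filter to an image.

    Raises ``ValueError`` if the window exceeds the image in either
    dimension.  Output intensities are real-valued in [0, 255].
    """
    wy = 2 * params.q + 1  # rows
    wx = 2 * params.p + 1  # columns
    if wy > img.n_rows or wx > img.n_cols:
        raise ValueError(
            f"smoothing window {wy}x{wx} larger than image {img.n_rows}x{img.n_cols}"
        )
    if params.p == 0 and params.q == 0:
        return GrayImage(img.pixels.copy(), row_offset=img.row_offset)

    size = (wy, wx)
    # uniform_filter with zero padding gives sum/window_area; rescaling by
    # the window area and dividing by the count of in-image pixels yields
    # the shrink-at-border mean.
    sums = ndimage.uniform_filter(img.pixels, size=size, mode="constant", cval=0.0)
    counts = ndimage.uniform_filter(
        np.ones_like(img.pixels), size=size, mode="constant", cval=0.0
    )
    out = sums / counts
    return GrayImage(np.clip(out, 0.0, 255.0), row_offset=img.row_offset)
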