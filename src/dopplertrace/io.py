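"""Raster and tabular I/O for the extraction pipeline.

Still images (PNG/TIFF/BMP, 8-bit gray or RGB) are read through imageio
and converted to grayscale; frames of common video containers are read
the same way when an imageio video plugin is available.  Profiles and
velocity series are written as plain CSV via pandas, with a JSON metadata
block recording every parameter used.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .analysis import VelocityProfile
from .edges import EdgeProfile
from .image_model import GrayImage, to_grayscale

__all__ = [
    "load_image",
    "load_mask",
    "iter_frames",
    "save_image",
    "profiles_to_frame",
    "save_profiles_csv",
    "save_velocity_csv",
    "save_json",
]


def load_image(path: str | Path) -> GrayImage:
    """Read a still raster and convert to 8-bit grayscale."""
    return to_grayscale(iio.imread(path))


def load_mask(path: str | Path, shape: tuple[int, int]) -> np.ndarray:
    """Read an annotation mask raster: non-zero pixels are masked."""
    m = np.asarray(iio.imread(path))
    if m.ndim == 3:
        m = m[:, :, :3].max(axis=2)
    if m.shape != shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {shape}")
    return m > 0


def iter_frames(path: str | Path) -> Iterator[GrayImage]:
    """Yield grayscale frames of a video container, in order."""
    for frame in iio.imiter(path):
        yield to_grayscale(np.asarray(frame))


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG/TIFF/BMP (rounded to integers)."""
    iio.imwrite(path, np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8))


def profiles_to_frame(profiles: list[EdgeProfile], frame_index: int = 0) -> pd.DataFrame:
    """Long-form table of edge rows: (frame, column, upper_row, lower_row, method)."""
    parts = []
    for prof in profiles:
        parts.append(
            pd.DataFrame(
                {
                    "frame": frame_index,
                    "column": np.arange(prof.n_cols),
                    "upper_row": prof.upper,
                    "lower_row": prof.lower,
                    "method": prof.method_tag,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def save_profiles_csv(profiles: list[EdgeProfile], path: str | Path, frame_index: int = 0) -> None:
    profiles_to_frame(profiles, frame_index).to_csv(path, index=False)


def save_velocity_csv(pos: VelocityProfile, neg: VelocityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": pos.times,
            "v_pos_cm_s": pos.velocity,
            "v_neg_cm_s": neg.velocity,
            "missing_pos": pos.missing.astype(int),
            "missing_neg": neg.missing.astype(int),
        }
    ).to_csv(path, index=False)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
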