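"""Report figures: profile overlays, Bland-Altman scatters, spectra, Canny maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import AgreementStats, VelocityProfile, profile_spectrum
from .edges import EdgeProfile
from .image_model import GrayImage, RegionOfInterest

__all__ = ["plot_overlay", "plot_agreement", "plot_spectra", "plot_canny_maps"]

_COLORS = {"method1": "tab:red", "method2": "tab:blue", "averaged": "tab:green"}


def plot_overlay(
    img: GrayImage,
    roi: RegionOfInterest,
    profiles: dict[str, EdgeProfile],
    path: str | Path,
) -> None:
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.imshow(img.pixels, cmap="gray", vmin=0, vmax=255, aspect="auto")
    ax.axhline(roi.y_base - img.row_offset, color="yellow", lw=0.8, label="baseline")
    for name, prof in profiles.items():
        c = _COLORS.get(name, None)
        x = np.arange(prof.n_cols)
        ax.plot(x, prof.upper - img.row_offset, color=c, lw=1.0, label=name)
        ax.plot(x, prof.lower - img.row_offset, color=c, lw=1.0)
    ax.set_xlabel("column (time)")
    ax.set_ylabel("row (velocity)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_agreement(agreement: dict[str, AgreementStats | None], path: str | Path) -> None:
    keys = [k for k, v in agreement.items() if v is not None]
    fig, axes = plt.subplots(1, max(len(keys), 1), figsize=(5 * max(len(keys), 1), 4), squeeze=False)
    for ax, key in zip(axes[0], keys):
        st = agreement[key]
        ax.scatter(st.means, st.diffs, s=4, alpha=0.4)
        ax.axhline(st.bias, color="k", label=f"bias {st.bias:.2f}")
        for y in (st.loa_low, st.loa_high):
            ax.axhline(y, color="k", ls="--")
        ax.set_title(f"{key} envelope")
        ax.set_xlabel("mean of methods (pixels)")
        ax.set_ylabel("difference (pixels)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_spectra(
    velocities: dict[str, tuple[VelocityProfile, VelocityProfile]], path: str | Path
) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for name, (pos, neg) in velocities.items():
        for ax, prof, side in ((axes[0], pos, "positive"), (axes[1], neg, "negative")):
            f, m = profile_spectrum(prof)
            ax.plot(f, m, lw=0.8, label=name)
            ax.set_title(f"{side} profile spectrum")
            ax.set_xlabel("frequency (Hz)")
            ax.set_ylabel("|DFT|")
    for ax in axes:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_canny_maps(maps: dict[float, np.ndarray], path: str | Path) -> None:
    n = len(maps)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (thr, m) in zip(axes[0], sorted(maps.items())):
        ax.imshow(m, cmap="gray", aspect="auto")
        ax.set_title(f"threshold {thr:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
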