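"""End-to-end extraction pipeline: image -> edges -> velocities -> analytics.

One frame flows through: grayscale conversion, ROI crop, optional
moving-average smoothing, both thresholding edge searches plus their
average, calibration to cm/s, E/A wave measurement on the averaged
positive trace, and Bland-Altman agreement between the two methods
(computed in pixel units, on the baseline-relative displacement
``y_base - edge_row``, separately for the positive and negative
envelopes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as dio
from .analysis import (
    AgreementStats,
    InsufficientDataError,
    VelocityProfile,
    WaveMeasurements,
    bland_altman,
    measure_waves,
    profile_spectrum,
    rows_to_velocity,
)
from .config import PipelineConfig
from .edges import EdgeProfile, average_profiles, detect_edges_method1, detect_edges_method2
from .image_model import GrayImage, RegionOfInterest, crop_roi, roi_histogram
from .smoothing import smooth_image

logger = logging.getLogger(__name__)

__all__ = ["FrameResult", "extract_frame", "run_pipeline", "suggest_thresholds", "ThresholdSuggestion"]

_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv", ".webm", ".gif"}


@dataclass(frozen=True)
class FrameResult:
    """All per-frame outputs of the extraction pipeline."""

    profiles: dict[str, EdgeProfile]            # method1 / method2 / averaged
    velocities: dict[str, tuple[VelocityProfile, VelocityProfile]]
    waves: WaveMeasurements
    agreement: dict[str, AgreementStats | None]  # positive / negative envelope


def extract_frame(
    img: GrayImage, cfg: PipelineConfig, mask: np.ndarray | None = None
) -> FrameResult:
    """Run the full extraction on one grayscale frame."""
    roi = cfg.roi
    work = crop_roi(img, roi)
    roi_mask = None
    if mask is not None:
        work_rows = slice(roi.n_up - img.row_offset, roi.n_lo - img.row_offset + 1)
        roi_mask = np.asarray(mask, dtype=bool)[work_rows]
    if cfg.smoothing_enabled:
        work = smooth_image(work, cfg.smoothing)

    a = cfg.thresholds.window_for(roi)
    e1 = detect_edges_method1(work, roi, cfg.thresholds.theta1, mask=roi_mask)
    e2 = detect_edges_method2(work, roi, cfg.thresholds.theta2, a, mask=roi_mask)
    avg = average_profiles(e1, e2)
    profiles = {"method1": e1, "method2": e2, "averaged": avg}

    velocities = {
        name: rows_to_velocity(prof, roi, cfg.calibration)
        for name, prof in profiles.items()
    }
    waves = measure_waves(velocities["averaged"][0])

    agreement: dict[str, AgreementStats | None] = {}
    for key, attr in (("positive", "upper"), ("negative", "lower")):
        s1 = roi.y_base - getattr(e1, attr)
        s2 = roi.y_base - getattr(e2, attr)
        try:
            agreement[key] = bland_altman(s1, s2)
        except InsufficientDataError:
            agreement[key] = None
    return FrameResult(profiles=profiles, velocities=velocities, waves=waves, agreement=agreement)


def _iter_inputs(paths: list[Path]):
    """Yield (label, GrayImage) over still images and video frames."""
    for path in paths:
        if path.suffix.lower() in _VIDEO_SUFFIXES:
            try:
                for i, frame in enumerate(dio.iter_frames(path)):
                    yield f"{path.stem}_f{i:04d}", frame
            except Exception as exc:  # plugin or codec missing, corrupt file
                logger.warning("skipping unreadable video %s: %s", path, exc)
        else:
            try:
                yield path.stem, dio.load_image(path)
            except Exception as exc:
                logger.warning("skipping unreadable image %s: %s", path, exc)


def run_pipeline(
    cfg: PipelineConfig,
    inputs: list[str | Path],
    outdir: str | Path,
    figures: bool = False,
) -> list[str]:
    """Process images/videos and write per-frame CSV, JSON (and figures).

    Returns the list of frame labels processed.  Every parameter used is
    logged to ``parameters.json`` in the output directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dio.save_json(cfg.to_dict(), outdir / "parameters.json")

    processed: list[str] = []
    for label, img in _iter_inputs([Path(p) for p in inputs]):
        mask = None
        if cfg.mask_path is not None:
            mask = dio.load_mask(cfg.mask_path, (img.n_rows, img.n_cols))
        res = extract_frame(img, cfg, mask=mask)

        dio.save_profiles_csv(list(res.profiles.values()), outdir / f"{label}_profiles.csv")
        pos, neg = res.velocities["averaged"]
        dio.save_velocity_csv(pos, neg, outdir / f"{label}_velocity.csv")
        dio.save_json(_summary_dict(res), outdir / f"{label}_summary.json")
        if figures:
            from . import plots

            plots.plot_overlay(img, cfg.roi, res.profiles, outdir / f"{label}_overlay.png")
            plots.plot_agreement(res.agreement, outdir / f"{label}_bland_altman.png")
            plots.plot_spectra(res.velocities, outdir / f"{label}_spectra.png")
        processed.append(label)
        logger.info("processed frame %s", label)
    return processed


def _summary_dict(res: FrameResult) -> dict:
    w = res.waves
    out: dict = {
        "waves": {
            "status": w.status,
            "e_wave_cm_s": w.e_wave,
            "a_wave_cm_s": w.a_wave,
            "e_sd_cm_s": w.e_sd,
            "a_sd_cm_s": w.a_sd,
            "e_per_beat": w.e_per_beat,
            "a_per_beat": w.a_per_beat,
        },
        "agreement_pixels": {},
    }
    for key, st in res.agreement.items():
        out["agreement_pixels"][key] = (
            None
            if st is None
            else {"bias": st.bias, "sd": st.sd, "loa_low": st.loa_low, "loa_high": st.loa_high, "n": st.n_pairs}
        )
    return out


@dataclass(frozen=True)
class ThresholdSuggestion:
    """Histogram-guided candidate threshold range.

    The ROI histogram of a spectrogram is bimodal: a background mode near 0
    and a foreground mode near the bright Doppler fill.  A threshold
    fraction theta is sensible when ``theta * mu_max`` falls between the
    modes; ``theta_at_valley`` places it at the histogram valley.  Final
    values remain user-set.
    """

    background_mode: int
    foreground_mode: int
    valley: int
    theta_min: float
    theta_max: float
    theta_at_valley: float


def suggest_thresholds(img: GrayImage, roi: RegionOfInterest) -> ThresholdSuggestion:
    """Locate the two dominant ROI-histogram modes and the valley between."""
    hist = roi_histogram(img, roi).astype(float)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(hist, kernel, mode="same")

    # the background mode sits in the dark half of the range and the bright
    # Doppler fill in the upper half; searching each half separately keeps
    # the heavy background tail from shadowing the foreground peak
    bg = int(np.argmax(smooth[:128]))
    fg = 128 + int(np.argmax(smooth[128:]))
    valley = bg + int(np.argmin(smooth[bg : fg + 1]))
    return ThresholdSuggestion(
        background_mode=bg,
        foreground_mode=fg,
        valley=valley,
        theta_min=(bg + 1) / fg,
        theta_max=1.0,
        theta_at_valley=valley / fg,
    )
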