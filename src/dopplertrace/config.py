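"""Pipeline configuration: a flat key-value (YAML) file.

Required keys::

    n_up, n_lo, y_base            ROI borders and baseline row (pixels)
    theta1, theta2                thresholds for the two edge searches
    search_window                 rows of the near-baseline window (method 2)
    p, q                          moving-average half-sizes (columns, rows)
    velocity_per_pixel            cm/s per row
    time_per_pixel                ms per column

Optional keys::

    smoothing                     apply the moving average (default true)
    mask                          path to a raster; non-zero pixels are
                                  zeroed before edge search (annotations)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .image_model import AxisCalibration, RegionOfInterest, SmoothingParams, ThresholdParams

__all__ = ["PipelineConfig", "ConfigError", "load_config", "save_config"]

_REQUIRED = [
    "n_up", "n_lo", "y_base",
    "theta1", "theta2", "search_window",
    "p", "q",
    "velocity_per_pixel", "time_per_pixel",
]


class ConfigError(ValueError):
    """Raised for unparseable, incomplete, or inconsistent configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    roi: RegionOfInterest
    thresholds: ThresholdParams
    smoothing: SmoothingParams
    calibration: AxisCalibration
    smoothing_enabled: bool = True
    mask_path: Path | None = None

    def to_dict(self) -> dict:
        d = {
            "n_up": self.roi.n_up,
            "n_lo": self.roi.n_lo,
            "y_base": self.roi.y_base,
            "theta1": self.thresholds.theta1,
            "theta2": self.thresholds.theta2,
            "search_window": self.thresholds.window_for(self.roi),
            "p": self.smoothing.p,
            "q": self.smoothing.q,
            "velocity_per_pixel": self.calibration.velocity_per_pixel,
            "time_per_pixel": self.calibration.time_per_pixel,
            "smoothing": self.smoothing_enabled,
        }
        if self.mask_path is not None:
            d["mask"] = str(self.mask_path)
        return d


def config_from_dict(data: dict, base_dir: Path | None = None) -> PipelineConfig:
    missing = [k for k in _REQUIRED if k not in data]
    if missing:
        raise ConfigError(f"missing configuration keys: {', '.join(sorted(missing))}")
    try:
        roi = RegionOfInterest(
            n_up=int(data["n_up"]), n_lo=int(data["n_lo"]), y_base=int(data["y_base"])
        )
        thresholds = ThresholdParams(
            theta1=float(data["theta1"]),
            theta2=float(data["theta2"]),
            search_window=int(data["search_window"]),
        )
        smoothing = SmoothingParams(p=int(data["p"]), q=int(data["q"]))
        cal = AxisCalibration(
            velocity_per_pixel=float(data["velocity_per_pixel"]),
            time_per_pixel=float(data["time_per_pixel"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    mask = data.get("mask")
    mask_path = None
    if mask is not None:
        mask_path = Path(mask)
        if base_dir is not None and not mask_path.is_absolute():
            mask_path = base_dir / mask_path
    return PipelineConfig(
        roi=roi,
        thresholds=thresholds,
        smoothing=smoothing,
        calibration=cal,
        smoothing_enabled=bool(data.get("smoothing", True)),
        mask_path=mask_path,
    )


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not hold a key-value mapping")
    return config_from_dict(data, base_dir=path.parent)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
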