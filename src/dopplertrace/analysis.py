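"""Calibrated velocity profiles and downstream analytics.

Edge rows become signed velocities through the display calibration
(cm/s per row, ms per column).  On the calibrated traces this module
measures the early-diastolic (E) and atrial (A) mitral-inflow peaks,
quantifies the agreement of two extraction methods with Bland-Altman
limits of agreement, and computes magnitude spectra of the profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .edges import EdgeProfile
from .image_model import AxisCalibration, RegionOfInterest

__all__ = [
    "VelocityProfile",
    "WaveMeasurements",
    "AgreementStats",
    "InsufficientDataError",
    "rows_to_velocity",
    "measure_waves",
    "bland_altman",
    "profile_spectrum",
]


class InsufficientDataError(ValueError):
    """Raised when fewer than two valid pairs remain for an agreement fit."""


@dataclass(frozen=True)
class VelocityProfile:
    """A signed velocity time series in cm/s, one value per image column.

    Rows above the baseline map to positive velocities (flow toward the
    transducer), rows below to negative.  ``missing`` flags columns where
    the extractor found no edge; their velocity is recorded as 0 cm/s, the
    physiological null.
    """

    velocity: np.ndarray
    dt: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.velocity, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("velocity must be a non-empty 1-D series")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        m = self.missing
        m = np.zeros(v.size, dtype=bool) if m is None else np.asarray(m, dtype=bool)
        if m.shape != v.shape:
            raise ValueError("missing flags must match the velocity length")
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "missing", m)

    @property
    def n_samples(self) -> int:
        return self.velocity.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt


@dataclass(frozen=True)
class WaveMeasurements:
    """E- and A-wave peak velocities measured across detected beats.

    ``e_wave``/``a_wave`` are means across beats (NaN if absent), with
    sample SDs; per-beat values and peak column indices are retained.
    ``status`` is ``"ok"`` or ``"insufficient peaks"``.
    """

    e_wave: float
    a_wave: float
    e_sd: float
    a_sd: float
    e_per_beat: np.ndarray
    a_per_beat: np.ndarray
    e_peak_columns: np.ndarray
    a_peak_columns: np.ndarray
    status: str

    @property
    def n_beats(self) -> int:
        return len(self.e_per_beat)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two paired series.

    ``bias`` is the mean difference, ``sd`` the sample (n-1) standard
    deviation of the differences, and the 95% limits of agreement are
    ``bias -/+ 1.96 sd``.  ``means`` and ``diffs`` hold the per-pair points
    of the Bland-Altman scatter.
    """

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.diffs.size


def rows_to_velocity(
    edges: EdgeProfile, roi: RegionOfInterest, cal: AxisCalibration
) -> tuple[VelocityProfile, VelocityProfile]:
    """Convert upper/lower edge rows to calibrated (positive, negative) traces.

    ``velocity = (y_base - edge_row) * velocity_per_pixel``: the upper trace
    (rows above the baseline) is >= 0 cm/s, the lower trace <= 0 cm/s.
    Missing columns become 0 cm/s with the missing flag set.
    """
    def _convert(rows: np.ndarray) -> VelocityProfile:
        miss = np.isnan(rows)
        v = (roi.y_base - rows) * cal.velocity_per_pixel
        v = np.where(miss, 0.0, v)
        return VelocityProfile(velocity=v, dt=cal.dt, missing=miss)

    return _convert(edges.upper), _convert(edges.lower)


def measure_waves(
    profile: VelocityProfile,
    min_separation: float = 0.12,
    min_prominence: float = 10.0,
    beat_gap: float = 0.4,
) -> WaveMeasurements:
    """Measure E and A peak velocities from a positive inflow trace.

    Local maxima with at least ``min_prominence`` (cm/s) and
    ``min_separation`` (s) between them are detected and grouped into
    beats: a new beat starts whenever the interval to the previous peak
    exceeds ``beat_gap`` (s).  Within a beat the earlier qualifying peak is
    E and the later is A (mitral inflow order); a beat with a single peak
    yields an E wave and an absent (NaN) A wave.  The default ``beat_gap``
    of 0.4 s sits above the typical E-to-A interval and below the A-to-next-E
    interval at resting heart rates.

    Fewer than two qualifying peaks overall yields an explicit
    ``"insufficient peaks"`` result rather than an exception.
    """
    v = profile.velocity
    distance = max(1, int(round(min_separation / profile.dt)))
    peaks, props = signal.find_peaks(v, prominence=min_prominence, distance=distance)

    if peaks.size < 2:
        nan = float("nan")
        empty = np.array([])
        return WaveMeasurements(
            e_wave=nan, a_wave=nan, e_sd=nan, a_sd=nan,
            e_per_beat=empty, a_per_beat=empty,
            e_peak_columns=np.array([], dtype=int),
            a_peak_columns=np.array([], dtype=int),
            status="insufficient peaks",
        )

    # group peaks into beats by the inter-peak interval
    gaps = np.diff(peaks) * profile.dt
    beat_starts = np.flatnonzero(gaps > beat_gap) + 1
    groups = np.split(np.arange(peaks.size), beat_starts)

    e_vals, a_vals, e_cols, a_cols = [], [], [], []
    for g in groups:
        idx = peaks[g]
        if len(g) > 2:
            # keep the two most prominent peaks of the beat, in time order
            prom = props["prominences"][g]
            keep = np.sort(g[np.argsort(prom)[-2:]])
            idx = peaks[keep]
        if len(idx) == 1:
            e_vals.append(v[idx[0]])
            e_cols.append(idx[0])
            a_vals.append(np.nan)
            a_cols.append(-1)
        else:
            e_vals.append(v[idx[0]])
            a_vals.append(v[idx[1]])
            e_cols.append(idx[0])
            a_cols.append(idx[1])

    e_arr = np.asarray(e_vals, dtype=float)
    a_arr = np.asarray(a_vals, dtype=float)

    def _summ(x: np.ndarray) -> tuple[float, float]:
        x = x[~np.isnan(x)]
        if x.size == 0:
            return float("nan"), float("nan")
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        return float(np.mean(x)), sd

    e_mean, e_sd = _summ(e_arr)
    a_mean, a_sd = _summ(a_arr)
    return WaveMeasurements(
        e_wave=e_mean, a_wave=a_mean, e_sd=e_sd, a_sd=a_sd,
        e_per_beat=e_arr, a_per_beat=a_arr,
        e_peak_columns=np.asarray(e_cols, dtype=int),
        a_peak_columns=np.asarray(a_cols, dtype=int),
        status="ok",
    )


def bland_altman(s1: np.ndarray, s2: np.ndarray) -> AgreementStats:
    """Bland-Altman limits of agreement between two paired series.

    Pairs with a NaN in either series are dropped; at least two valid
    pairs are required.  Differences are ``s1 - s2``; the limits are
    ``bias -/+ 1.96 sd`` with the sample (n-1) standard deviation.
    """
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"series must be 1-D and equal length, got {a.shape}, {b.shape}")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InsufficientDataError(
            f"need >= 2 valid pairs for Bland-Altman, got {a.size}"
        )
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(a + b) / 2.0,
        diffs=d,
    )


def profile_spectrum(profile: VelocityProfile) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum of a mean-removed velocity profile.

    Returns ``(freqs, magnitude)`` where ``freqs`` runs from 0 to the
    Nyquist frequency ``1 / (2 dt)`` and ``magnitude`` is the modulus of
    the unnormalised DFT of the mean-removed series.  Mean removal keeps
    the DC term from masking the fluctuation content of interest.

    With this convention Parseval's relation reads
    ``|X_0|^2 + 2 * sum_{0<k<N/2} |X_k|^2 + |X_{N/2}|^2 = N * sum x^2``
    (the Nyquist term present only for even N).
    """
    if profile.n_samples < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    x = profile.velocity - profile.velocity.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=profile.dt)
    return freqs, spec
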