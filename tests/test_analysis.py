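"""Velocity calibration, E/A wave picking, Bland-Altman, spectra."""

import numpy as np
import pytest

from dopplertrace import (
    AxisCalibration,
    EdgeProfile,
    InsufficientDataError,
    RegionOfInterest,
    VelocityProfile,
    bland_altman,
    measure_waves,
    profile_spectrum,
    rows_to_velocity,
)


@pytest.fixture
def roi():
    return RegionOfInterest(n_up=10, n_lo=389, y_base=250)


class TestRowsToVelocity:
    def test_baseline_row_is_zero_velocity(self, roi, cal):
        prof = EdgeProfile(upper=[250.0], lower=[250.0], method_tag="m")
        pos, neg = rows_to_velocity(prof, roi, cal)
        assert pos.velocity[0] == 0.0 and neg.velocity[0] == 0.0

    def test_ten_rows_above_baseline_is_3_4_cm_s(self, roi, cal):
        prof = EdgeProfile(upper=[240.0], lower=[260.0], method_tag="m")
        pos, neg = rows_to_velocity(prof, roi, cal)
        assert pos.velocity[0] == pytest.approx(3.4)
        assert neg.velocity[0] == pytest.approx(-3.4)

    def test_elementwise_affine_oracle_and_linearity(self, roi, rng):
        upper = rng.uniform(20, 250, 30)
        lower = rng.uniform(250, 380, 30)
        prof = EdgeProfile(upper=upper, lower=lower, method_tag="m")
        cal1 = AxisCalibration(velocity_per_pixel=0.34, time_per_pixel=1.9)
        cal2 = AxisCalibration(velocity_per_pixel=0.68, time_per_pixel=1.9)
        pos1, neg1 = rows_to_velocity(prof, roi, cal1)
        pos2, _ = rows_to_velocity(prof, roi, cal2)
        for i in range(30):
            assert pos1.velocity[i] == pytest.approx((250 - upper[i]) * 0.34)
            assert neg1.velocity[i] == pytest.approx((250 - lower[i]) * 0.34)
        np.testing.assert_allclose(pos2.velocity, 2 * pos1.velocity)

    def test_missing_columns_become_zero_with_flag(self, roi, cal):
        prof = EdgeProfile(upper=[240.0, np.nan], lower=[260.0, np.nan], method_tag="m")
        pos, _ = rows_to_velocity(prof, roi, cal)
        assert pos.velocity[1] == 0.0
        assert pos.missing.tolist() == [False, True]


def two_lobe_profile(e=67.0, a=72.0, beats=3, dt=1.9e-3, period=0.8):
    """Gaussian E and A lobes per beat on a zero baseline."""
    n = int(beats * period / dt)
    t = np.arange(n) * dt
    ph = (t % period) / period
    v = e * np.exp(-0.5 * ((ph - 0.45) / 0.04) ** 2) + a * np.exp(
        -0.5 * ((ph - 0.75) / 0.04) ** 2
    )
    return VelocityProfile(velocity=v, dt=dt)


class TestMeasureWaves:
    def test_two_lobe_beats_recover_generator_heights(self):
        prof = two_lobe_profile(e=67.0, a=72.0)
        w = measure_waves(prof)
        assert w.status == "ok"
        assert w.n_beats == 3
        assert w.e_wave == pytest.approx(67.0, abs=0.5)
        assert w.a_wave == pytest.approx(72.0, abs=0.5)
        assert np.all(w.e_peak_columns < w.a_peak_columns)

    def test_flat_profile_reports_insufficient_peaks(self):
        prof = VelocityProfile(velocity=np.zeros(500), dt=1.9e-3)
        w = measure_waves(prof)
        assert w.status == "insufficient peaks"
        assert np.isnan(w.e_wave) and np.isnan(w.a_wave)

    def test_single_lobe_beats_yield_e_only(self):
        dt, period = 1.9e-3, 0.8
        n = int(3 * period / dt)
        t = np.arange(n) * dt
        ph = (t % period) / period
        v = 67.0 * np.exp(-0.5 * ((ph - 0.5) / 0.05) ** 2)
        w = measure_waves(VelocityProfile(velocity=v, dt=dt))
        assert w.status == "ok"
        assert w.e_wave == pytest.approx(67.0, abs=0.5)
        assert np.isnan(w.a_wave)
        assert np.all(np.isnan(w.a_per_beat))


class TestBlandAltman:
    def test_hand_computed_three_point_example(self):
        st = bland_altman(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert st.bias == pytest.approx(2.0)
        assert st.sd == pytest.approx(1.0)
        assert st.loa_low == pytest.approx(0.04)
        assert st.loa_high == pytest.approx(3.96)

    def test_identical_series_give_zero_everything(self, rng):
        s = rng.uniform(-5, 5, 40)
        st = bland_altman(s, s)
        assert st.bias == 0.0 and st.sd == 0.0
        assert st.loa_low == 0.0 and st.loa_high == 0.0

    def test_antisymmetric_under_swap(self, rng):
        s1, s2 = rng.normal(0, 3, 50), rng.normal(1, 3, 50)
        a, b = bland_altman(s1, s2), bland_altman(s2, s1)
        assert a.bias == pytest.approx(-b.bias)
        assert a.sd == pytest.approx(b.sd)

    def test_nan_pairs_dropped_and_insufficient_data_raises(self):
        s1 = np.array([1.0, np.nan, 3.0, 4.0])
        s2 = np.array([0.0, 0.0, np.nan, 1.0])
        st = bland_altman(s1, s2)
        assert st.n_pairs == 2
        with pytest.raises(InsufficientDataError):
            bland_altman(np.array([1.0, np.nan]), np.array([0.0, 0.0]))


class TestProfileSpectrum:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        fs = 532.0  # a display-typical sampling rate
        t = np.arange(1024) / fs
        prof = VelocityProfile(velocity=np.sin(2 * np.pi * 5.0 * t), dt=1 / fs)
        freqs, mag = profile_spectrum(prof)
        assert freqs[np.argmax(mag)] == pytest.approx(5.0, abs=fs / 1024)
        assert freqs[-1] == pytest.approx(fs / 2)

    def test_constant_profile_has_zero_spectrum(self):
        prof = VelocityProfile(velocity=np.full(64, 13.0), dt=1e-3)
        _, mag = profile_spectrum(prof)
        np.testing.assert_allclose(mag, 0.0, atol=1e-9)

    def test_matches_naive_dft_oracle(self, rng):
        x = rng.normal(0, 1, 33)
        prof = VelocityProfile(velocity=x, dt=2e-3)
        freqs, mag = profile_spectrum(prof)
        xc = x - x.mean()
        n = len(xc)
        for k in range(len(freqs)):
            xk = sum(xc[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
            assert mag[k] == pytest.approx(abs(xk), abs=1e-9)

    def test_parseval_relation(self, rng):
        x = rng.normal(0, 2, 64)
        prof = VelocityProfile(velocity=x, dt=1e-3)
        _, mag = profile_spectrum(prof)
        xc = x - x.mean()
        lhs = mag[0] ** 2 + 2 * np.sum(mag[1:-1] ** 2) + mag[-1] ** 2  # even N
        assert lhs == pytest.approx(len(xc) * np.sum(xc**2))
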