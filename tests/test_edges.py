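"""Thresholding edge searches against brute-force oracles and invariants."""

import numpy as np
import pytest

from dopplertrace import (
    EdgeProfile,
    GrayImage,
    RegionOfInterest,
    average_profiles,
    column_max,
    detect_edges_method1,
    detect_edges_method2,
)

from conftest import make_gray


def oracle_method1(pix, roi, theta1):
    """Exhaustive scan of every ROI row per column (order-free definition)."""
    upper, lower = [], []
    for x in range(pix.shape[1]):
        col = pix[roi.n_up : roi.n_lo + 1, x]
        mmax = col.max()
        rows = [roi.n_up + y for y, v in enumerate(col) if v > theta1 * mmax]
        upper.append(min(rows) if rows else np.nan)
        lower.append(max(rows) if rows else np.nan)
    return np.array(upper), np.array(lower)


def oracle_method2(pix, roi, theta2, a):
    """Walk from the near-baseline window maximum outward, stop below cutoff."""
    upper, lower = [], []
    for x in range(pix.shape[1]):
        col = pix[:, x]
        win = col[roi.y_base - a : roi.y_base + 1]
        if win.max() == 0:
            upper.append(np.nan)
        else:
            r = roi.y_base - a + int(np.argmax(win))
            cut = theta2 * win.max()
            while r - 1 >= roi.n_up and col[r - 1] >= cut:
                r -= 1
            upper.append(r)
        win = col[roi.y_base : roi.y_base + a + 1]
        if win.max() == 0:
            lower.append(np.nan)
        else:
            r = roi.y_base + int(np.argmax(win))
            cut = theta2 * win.max()
            while r + 1 <= roi.n_lo and col[r + 1] >= cut:
                r += 1
            lower.append(r)
    return np.array(upper), np.array(lower)


class TestColumnMax:
    def test_simple_column(self):
        img = make_gray(np.array([[0, 50, 200, 50, 0]], dtype=float).T.repeat(2, axis=1))
        cm = column_max(img, 0, 0, 4)
        assert cm.value == 200 and cm.row == 2

    def test_constant_column_ties_to_first_row(self):
        img = make_gray(np.full((6, 3), 42.0))
        cm = column_max(img, 1, 2, 5)
        assert cm.value == 42 and cm.row == 2

    def test_single_row_range(self):
        img = make_gray(np.arange(12.0).reshape(4, 3))
        cm = column_max(img, 2, 3, 3)
        assert cm.value == 11 and cm.row == 3

    def test_empty_range_raises(self):
        img = make_gray(np.zeros((4, 3)))
        with pytest.raises(IndexError):
            column_max(img, 0, 3, 2)


class TestMethod1:
    def test_block_column_recovers_block_bounds(self):
        pix = np.zeros((40, 1))
        pix[10:21, 0] = 200.0
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=0, n_lo=39, y_base=15)
        prof = detect_edges_method1(img, roi, theta1=0.3)
        assert prof.upper[0] == 10 and prof.lower[0] == 20

    def test_all_zero_column_is_missing(self):
        pix = np.zeros((20, 3))
        pix[8:12, 0] = 100.0  # only column 0 has signal
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=0, n_lo=19, y_base=10)
        prof = detect_edges_method1(img, roi, theta1=0.5)
        assert np.isnan(prof.upper[1]) and np.isnan(prof.lower[2])
        assert not np.isnan(prof.upper[0])

    def test_matches_exhaustive_oracle_on_random_images(self, rng):
        roi = RegionOfInterest(n_up=3, n_lo=44, y_base=20)
        for _ in range(50):
            pix = rng.uniform(0, 255, size=(48, 1)) * (rng.random((48, 1)) > 0.3)
            theta1 = rng.uniform(0.05, 0.95)
            img = GrayImage(pix)
            prof = detect_edges_method1(img, roi, theta1)
            exp_up, exp_lo = oracle_method1(pix, roi, theta1)
            np.testing.assert_array_equal(prof.upper, exp_up)
            np.testing.assert_array_equal(prof.lower, exp_lo)

    def test_invariant_to_intensity_scaling(self, rng):
        pix = rng.uniform(0, 120, size=(30, 20))
        roi = RegionOfInterest(n_up=1, n_lo=28, y_base=14)
        base = detect_edges_method1(GrayImage(pix), roi, 0.4)
        scaled = detect_edges_method1(GrayImage(pix * 2.0), roi, 0.4)
        np.testing.assert_array_equal(base.upper, scaled.upper)
        np.testing.assert_array_equal(base.lower, scaled.lower)

    def test_mask_removes_text_artifact_outlier(self):
        pix = np.zeros((40, 5))
        pix[18:23, :] = 180.0           # true envelope band around baseline
        pix[2:5, 1:3] = 250.0           # bright "text" in the ROI corner
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=0, n_lo=39, y_base=20)
        unmasked = detect_edges_method1(img, roi, 0.3)
        assert unmasked.upper[1] == 2    # search latches onto the text
        mask = np.zeros_like(pix, dtype=bool)
        mask[2:5, 1:3] = True
        masked = detect_edges_method1(img, roi, 0.3, mask=mask)
        assert masked.upper[1] == 18


class TestMethod2:
    def test_linear_decay_column_stops_at_threshold(self):
        # intensity falls linearly from 200 at the baseline to 0 at the top
        n = 51
        pix = np.zeros((n, 1))
        yb = 40
        for r in range(yb + 1):
            pix[r, 0] = 200.0 * (1 - (yb - r) / yb)
        pix[yb:, 0] = 200.0
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=0, n_lo=n - 1, y_base=yb)
        prof = detect_edges_method2(img, roi, theta2=0.05, a=5)
        cut = 0.05 * 200.0
        rows = np.arange(n)
        expected = rows[(pix[:, 0] >= cut) & (rows <= yb)].min()
        assert prof.upper[0] == expected

    def test_constant_column_runs_to_roi_borders(self):
        pix = np.full((30, 2), 100.0)
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=2, n_lo=27, y_base=14)
        prof = detect_edges_method2(img, roi, theta2=0.1, a=4)
        assert np.all(prof.upper == 2) and np.all(prof.lower == 27)

    def test_zero_window_marks_half_column_missing(self):
        pix = np.zeros((30, 1))
        pix[16:25, 0] = 150.0  # signal only below the baseline
        img = GrayImage(pix)
        roi = RegionOfInterest(n_up=2, n_lo=27, y_base=14)
        prof = detect_edges_method2(img, roi, theta2=0.1, a=4)
        assert np.isnan(prof.upper[0]) and prof.lower[0] == 24

    def test_matches_walk_oracle_on_random_decay_columns(self, rng):
        roi = RegionOfInterest(n_up=2, n_lo=45, y_base=24)
        a = 6
        for _ in range(50):
            # monotone decay away from the baseline plus noise floor
            dist = np.abs(np.arange(48)[:, None] - roi.y_base)
            pix = np.clip(
                220 * np.exp(-dist / rng.uniform(3, 15)) + rng.uniform(0, 4, (48, 4)),
                0, 255,
            )
            theta2 = rng.uniform(0.02, 0.5)
            prof = detect_edges_method2(GrayImage(pix), roi, theta2, a)
            exp_up, exp_lo = oracle_method2(pix, roi, theta2, a)
            np.testing.assert_array_equal(prof.upper, exp_up)
            np.testing.assert_array_equal(prof.lower, exp_lo)

    def test_window_larger_than_half_height_rejected(self):
        img = make_gray(np.zeros((30, 2)))
        roi = RegionOfInterest(n_up=2, n_lo=27, y_base=14)
        with pytest.raises(ValueError):
            detect_edges_method2(img, roi, theta2=0.1, a=13)


class TestOrderingAndStructure:
    def test_method2_envelope_encloses_method1_on_decay_columns(self, rng):
        """Method 1 underestimates and method 2 overestimates the magnitude."""
        roi = RegionOfInterest(n_up=2, n_lo=45, y_base=24)
        dist = np.abs(np.arange(48)[:, None] - roi.y_base)
        pix = np.clip(220 * np.exp(-dist / rng.uniform(4, 12, size=(1, 30))), 0, 255)
        img = GrayImage(pix)
        e1 = detect_edges_method1(img, roi, theta1=0.3)
        e2 = detect_edges_method2(img, roi, theta2=0.05, a=6)
        assert np.all(e2.upper <= e1.upper)
        assert np.all(e2.lower >= e1.lower)

    def test_edges_stay_inside_roi_and_one_per_column(self, noisy_spectrogram):
        img, gt = noisy_spectrogram
        roi = gt.roi
        for prof in (
            detect_edges_method1(img, roi, 0.3),
            detect_edges_method2(img, roi, 0.05, a=10),
        ):
            assert prof.n_cols == img.n_cols
            ok = ~np.isnan(prof.upper)
            assert np.all(prof.upper[ok] >= roi.n_up)
            assert np.all(prof.upper[ok] <= roi.y_base)
            ok = ~np.isnan(prof.lower)
            assert np.all(prof.lower[ok] >= roi.y_base)
            assert np.all(prof.lower[ok] <= roi.n_lo)


class TestAverageProfiles:
    def test_identical_profiles_average_to_themselves(self):
        p = EdgeProfile(upper=[10, 11, np.nan], lower=[30, 31, np.nan], method_tag="method1")
        avg = average_profiles(p, p)
        np.testing.assert_array_equal(avg.upper, p.upper)
        np.testing.assert_array_equal(avg.lower, p.lower)
        assert avg.method_tag == "averaged"

    def test_elementwise_mean_and_missing_policy(self):
        e1 = EdgeProfile(upper=[100, np.nan, np.nan], lower=[200, 210, np.nan], method_tag="method1")
        e2 = EdgeProfile(upper=[90, 80, np.nan], lower=[204, np.nan, np.nan], method_tag="method2")
        avg = average_profiles(e1, e2)
        assert avg.upper[0] == 95            # arithmetic mean
        assert avg.upper[1] == 80            # present + missing -> present
        assert np.isnan(avg.upper[2])        # both missing -> missing
        assert avg.lower[0] == 202 and avg.lower[1] == 210

    def test_random_profiles_match_loop_oracle(self, rng):
        n = 40
        u1, u2 = rng.uniform(0, 50, n), rng.uniform(0, 50, n)
        l1, l2 = rng.uniform(60, 100, n), rng.uniform(60, 100, n)
        avg = average_profiles(
            EdgeProfile(upper=u1, lower=l1, method_tag="method1"),
            EdgeProfile(upper=u2, lower=l2, method_tag="method2"),
        )
        for i in range(n):
            assert avg.upper[i] == pytest.approx((u1[i] + u2[i]) / 2)
            assert avg.lower[i] == pytest.approx((l1[i] + l2[i]) / 2)

    def test_mismatched_lengths_rejected(self):
        e1 = EdgeProfile(upper=[1.0, 2.0], lower=[5.0, 6.0], method_tag="m")
        e2 = EdgeProfile(upper=[1.0], lower=[5.0], method_tag="m")
        with pytest.raises(ValueError):
            average_profiles(e1, e2)
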