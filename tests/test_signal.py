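"""Curve conditioning: median smoothing, rezeroing, ST correction, excursion.

Brute-force oracles are written independently of the implementation:
medians from explicit sorted windows, Pearson from the textbook formula,
excursion as a max-minus-min loop.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import plmotion as pm
from plmotion.signal import _running_median

from conftest import make_curve


def brute_median(x, window):
    half = window // 2
    n = len(x)
    out = []
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out.append(sorted(x[i - k : i + k + 1])[k])
    return np.array(out, dtype=float)


def brute_pearson(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum()))


series = st_.lists(
    st_.floats(min_value=-100, max_value=100, allow_nan=False), min_size=1, max_size=40
)


class TestSmoothMedian:
    def test_spike_removed_by_window_five(self, curve_factory):
        out = pm.smooth_median(curve_factory([0, 0, 10, 0, 0]), window=5)
        assert np.allclose(out.x_mm, 0.0)
        assert out.stage == "smoothed"

    def test_constant_series_unchanged(self, curve_factory):
        out = pm.smooth_median(curve_factory([3.0] * 7))
        assert np.allclose(out.x_mm, 3.0)

    def test_window_one_is_identity(self, curve_factory):
        x = [1.0, -2.0, 5.0, 0.0]
        out = pm.smooth_median(curve_factory(x), window=1)
        assert np.allclose(out.x_mm, x)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, curve_factory, window):
        with pytest.raises(ValueError):
            pm.smooth_median(curve_factory([1.0, 2.0]), window=window)

    @given(x=series, window=st_.sampled_from([1, 3, 5, 7]))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_with_shrinking_edges(self, x, window):
        assert np.allclose(_running_median(np.array(x), window), brute_median(x, window))

    @given(x=series)
    @settings(max_examples=100, deadline=None)
    def test_no_overshoot(self, x):
        out = _running_median(np.array(x), 5)
        assert out.min() >= min(x) - 1e-12 and out.max() <= max(x) + 1e-12

    def test_missing_samples_stay_missing(self, curve_factory):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        out = pm.smooth_median(curve_factory(x), window=3)
        assert np.isnan(out.x_mm[2]) and not np.isnan(out.x_mm[1])


class TestRezero:
    def test_subtracts_first_sample(self, curve_factory):
        out = pm.rezero(curve_factory([5.0, 6.0, 7.0], stage="smoothed"))
        assert np.allclose(out.x_mm, [0.0, 1.0, 2.0])
        assert out.stage == "rezeroed"

    def test_zero_start_series_unchanged(self, curve_factory):
        out = pm.rezero(curve_factory([0.0, 1.0, -2.0], stage="smoothed"))
        assert np.allclose(out.x_mm, [0.0, 1.0, -2.0])

    def test_idempotent(self, curve_factory):
        once = pm.rezero(curve_factory([5.0, 6.0, 7.0], stage="smoothed"))
        twice = pm.rezero(once)
        assert np.allclose(once.x_mm, twice.x_mm)

    def test_requires_smoothed_stage(self, curve_factory):
        with pytest.raises(ValueError, match="pipeline order"):
            pm.rezero(curve_factory([1.0, 2.0], stage="raw"))


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pm.pearson(x, x) == pytest.approx(1.0)

    def test_sign_flip_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pm.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 100.0]
        assert pm.pearson(np.array(a), np.array(b)) == pytest.approx(brute_pearson(a, b))

    def test_constant_series_raises(self):
        with pytest.raises(pm.ConstantSeriesError):
            pm.pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_pairwise_nan_removal(self):
        a = np.array([1.0, np.nan, 3.0, 4.0, 2.0])
        b = np.array([2.0, 5.0, 6.0, 8.0, 4.0])
        ok = ~np.isnan(a)
        assert pm.pearson(a, b) == pytest.approx(brute_pearson(a[ok], b[ok]))

    @given(x=st_.lists(st_.floats(-50, 50), min_size=3, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_bounded_in_unit_interval(self, x):
        a = np.array(x)
        b = a * 2.0 + np.sin(a)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return
        assert -1.0 - 1e-9 <= pm.pearson(a, b) <= 1.0 + 1e-9


class TestStCorrect:
    def test_identical_curves_fully_removed(self, curve_factory):
        pl = curve_factory([0.0, 1.0, 2.0, 1.0], stage="rezeroed")
        st = curve_factory([0.0, 1.0, 2.0, 1.0], stage="rezeroed", role="soft_tissue")
        out = pm.st_correct(pl, st)
        assert np.allclose(out.x_mm, 0.0)
        assert out.corrected and out.st_corr_r == pytest.approx(1.0)
        assert out.stage == "st_corrected"

    def test_uncorrelated_curve_passes_through(self, curve_factory):
        t = np.arange(40, dtype=float)
        pl = curve_factory(np.sin(t), stage="rezeroed", t=t)
        st = curve_factory(np.cos(t), stage="rezeroed", role="soft_tissue", t=t)
        out = pm.st_correct(pl, st)
        assert out.corrected is False
        assert np.allclose(out.x_mm, pl.x_mm)
        assert abs(out.st_corr_r) < 0.5

    def test_strong_anticorrelation_does_not_subtract(self, curve_factory):
        pl = curve_factory([0.0, 1.0, 2.0, 3.0], stage="rezeroed")
        st = curve_factory([0.0, -1.0, -2.0, -3.0], stage="rezeroed", role="soft_tissue")
        out = pm.st_correct(pl, st)
        assert out.corrected is False
        assert out.st_corr_r == pytest.approx(-1.0)
        assert np.allclose(out.x_mm, pl.x_mm)

    def test_threshold_is_inclusive(self, curve_factory):
        # the gate fires at r == threshold exactly (>= is inclusive)
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        b = a + rng.normal(size=200)
        pl = curve_factory(a, stage="rezeroed")
        st = curve_factory(b, stage="rezeroed", role="soft_tissue")
        r = pm.pearson(a, b)
        out = pm.st_correct(pl, st, threshold=r)
        assert out.corrected is True and out.st_corr_r == pytest.approx(r)

    def test_constant_st_means_no_correction(self, curve_factory):
        pl = curve_factory([0.0, 1.0, 2.0], stage="rezeroed")
        st = curve_factory([0.0, 0.0, 0.0], stage="rezeroed", role="soft_tissue")
        out = pm.st_correct(pl, st)
        assert out.corrected is False and np.isnan(out.st_corr_r)

    def test_mismatched_time_base_rejected(self, curve_factory):
        pl = curve_factory([0.0, 1.0, 2.0], stage="rezeroed")
        st = curve_factory([0.0, 1.0, 2.0], stage="rezeroed", role="soft_tissue",
                           t=np.array([0.0, 0.5, 1.5]))
        with pytest.raises(ValueError, match="time base"):
            pm.st_correct(pl, st)

    def test_requires_rezeroed_inputs(self, curve_factory):
        pl = curve_factory([0.0, 1.0, 2.0], stage="smoothed")
        st = curve_factory([0.0, 1.0, 2.0], stage="rezeroed", role="soft_tissue")
        with pytest.raises(ValueError, match="pipeline order"):
            pm.st_correct(pl, st)

    def test_gate_monotone_in_common_mode_amplitude(self):
        # more shared probe motion can only raise the PL-vs-ST correlation
        t = np.linspace(0, 3, 61)
        pleural = 2.0 * np.sin(2 * np.pi * 0.5 * t)
        tissue = 0.5 * np.sin(2 * np.pi * 0.3 * t + 1.0)
        probe = t / t.max()
        last = -1.0
        for amp in [0.0, 1.0, 2.0, 4.0, 8.0]:
            r = pm.pearson(pleural + amp * probe, tissue + amp * probe)
            assert r >= last - 1e-9
            last = r


class TestExcursion:
    def test_constant_curve_zero(self, curve_factory):
        assert pm.max_excursion(curve_factory([2.0] * 5, stage="st_corrected")) == 0.0

    def test_brute_force_example(self, curve_factory):
        assert pm.max_excursion(
            curve_factory([0.0, 1.0, 3.0, 2.0, -1.0], stage="st_corrected")
        ) == pytest.approx(4.0)

    def test_all_missing_rejected(self, curve_factory):
        with pytest.raises(ValueError, match="no valid samples"):
            pm.max_excursion(curve_factory([np.nan, np.nan], stage="st_corrected"))

    def test_requires_corrected_stage(self, curve_factory):
        with pytest.raises(ValueError, match="pipeline order"):
            pm.max_excursion(curve_factory([0.0, 1.0], stage="raw"))

    @given(x=series)
    @settings(max_examples=200, deadline=None)
    def test_matches_max_minus_min_loop(self, x):
        hi, lo = x[0], x[0]
        for v in x:
            hi, lo = max(hi, v), min(lo, v)
        got = pm.max_excursion(make_curve(x, stage="st_corrected"))
        assert got == pytest.approx(hi - lo)

    def test_full_period_sinusoid_close_to_twice_amplitude(self, curve_factory):
        t = np.arange(0, 4, 0.05)
        a = 3.0
        raw = curve_factory(a * np.sin(2 * np.pi * 0.5 * t), t=t)
        smoothed = pm.rezero(pm.smooth_median(raw))
        st = pm.rezero(pm.smooth_median(
            curve_factory(np.zeros_like(t) + 1e-12 * t, role="soft_tissue", t=t)))
        corrected = pm.st_correct(smoothed, st)
        assert pm.max_excursion(corrected) == pytest.approx(2 * a, rel=0.02)

    def test_translation_invariance_pre_rezero(self, curve_factory):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        def run(shift):
            raw = curve_factory(x + shift)
            st = curve_factory(rng.normal(size=50) * 0 + np.linspace(0, 1e-9, 50),
                               role="soft_tissue")
            pl = pm.rezero(pm.smooth_median(raw))
            stc = pm.st_correct(pl, pm.rezero(pm.smooth_median(st)))
            return pm.max_excursion(stc)
        assert run(0.0) == pytest.approx(run(123.4))


class TestClipPlMovement:
    def test_max_selection(self):
        val, role = pm.clip_pl_movement(
            {"pleural_left": 2.0, "pleural_central": 5.4, "pleural_right": 3.1}
        )
        assert val == 5.4 and role == "pleural_central"

    def test_single_survivor(self):
        val, role = pm.clip_pl_movement({"pleural_right": 1.5})
        assert val == 1.5 and role == "pleural_right"

    def test_tie_breaks_left_first(self):
        val, role = pm.clip_pl_movement({"pleural_central": 4.0, "pleural_left": 4.0})
        assert val == 4.0 and role == "pleural_left"

    def test_no_survivors_raises_toward_qc(self):
        with pytest.raises(ValueError, match="redo/discard"):
            pm.clip_pl_movement({})


class TestEndToEndCorrection:
    def test_probe_drift_removed_and_truth_recovered(self, drift_clip):
        spec, frames, truth = drift_clip
        trajs = pm.track_landmarks(frames, pm.default_seeds(spec), fps=spec.fps)
        cal = pm.calibrate((0, 0), (spec.px_per_mm * 10, 0), 10.0)
        by_role = {t.role: t for t in trajs}
        pl_curves = [pm.to_motion_curve(by_role[r], cal) for r in pm.PLEURAL_ROLES]
        st_curve = pm.to_motion_curve(by_role[pm.SOFT_TISSUE], cal)
        corrected, st_proc = pm.process_clip_curves(pl_curves, st_curve)
        truth_rel = truth.pleural_x_mm - truth.pleural_x_mm[0]
        tracker_err_mm = 1.0 / spec.px_per_mm  # 1 px reference-tracker bound
        for curve in corrected.values():
            assert curve.corrected is True
            assert np.nanmax(np.abs(curve.x_mm - truth_rel)) <= 1.5 * tracker_err_mm
            # the corrected curve no longer follows the soft-tissue motion
            assert pm.pearson(curve.x_mm, st_proc.x_mm) < 0.5
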