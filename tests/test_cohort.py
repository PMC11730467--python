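"""Spline smoother, autumn-window detection, overlap index, classification."""

import numpy as np
import pandas as pd
import pytest

from coashift import (
    CohortTimingModel,
    RunConfig,
    SimScenario,
    classify_cohort_timing,
    detect_autumn_window,
    fit_age_smoother,
    overlap_index,
    simulate_banding,
)
from coashift.cohort import DegenerateCurveError, FittedCohortCurve, fit_penalized_spline


def _curve(days, values, age="X"):
    return FittedCohortCurve(age, np.asarray(days, int), np.asarray(values, float), 10, 1.0, 999)


class TestSmoother:
    def test_noiseless_line_reproduced(self, rng):
        day = rng.uniform(100, 300, 800)
        lat = 50.0 - 0.05 * day
        grid = np.arange(110, 291, dtype=float)
        fit = fit_penalized_spline(day, lat, grid)
        np.testing.assert_allclose(fit.values, 50.0 - 0.05 * grid, atol=0.01)

    def test_identical_record_sets_give_identical_curves(self, rng):
        n = 1200
        df = pd.DataFrame({
            "julian_day": rng.integers(150, 330, n),
            "latitude": rng.normal(40, 2, n),
            "age_class": np.where(np.arange(n) % 2 == 0, "HY", "AHY"),
        })
        # duplicate each row into both classes so the two sets coincide
        both = pd.concat([df.assign(age_class="HY"), df.assign(age_class="AHY")])
        curves = fit_age_smoother(both)
        np.testing.assert_allclose(curves["HY"].values, curves["AHY"].values, atol=1e-9)

    def test_recovers_generating_sigmoid(self):
        sc = SimScenario(seed=13, banding_noise_lat=1.0)
        band = simulate_banding(sc, "sp", n_records=5000, cohort_separation=0.0)
        curves = fit_age_smoother(band, window=(180, 320))
        # generating mean curve: sigmoid averaged over the N(mean, spread)
        # distribution of individual passage midpoints
        t = np.linspace(sc.adult_mean_day - 5 * sc.passage_spread,
                        sc.adult_mean_day + 5 * sc.passage_spread, 801)
        w = np.exp(-0.5 * ((t - sc.adult_mean_day) / sc.passage_spread) ** 2)
        w /= w.sum()
        for curve in curves.values():
            d = curve.days.astype(float)
            prog = 1.0 / (1.0 + np.exp(-(d[:, None] - t[None, :]) / sc.transit_width_days))
            truth = (sc.breeding_lat
                     + (sc.nonbreeding_lat - sc.breeding_lat) * (prog @ w))
            frac_close = np.mean(np.abs(curve.values - truth) < 0.5)
            assert frac_close >= 0.95


class TestAutumnWindow:
    def test_monotone_decline_found(self):
        days = np.arange(1, 366)
        vals = np.where(days < 180, 48.0, np.where(days <= 300, 48.0 - 0.1 * (days - 180), 36.0))
        win = detect_autumn_window(days, vals)
        assert abs(win[0] - 180) <= 5 and abs(win[1] - 300) <= 5

    def test_flat_curve_none(self):
        days = np.arange(1, 366)
        assert detect_autumn_window(days, np.full(365, 40.0)) is None

    def test_autumn_selected_not_spring(self):
        days = np.arange(1, 366)
        vals = np.full(365, 36.0)
        vals[60:120] = 36.0 + 0.2 * np.arange(60)  # spring northward
        vals[120:240] = 48.0
        vals[240:300] = 48.0 - 0.2 * np.arange(60)  # autumn southward
        vals[300:] = 36.0
        win = detect_autumn_window(days, vals)
        assert win[0] >= 235 and win[1] <= 305


class TestOverlapIndex:
    def test_identical_curves_one(self):
        days = np.arange(200, 301)
        f = 40 - 0.05 * (days - 200.0)
        assert overlap_index(_curve(days, f), _curve(days, f)) == pytest.approx(1.0)

    def test_disjoint_support_zero(self):
        days = np.arange(0, 101)
        a = np.where(days < 40, 1.0, 0.0)
        b = np.where(days > 60, 1.0, 0.0)
        assert overlap_index(_curve(days, a), _curve(days, b)) == pytest.approx(0.0)

    def test_matches_fine_grid_integrator(self):
        """Trapezoid min/max on the day grid equals dense numerical
        integration of the piecewise-linear interpolants."""
        days = np.arange(0, 51)
        a = np.sin(days / 50 * np.pi)
        b = (days / 50.0) ** 2
        got = overlap_index(_curve(days, a), _curve(days, b))
        fine = np.linspace(0, 50, 50 * 200 + 1)

        def norm(v):
            return (v - v.min()) / (v.max() - v.min())

        fa = np.interp(fine, days, norm(a))
        fb = np.interp(fine, days, norm(b))
        oracle = np.trapezoid(np.minimum(fa, fb), fine) / np.trapezoid(np.maximum(fa, fb), fine)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_symmetric_and_affine_invariant(self, rng):
        days = np.arange(100, 201)
        a = rng.normal(40, 1, 101).cumsum() / 50
        b = rng.normal(38, 1, 101).cumsum() / 50
        i1 = overlap_index(_curve(days, a), _curve(days, b))
        i2 = overlap_index(_curve(days, b), _curve(days, a))
        i3 = overlap_index(_curve(days, 3.0 * a - 7.0), _curve(days, b))
        assert i1 == pytest.approx(i2, rel=1e-12)
        assert i1 == pytest.approx(i3, rel=1e-10)

    def test_constant_curve_degenerate(self):
        days = np.arange(0, 11)
        with pytest.raises(DegenerateCurveError):
            overlap_index(_curve(days, np.full(11, 2.0)), _curve(days, days / 10.0))


class TestClassification:
    @pytest.mark.parametrize("idx,expect", [
        (0.90, "mixed_age"),
        (0.85, "age_separated"),  # strict inequality at the threshold
        (0.10, "age_separated"),
    ])
    def test_threshold_rule(self, idx, expect):
        assert classify_cohort_timing(idx) == expect

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_cohort_timing(1.2)


class TestCohortTimingModel:
    def test_overlap_monotone_in_separation(self):
        sc = SimScenario(seed=21, passage_spread=5.0)
        vals, classes = [], []
        for sep in (0, 10, 20, 30, 40):
            band = simulate_banding(sc, "sp", seed=100, cohort_separation=float(sep))
            res = CohortTimingModel(band).fit()
            vals.append(res.overlap_index)
            classes.append(res.classification)
        assert all(b <= a + 0.02 for a, b in zip(vals, vals[1:]))
        # the auto-detected window keeps the shared plateaus, so the index
        # floors well above 0 at 40 days but far below the 0.85 threshold
        assert vals[0] > 0.95 and vals[-1] < 0.65
        assert classes[0] == "mixed_age" and classes[-1] == "age_separated"

    def test_insufficient_records_total(self):
        band = simulate_banding(SimScenario(seed=5), "sp", n_records=400)
        res = CohortTimingModel(band).fit()
        assert res.classification == "insufficient_data"

    def test_manual_window_override(self):
        sc = SimScenario(seed=6)
        band = simulate_banding(sc, "sp", n_records=3000)
        cfg = RunConfig(autumn_window=(220, 290))
        res = CohortTimingModel(band, config=cfg).fit()
        assert res.window == (220, 290)
        assert res.classification in ("mixed_age", "age_separated")
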