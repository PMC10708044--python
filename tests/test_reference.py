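import datetime

import numpy as np
import pytest

import frostmap as fm
from frostmap.reference import (SmfBounds, fit_smf, multi_year_average,
                                smf_transform, smf_transform_stack)

START = datetime.date(2018, 3, 1)


def make(values):
    return fm.DailyCurve(START, np.asarray(values, dtype=float))


class TestMultiYearAverage:
    def test_mean_of_identical_curves_is_identity(self, season_curve):
        out = multi_year_average([season_curve, season_curve])
        np.testing.assert_allclose(out.values, season_curve.values)

    def test_constant_curves(self):
        out = multi_year_average([make(np.full(10, 0.2)), make(np.full(10, 0.4))])
        np.testing.assert_allclose(out.values, 0.3)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(3)
        curves = [make(rng.uniform(0, 1, 30)) for _ in range(5)]
        out = multi_year_average(curves)
        expected = sum(c.values for c in curves) / 5.0
        np.testing.assert_allclose(out.values, expected, atol=1e-15)

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError, match="length"):
            multi_year_average([make(np.zeros(10)), make(np.zeros(12))])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            multi_year_average([])


class TestSmfTransform:
    def test_identity_under_unit_scaling(self, season_curve):
        for bias in (0.0, 0.61, 2.0):
            h = smf_transform(season_curve, 1.0, 1.0, 0.0, bias)
            np.testing.assert_allclose(h.values, season_curve.values, atol=1e-12)

    def test_constant_curve_closed_form(self):
        h = smf_transform(make(np.full(20, 0.5)), 1.0, 2.0, 0.0, 0.61)
        np.testing.assert_allclose(h.values, 2 * (0.5 + 0.61) - 0.61)

    def test_triangular_curve_matches_pointwise_oracle(self):
        g = make(np.concatenate([np.linspace(0, 1, 30), np.linspace(1, 0, 30)[1:]]))
        sx, sy, t0, bias = 1.05, 1.2, 3.0, 0.61
        h = smf_transform(g, sx, sy, t0, bias)
        x = np.arange(len(g), dtype=float)
        for i in range(len(g)):  # independent pointwise evaluation
            arg = np.clip(sx * (i + t0), 0, len(g) - 1)
            lo = int(np.floor(arg))
            hi = min(lo + 1, len(g) - 1)
            gval = g.values[lo] + (arg - lo) * (g.values[hi] - g.values[lo])
            assert h.values[i] == pytest.approx(sy * (gval + bias) - bias, abs=1e-12)

    def test_sy_one_is_bias_independent(self, season_curve):
        a = smf_transform(season_curve, 1.05, 1.0, -2.0, 0.0)
        b = smf_transform(season_curve, 1.05, 1.0, -2.0, 5.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_out_of_box_parameters_warn(self, season_curve):
        with pytest.warns(UserWarning, match="outside the standard box"):
            smf_transform(season_curve, 1.5, 1.0, 0.0)

    def test_stack_transform_matches_per_pixel_curve_transform(self, season_curve):
        rng = np.random.default_rng(4)
        stack = np.stack([season_curve.values + rng.normal(0, 0.02, len(season_curve))
                          for _ in range(6)]).T.reshape(len(season_curve), 2, 3)
        out = smf_transform_stack(stack, 1.05, 1.2, -3.0, 0.61)
        for r in range(2):
            for c in range(3):
                expected = smf_transform(make(stack[:, r, c]), 1.05, 1.2, -3.0, 0.61,
                                         bounds=None)
                np.testing.assert_allclose(out[:, r, c], expected.values, atol=1e-12)


class TestFitSmf:
    def test_self_fit_returns_identity(self, season_curve):
        fit = fit_smf(season_curve, season_curve)
        assert (fit.sx, fit.sy, fit.t0) == pytest.approx((1.0, 1.0, 0.0), abs=1e-6)
        assert fit.objective < 1e-10

    def test_noise_free_parameter_recovery(self, season_curve):
        truth = (1.05, 1.3, -4.0)
        target = smf_transform(season_curve, *truth, 0.61)
        fit = fit_smf(season_curve, target)
        assert fit.sx == pytest.approx(truth[0], abs=0.01)
        assert fit.sy == pytest.approx(truth[1], abs=0.02)
        assert fit.t0 == pytest.approx(truth[2], abs=0.5)

    def test_noisy_recovery_over_seeds(self, season_curve):
        target = smf_transform(season_curve, 1.05, 1.3, -4.0, 0.61)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = make(target.values + rng.normal(0, 0.02, len(target)))
            fit = fit_smf(season_curve, noisy)
            hits += (abs(fit.sx - 1.05) <= 0.03 and abs(fit.sy - 1.3) <= 0.06
                     and abs(fit.t0 + 4.0) <= 1.5)
        assert hits >= 9

    def test_never_worse_than_no_transformation(self, season_curve):
        rng = np.random.default_rng(5)
        target = make(season_curve.values + rng.normal(0, 0.05, len(season_curve)))
        fit = fit_smf(season_curve, target)
        identity_rmse = np.sqrt(np.mean((season_curve.values - target.values) ** 2))
        assert fit.objective <= identity_rmse + 1e-12

    def test_coarse_lattice_oracle_cannot_beat_fitter(self, season_curve):
        """Independent triple-loop grid search never improves on the fit."""
        rng = np.random.default_rng(6)
        target = make(smf_transform(season_curve, 0.95, 0.8, 5.0, 0.61).values
                      + rng.normal(0, 0.01, len(season_curve)))
        fit = fit_smf(season_curve, target)
        x = np.arange(len(season_curve), dtype=float)
        best = np.inf
        for sx in np.arange(0.9, 1.1001, 0.01):
            for sy in np.arange(0.5, 1.8501, 0.05):
                for t0 in np.arange(-10, 10.5, 1.0):
                    gv = np.interp(sx * (x + t0), x, season_curve.values)
                    h = sy * (gv + 0.61) - 0.61
                    best = min(best, np.sqrt(np.mean((h - target.values) ** 2)))
        assert fit.objective <= best + 1e-3

    def test_degenerate_target_warns(self, season_curve):
        with pytest.warns(UserWarning, match="zero variance"):
            fit_smf(season_curve, make(np.full(len(season_curve), 0.4)))

    def test_weight_vector_steers_the_fit(self, season_curve):
        # zero weight on the second half makes the fit ignore a corrupted tail
        target = smf_transform(season_curve, 1.02, 1.1, 2.0, 0.61)
        corrupted = target.values.copy()
        corrupted[len(corrupted) // 2:] -= 0.4
        w = np.ones(len(season_curve))
        w[len(w) // 2:] = 0.0
        fit = fit_smf(season_curve, make(corrupted), weights=w)
        assert fit.sy == pytest.approx(1.1, abs=0.02)

    def test_grid_mismatch_raises(self, season_curve):
        other = fm.DailyCurve(START + datetime.timedelta(days=1),
                              season_curve.values.copy())
        with pytest.raises(ValueError, match="grid"):
            fit_smf(season_curve, other)

    def test_bounds_box_membership(self):
        b = SmfBounds()
        assert b.contains(1.0, 1.0, 0.0)
        assert not b.contains(1.2, 1.0, 0.0)
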