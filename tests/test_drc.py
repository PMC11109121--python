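"""Dilution design, viability normalization, 4PL fitting and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codrp.drc import (DoseResponseProfile, FourPL, compute_auc, fit_four_pl,
                       four_pl, make_dilution_series, normalize_viability,
                       profile_auc)
from codrp.errors import ControlError, ValidationError


class TestDilutionSeries:
    def test_default_seven_point_threefold_series(self):
        got = make_dilution_series(50, 3, 7)
        expected = [50, 16.667, 5.556, 1.852, 0.617, 0.206, 0.0686]
        np.testing.assert_allclose(got, expected, rtol=5e-3)
        assert np.all(np.diff(got) < 0)

    def test_simple_twofold_series(self):
        np.testing.assert_allclose(make_dilution_series(10, 2, 3), [10, 5, 2.5])

    @pytest.mark.parametrize("args", [(50, 3, 1), (50, 1.0, 7), (0, 3, 7)])
    def test_degenerate_designs_rejected(self, args):
        with pytest.raises(ValidationError):
            make_dilution_series(*args)


class TestNormalization:
    def _profile(self, conc, reps, dmso):
        return DoseResponseProfile("p", "d", conc, reps, dmso)

    def test_mean_over_replicates_divided_by_control_mean(self):
        prof = self._profile([10, 5], [[80, 100, 120], [200, 200, 200]], [200, 200])
        np.testing.assert_allclose(normalize_viability(prof), [0.5, 1.0])

    def test_readouts_equal_to_control_give_unit_viability(self, dose_grid):
        prof = self._profile(dose_grid, [[300.0]] * len(dose_grid), [300.0, 300.0])
        np.testing.assert_allclose(normalize_viability(prof), 1.0)

    def test_zero_readouts_give_zero_viability(self, dose_grid):
        prof = self._profile(dose_grid, [[0.0]] * len(dose_grid), [100.0])
        np.testing.assert_allclose(normalize_viability(prof), 0.0)

    def test_nonpositive_control_is_control_error(self, dose_grid):
        prof = self._profile(dose_grid, [[1.0]] * len(dose_grid), [0.0, 0.0])
        with pytest.raises(ControlError):
            normalize_viability(prof)


class TestFourPLFit:
    def test_noiseless_parameters_recovered_to_1e6(self, dose_grid):
        truth = (1.0, 0.0, 0.5, 1.0)  # top, bottom, log10_ec50, hill
        v = four_pl(np.log10(dose_grid), *truth)
        fit = fit_four_pl(dose_grid, v)
        assert fit.converged and not fit.fallback_used
        got = (fit.top, fit.bottom, fit.log10_ec50, fit.hill)
        np.testing.assert_allclose(got, truth, atol=1e-6)

    def test_flat_profile_falls_back_and_auc_is_one(self, dose_grid):
        v = np.ones_like(dose_grid)
        fit = fit_four_pl(dose_grid, v)
        assert fit.fallback_used
        res = compute_auc(fit, dose_grid, observed_viability=v)
        assert res.method == "trapezoid_raw"
        assert res.auc == pytest.approx(1.0)

    def test_noisy_ec50_recovered_within_tolerance(self, dose_grid, rng):
        # shallow effect (bottom 0.2, hill 2) with 5% replicate noise
        v_true = four_pl(np.log10(dose_grid), 1.0, 0.2, 0.0, 2.0)
        v_obs = (v_true[:, None] * (1 + 0.05 * rng.standard_normal((7, 3)))).mean(axis=1)
        fit = fit_four_pl(dose_grid, v_obs)
        assert not fit.fallback_used
        assert abs(fit.log10_ec50 - 0.0) < 0.15

    def test_fewer_than_two_distinct_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            fit_four_pl([10, 10], [0.5, 0.5])


class TestAUC:
    def test_unit_and_zero_viability_bracket_the_scale(self, dose_grid):
        flat1 = fit_four_pl(dose_grid, np.ones(7))
        assert compute_auc(flat1, dose_grid, np.ones(7)).auc == pytest.approx(1.0)
        flat0 = fit_four_pl(dose_grid, np.zeros(7))
        assert compute_auc(flat0, dose_grid, np.zeros(7)).auc == pytest.approx(0.0)

    def test_logistic_centered_on_grid_midpoint_gives_half(self, dose_grid):
        x = np.log10(dose_grid)
        mid = 0.5 * (x.max() + x.min())
        fit = FourPL(top=1.0, bottom=0.0, log10_ec50=mid, hill=1.3)
        res = compute_auc(fit, dose_grid)
        assert res.auc == pytest.approx(0.5, abs=1e-9)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValidationError):
            compute_auc(FourPL(1, 0, 0, 1), [10.0])

    @pytest.mark.parametrize("params", [(1.0, 0.0, 0.5, 1.0), (1.2, 0.1, -0.5, 0.9),
                                        (0.9, 0.3, 1.2, 3.0)])
    def test_quadrature_matches_dense_trapezoid_oracle(self, params, dose_grid):
        fit = FourPL(*params)
        res = compute_auc(fit, dose_grid)
        x = np.linspace(np.log10(dose_grid.min()), np.log10(dose_grid.max()), 10_000)
        oracle = np.trapezoid(np.clip(fit.predict_log10(x), 0, 1), x) / (x[-1] - x[0])
        assert res.auc == pytest.approx(oracle, abs=1e-6)

    @given(st.lists(st.floats(0, 2), min_size=7, max_size=7),
           st.lists(st.floats(0, 1), min_size=7, max_size=7))
    @settings(derandomize=True, max_examples=100)
    def test_pointwise_larger_viability_never_lowers_auc(self, base, bump):
        conc = make_dilution_series(50, 3, 7)
        lo = np.array(base)
        hi = lo + np.array(bump)
        fb = FourPL(1, 0, 0, 1, converged=False, fallback_used=True)
        auc_lo = compute_auc(fb, conc, observed_viability=lo).auc
        auc_hi = compute_auc(fb, conc, observed_viability=hi).auc
        assert auc_hi >= auc_lo - 1e-12
        assert 0.0 <= auc_lo <= 1.0 and 0.0 <= auc_hi <= 1.0

    def test_auc_invariant_under_replicate_relabeling(self, dose_grid, rng):
        reps = [rng.uniform(50, 150, size=3) for _ in dose_grid]
        dmso = np.array([140.0, 150.0, 160.0])
        a = profile_auc(DoseResponseProfile("p", "d", dose_grid, reps, dmso)).auc
        shuffled = [r[::-1].copy() for r in reps]
        b = profile_auc(DoseResponseProfile("p", "d", dose_grid, shuffled, dmso[::-1])).auc
        assert a == pytest.approx(b, abs=1e-12)
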