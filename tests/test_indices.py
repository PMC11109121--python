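"""Growth rate, Z-scoring, CODRP distance/index, and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codrp.errors import ValidationError, ZeroVarianceError
from codrp.indices import (IndexConfig, classify, codrp_distance, codrp_index,
                           derive_cutoff_youden, growth_rate, score_cohort,
                           zscore)


class TestGrowthRate:
    @pytest.mark.parametrize(("d1", "d3", "expected"),
                             [(100, 300, 2.0), (150, 150, 0.0), (200, 100, -0.5)])
    def test_relative_area_increase(self, d1, d3, expected):
        assert growth_rate(d1, d3) == pytest.approx(expected)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            growth_rate(0, 100)


class TestZScore:
    def test_sample_sd_example(self):
        np.testing.assert_allclose(zscore([0.2, 0.4, 0.6]), [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_zero_variance_names_the_column(self):
        with pytest.raises(ZeroVarianceError, match="auc"):
            zscore([5.0, 5.0, 5.0], label="auc")

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=20, unique=True))
    @settings(derandomize=True, max_examples=100)
    def test_normalization_identity(self, values):
        z = zscore(values)
        assert abs(z.mean()) < 1e-12
        assert np.std(z, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_population_mode_uses_n_denominator(self):
        z = zscore([0.2, 0.4, 0.6], sd_mode="population")
        np.testing.assert_allclose(z, [-1.22474487, 0.0, 1.22474487], atol=1e-8)


class TestCodrpDistance:
    @pytest.mark.parametrize(("zg", "za", "expected"),
                             [(-4.5, -4.5, 0.0),
                              (0.0, 0.0, 4.5 * math.sqrt(2)),
                              (-1.5, 0.5, math.sqrt(3 ** 2 + 5 ** 2))])
    def test_euclidean_distance_from_reference(self, zg, za, expected):
        assert codrp_distance(zg, za) == pytest.approx(expected, abs=1e-5)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValidationError):
            codrp_distance(float("nan"), 0.0)

    @given(st.floats(-4.4, 5.0), st.floats(-4.4, 5.0), st.floats(1e-6, 2.0))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_increasing_in_each_argument_above_reference(self, zg, za, step):
        base = codrp_distance(zg, za)
        assert codrp_distance(zg + step, za) > base
        assert codrp_distance(zg, za + step) > base


class TestCodrpIndex:
    def test_equally_spaced_distances_zscore_to_unit_steps(self):
        # distances [4, 5, 6] arise from e.g. z pairs on the reference diagonal
        zg = np.array([4 / math.sqrt(2) - 4.5, 5 / math.sqrt(2) - 4.5,
                       6 / math.sqrt(2) - 4.5])
        d, cz = codrp_index(zg, zg)
        np.testing.assert_allclose(d, [4, 5, 6], atol=1e-12)
        np.testing.assert_allclose(cz, [-1, 0, 1], atol=1e-12)

    def test_two_symmetric_patients_raise_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            codrp_index([-1.0, 1.0], [1.0, -1.0])  # equal distances

    def test_patient_at_reference_is_most_sensitive(self):
        zg = np.array([-4.5, 0.0, 1.0])
        za = np.array([-4.5, -1.0, 2.0])
        _, cz = codrp_index(zg, za)
        assert np.argmin(cz) == 0


class TestClassify:
    @pytest.mark.parametrize(("z", "expected"),
                             [(-0.5, "sensitive"), (0.3, "resistant"),
                              (-0.17, "sensitive")])  # tie counts sensitive
    def test_cutoff_semantics(self, z, expected):
        assert classify(z, cutoff=-0.17) == expected


class TestScoreCohort:
    def _toy(self, rng, n=8):
        pids = [f"P{i}" for i in range(n)]
        aucs = dict(zip(pids, rng.uniform(0.2, 0.9, n)))
        growth = dict(zip(pids, rng.uniform(0.1, 1.0, n)))
        return aucs, growth

    def test_permutation_invariance(self, rng):
        aucs, growth = self._toy(rng)
        a = score_cohort(aucs, growth, drug="d")
        perm = list(aucs)[::-1]
        b = score_cohort({p: aucs[p] for p in perm}, {p: growth[p] for p in perm},
                         drug="d")
        for col in ("z_auc", "z_growth", "codrp_z", "call_codrp"):
            assert list(a[col]) == list(b[col])

    def test_affine_shift_of_auc_leaves_scores_unchanged(self, rng):
        aucs, growth = self._toy(rng)
        a = score_cohort(aucs, growth, drug="d")
        b = score_cohort({p: v + 0.07 for p, v in aucs.items()}, growth, drug="d")
        np.testing.assert_allclose(a["z_auc"], b["z_auc"], atol=1e-10)
        np.testing.assert_allclose(a["codrp_z"], b["codrp_z"], atol=1e-10)
        assert list(a["call_codrp"]) == list(b["call_codrp"])

    def test_jittered_constant_growth_reduces_to_auc_ordering(self, rng):
        """Growth spread below the degenerate-variance floor collapses
        z_growth to 0, making the CODRP index a strictly increasing
        transform of z_auc: identical ranking, near-identical calls."""
        aucs, _ = self._toy(rng, n=10)
        growth = {p: 0.5 + 1e-9 * rng.standard_normal() for p in aucs}
        scored = score_cohort(aucs, growth, drug="d")
        assert np.all(scored["z_growth"] == 0.0)
        assert list(scored.sort_values("codrp_z")["patient_id"]) == \
            list(scored.sort_values("z_auc")["patient_id"])

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValidationError):
            score_cohort({"a": 0.5, "b": 0.6}, {"a": 0.1, "c": 0.2}, drug="d")


def test_youden_utility_recovers_a_separating_cutoff():
    z = [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]
    labels = ["sensitive"] * 3 + ["resistant"] * 3
    cut = derive_cutoff_youden(z, labels)
    assert all((v <= cut) == (l == "sensitive") for v, l in zip(z, labels))


def test_index_config_validation():
    with pytest.raises(ValidationError):
        IndexConfig(reference_z=1.0)
    with pytest.raises(ValidationError):
        IndexConfig(sd_mode="robust")
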