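"""Group inference: t test, permutation test, clinical correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from topoconn import (
    SingleLinkageMatrix,
    bonferroni_alpha,
    clinical_correlations,
    compare_barcode_slopes,
    slm_permutation_test,
)


def make_slm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"R{i}" for i in range(values.shape[0]))
    return SingleLinkageMatrix(values=values, roi_labels=labels)


def slm_with_edge(v, p=3):
    """p-node SLM whose (0,1) entry is v and all other pairs 0.9."""
    m = np.full((p, p), 0.9)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = v
    return make_slm(m)


class TestSlopeComparison:
    def test_identical_groups_give_t_zero_p_one(self):
        res = compare_barcode_slopes([-5.0, -6.0, -7.0], [-5.0, -6.0, -7.0])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_pooled_variance_computation(self):
        # means -11 and -7, both sample variances 1, pooled s^2 = 1,
        # t = -4 / sqrt(2/3) = -sqrt(24), df = 4
        res = compare_barcode_slopes([-10.0, -12.0, -11.0], [-6.0, -7.0, -8.0])
        assert res.t_statistic == pytest.approx(-math.sqrt(24), rel=1e-12)
        assert res.degrees_of_freedom == 4
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(math.sqrt(24), 4), rel=1e-9
        )
        assert res.group_means == (-11.0, -7.0)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError, match="pooled variance"):
            compare_barcode_slopes([0.0, 0.0], [0.0, 0.0])

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_barcode_slopes([1.0], [2.0, 3.0])

    def test_welch_option(self):
        res = compare_barcode_slopes(
            [-10.0, -12.0, -11.0], [-6.0, -7.0, -8.0, -9.0], equal_var=False
        )
        ref = stats.ttest_ind(
            [-10.0, -12.0, -11.0], [-6.0, -7.0, -8.0, -9.0], equal_var=False
        )
        assert res.t_statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        slms = [slm_with_edge(v) for v in (0.1, 0.2, 0.3)]
        res = slm_permutation_test(slms, list(slms), n_permutations=200, seed=1)
        assert np.all(res.table["observed_diff"] == 0.0)
        assert np.all(res.table["p_value"] == 1.0)

    def test_p_values_never_zero_and_at_most_one(self):
        a = [slm_with_edge(v) for v in (0.1, 0.11, 0.12)]
        b = [slm_with_edge(v) for v in (0.8, 0.81, 0.82)]
        res = slm_permutation_test(a, b, n_permutations=100, seed=2)
        pv = res.table["p_value"].to_numpy()
        assert np.all(pv > 0) and np.all(pv <= 1)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """3 vs 3, one separated edge: the exhaustive two-sided p over the
        C(6,3) = 20 relabelings is 2/20; Monte-Carlo agrees within 3 SE."""
        a = [slm_with_edge(v) for v in (0.10, 0.12, 0.14)]
        b = [slm_with_edge(v) for v in (0.60, 0.62, 0.64)]

        # independent oracle: enumerate all 20 assignments by hand
        vals = np.array([0.10, 0.12, 0.14, 0.60, 0.62, 0.64])
        obs = vals[3:].mean() - vals[:3].mean()
        count = 0
        for combo in itertools.combinations(range(6), 3):
            ga = vals[list(combo)]
            gb = np.delete(vals, list(combo))
            if abs(gb.mean() - ga.mean()) >= abs(obs):
                count += 1
        p_exact = count / 20
        assert p_exact == pytest.approx(0.1)

        res_ex = slm_permutation_test(a, b, exhaustive=True)
        edge = res_ex.table.query("roi_i == 0 and roi_j == 1").iloc[0]
        assert edge["p_value"] == pytest.approx(p_exact)

        res_mc = slm_permutation_test(a, b, n_permutations=10_000, seed=3)
        p_mc = res_mc.table.query("roi_i == 0 and roi_j == 1").iloc[0]["p_value"]
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_exhaustive_invariant_to_subject_order_within_groups(self):
        a = [slm_with_edge(v) for v in (0.10, 0.12, 0.14)]
        b = [slm_with_edge(v) for v in (0.60, 0.62, 0.64)]
        r1 = slm_permutation_test(a, b, exhaustive=True)
        r2 = slm_permutation_test(a[::-1], b[::-1], exhaustive=True)
        assert r1.table["p_value"].equals(r2.table["p_value"])
        assert r1.table["observed_diff"].equals(r2.table["observed_diff"])

    def test_observed_diff_is_group2_minus_group1(self):
        a = [slm_with_edge(0.1)] * 3
        b = [slm_with_edge(0.5)] * 3
        res = slm_permutation_test(a, b, n_permutations=50, seed=0)
        edge = res.table.query("roi_i == 0 and roi_j == 1").iloc[0]
        assert edge["observed_diff"] == pytest.approx(0.4)

    def test_edgewise_variant_runs(self):
        a = [slm_with_edge(v) for v in (0.1, 0.2, 0.3)]
        res = slm_permutation_test(
            a, list(a), n_permutations=50, seed=4, method="edgewise"
        )
        assert np.all(res.table["p_value"] > 0)

    def test_mismatched_labels_rejected(self):
        a = [slm_with_edge(0.1)]
        bad = SingleLinkageMatrix(
            values=a[0].values, roi_labels=("X", "Y", "Z")
        )
        with pytest.raises(ValueError, match="labels"):
            slm_permutation_test(a, [bad], n_permutations=10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            slm_permutation_test([], [slm_with_edge(0.1)], n_permutations=10)


class TestClinicalCorrelations:
    def test_bonferroni_threshold_for_36_test_family(self):
        # 0.05 over 36 tests -> 0.0014 at 4-decimal precision
        assert round(bonferroni_alpha(0.05, 36), 4) == 0.0014

    def test_perfect_affine_relation_gives_r_one(self):
        slms = [slm_with_edge(0.1 * k + 0.05) for k in range(5)]
        cov = pd.DataFrame(
            {"duration": [2.0 * (0.1 * k + 0.05) + 1.0 for k in range(5)]}
        )
        res = clinical_correlations(slms, [(0, 1)], cov)
        assert res.table["r"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        # SLDs 0.1..0.5 vs covariate (1,3,2,5,4): r = 0.8
        slms = [slm_with_edge(v) for v in (0.1, 0.2, 0.3, 0.4, 0.5)]
        cov = pd.DataFrame({"c": [1.0, 3.0, 2.0, 5.0, 4.0]})
        res = clinical_correlations(slms, [(0, 1)], cov)
        assert res.table["r"].iloc[0] == pytest.approx(0.8, abs=1e-12)
        assert res.table["n"].iloc[0] == 5

    def test_corrected_alpha_uses_explicit_family_size(self):
        slms = [slm_with_edge(v) for v in (0.1, 0.2, 0.3)]
        cov = pd.DataFrame({"c": [1.0, 2.0, 3.0]})
        res = clinical_correlations(slms, [(0, 1)], cov, alpha=0.05, family_size=36)
        assert res.corrected_alpha == pytest.approx(0.05 / 36)

    def test_constant_covariate_flagged_not_dropped(self):
        slms = [slm_with_edge(v) for v in (0.1, 0.2, 0.3)]
        cov = pd.DataFrame({"c": [1.0, 1.0, 1.0]})
        res = clinical_correlations(slms, [(0, 1)], cov)
        row = res.table.iloc[0]
        assert not row["valid"] and math.isnan(row["r"])
        assert len(res.table) == 1

    def test_too_few_subjects_rejected(self):
        slms = [slm_with_edge(0.1), slm_with_edge(0.2)]
        cov = pd.DataFrame({"c": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            clinical_correlations(slms, [(0, 1)], cov)
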