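"""Statistical toolkit: gated comparisons, summary t, Holm, Spearman,
conditional-MLE odds ratio, cross-modal association."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from metaconn import stats as mst
from metaconn.connectivity import subject_connectivity
from metaconn.preproc import RoiSeries


class TestShapiroGate:
    def test_identical_constant_samples_degenerate(self):
        res = mst.shapiro_gate_compare([3, 3, 3, 3], [3, 3, 3])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_identical_normal_samples_t_zero(self):
        x = np.random.default_rng(0).normal(size=20)
        res = mst.shapiro_gate_compare(x, x)
        assert res.statistic_name == "t_welch"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_large_shift_detected_by_t(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        res = mst.shapiro_gate_compare(x, x + 10.0)
        assert res.statistic_name == "t_welch"
        assert res.p < 1e-3

    def test_u_statistic_orientation(self):
        """(1,2,3) vs (4,5,6): first-sample U = 0 by rank-count."""
        res = mst.shapiro_gate_compare([1, 2, 3], [4, 5, 6])
        # samples too small for Shapiro to reject; scipy shapiro needs n>=3
        if res.statistic_name == "U":
            assert res.statistic == 0.0
        else:  # normality passed -> still check the documented U directly
            u = sps.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided")
            assert u.statistic == 0.0

    def test_skewed_data_routes_to_mannwhitney(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(size=40) ** 3
        y = rng.exponential(size=40) ** 3
        res = mst.shapiro_gate_compare(x, y)
        assert res.statistic_name == "U"

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="n >= 3"):
            mst.shapiro_gate_compare([1, 2], [1, 2, 3])


class TestTFromSummary:
    def test_cohort_age_row(self):
        """HC (59.54 +/- 5.13, n=13) vs PD (62.92 +/- 9.48, n=12): t = -1.10."""
        res = mst.t_from_summary(59.54, 5.13, 13, 62.92, 9.48, 12)
        assert res.statistic == pytest.approx(-1.10, abs=5e-3)

    def test_depression_score_row(self):
        """BDI-II (7.62 +/- 6.97, n=13) vs (7.33 +/- 6.08, n=12): t = 0.11."""
        res = mst.t_from_summary(7.62, 6.97, 13, 7.33, 6.08, 12)
        assert res.statistic == pytest.approx(0.11, abs=5e-3)

    def test_equal_means_zero(self):
        assert mst.t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12).statistic == 0.0

    def test_zero_pooled_variance_raises(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            mst.t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_full_data_welch(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1.0, size=rng.integers(5, 30))
        y = rng.normal(0.3, 2.0, size=rng.integers(5, 30))
        res = mst.t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        full = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(full.statistic, rel=1e-10)
        assert res.p == pytest.approx(full.pvalue, rel=1e-8)


class TestHolm:
    def test_single_p_unchanged(self):
        fam = mst.holm_correct([0.03])
        assert fam.adjusted_p[0] == pytest.approx(0.03)

    def test_two_p_step_down(self):
        fam = mst.holm_correct([0.01, 0.04])
        np.testing.assert_allclose(fam.adjusted_p, [0.02, 0.04])

    def test_all_ones(self):
        assert (mst.holm_correct([1.0, 1.0, 1.0]).adjusted_p == 1.0).all()

    def test_matches_hand_stepdown(self):
        """Holm by hand: sort, multiply by (m - rank), cumulative max, cap."""
        rng = np.random.default_rng(3)
        p = rng.uniform(size=8)
        fam = mst.holm_correct(p)
        order = np.argsort(p)
        mult = (len(p) - np.arange(len(p))) * p[order]
        hand = np.minimum(np.maximum.accumulate(mult), 1.0)
        np.testing.assert_allclose(fam.adjusted_p[order], hand, atol=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_dominates_bonferroni(self, seed):
        """Holm adjusted p <= Bonferroni adjusted p, so Holm rejects a
        superset at equal alpha."""
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=6)
        fam = mst.holm_correct(p)
        bonf = np.minimum(p * len(p), 1.0)
        assert (fam.adjusted_p <= bonf + 1e-12).all()
        assert (fam.adjusted_p >= p - 1e-12).all()
        bonf_rej = bonf < fam.alpha
        assert (~bonf_rej | fam.rejected).all()


class TestSpearman:
    def test_monotone_pairing(self):
        res = mst.spearman_severity([1, 2, 5, 9], [10, 20, 22, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_pairing(self):
        res = mst.spearman_severity([1, 2, 5, 9], [4, 3, 2, 1])
        assert res.statistic == pytest.approx(-1.0)

    def test_exact_p_matches_permutation_oracle(self):
        """Exact small-n p equals a full pairing permutation test."""
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 0.5, 3.0])
        res = mst.spearman_severity(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        null = []
        for perm in itertools.permutations(range(6)):
            null.append(abs(np.corrcoef(rx, ry[list(perm)])[0, 1]))
        p_oracle = np.mean(np.asarray(null) >= abs(res.statistic) - 1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert "exact" in res.test_chosen_by

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = mst.spearman_severity(x, y)
        ref = sps.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="constant"):
            mst.spearman_severity([1, 1, 1, 1], [1, 2, 3, 4])


class TestFisherOR:
    def test_sex_table(self):
        """[[7,6],[9,3]] -> conditional MLE OR = 0.40 (2 d.p.), p ~ 0.41."""
        res = mst.fisher_or([[7, 6], [9, 3]])
        assert res.statistic == pytest.approx(0.40, abs=5e-3)
        assert res.p == pytest.approx(0.41, abs=5e-3)

    def test_balanced_table_unit_or(self):
        assert mst.fisher_or([[5, 5], [5, 5]]).statistic == pytest.approx(1.0, abs=1e-8)

    def test_degenerate_diagonal_table(self):
        res = mst.fisher_or([[2, 0], [0, 2]])
        assert np.isinf(res.statistic) and "at_support_max" in res.flags

    def test_zero_margin_flagged(self):
        res = mst.fisher_or([[0, 0], [3, 4]])
        assert "zero_margin" in res.flags

    @pytest.mark.parametrize(
        "table",
        [[[7, 6], [9, 3]], [[12, 2], [5, 9]], [[3, 8], [7, 4]], [[10, 10], [1, 19]]],
    )
    def test_matches_conditional_mle_oracle(self, table):
        """Bisection CMLE agrees with the reference implementation."""
        ours = mst.fisher_or(table).statistic
        ref = scipy_odds_ratio(np.asarray(table), kind="conditional").statistic
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_estimate_tracks_sample_or_direction(self):
        for table in ([[2, 8], [9, 3]], [[9, 3], [2, 8]]):
            t = np.asarray(table)
            sample = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
            est = mst.fisher_or(table).statistic
            assert (est < 1) == (sample < 1)


class TestCrossModal:
    @staticmethod
    def _result(seed=0):
        rng = np.random.default_rng(seed)
        return subject_connectivity(
            RoiSeries(rng.normal(size=(6, 20)), np.arange(1, 7), "fpet", "s")
        )

    def test_self_association_is_identity_fit(self):
        res = self._result()
        r, slope, intercept = mst.cross_modal_association(res, res)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_transform_recovered(self):
        import copy

        res1 = self._result(1)
        res2 = copy.deepcopy(res1)
        res2.z = 2.0 * res1.z + 0.1
        r, slope, intercept = mst.cross_modal_association(res1, res2)
        assert (r, slope) == (pytest.approx(1.0), pytest.approx(2.0))
        assert intercept == pytest.approx(0.1)

    def test_r_matches_brute_force(self):
        res1, res2 = self._result(2), self._result(3)
        r, _, _ = mst.cross_modal_association(res1, res2)
        iu = np.triu_indices(6, 1)
        x, y = res1.z[iu], res2.z[iu]
        xm, ym = x - x.mean(), y - y.mean()
        brute = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert r == pytest.approx(brute, abs=1e-12)


class TestUnitDegreeComparison:
    def test_detects_planted_unit_difference(self):
        import pandas as pd

        from metaconn.connectome import DegreeTable

        units = ["frontal"] * 5 + ["parietal"] * 5
        table = pd.DataFrame(
            {"roi_id": np.arange(1, 11), "name": [f"r{k}" for k in range(10)],
             "unit": units}
        )
        cols = pd.Index(np.arange(1, 11), name="roi_id")
        a = DegreeTable(pd.DataFrame([[1, 2, 1, 2, 1, 0, 1, 0, 1, 0]], columns=cols), "group")
        b = DegreeTable(pd.DataFrame([[7, 8, 9, 8, 7, 1, 0, 1, 0, 1]], columns=cols), "group")
        out = mst.unit_degree_comparison(a, b, table)
        frontal = out.set_index("unit").loc["frontal"]
        assert frontal["p"] < 0.05 and frontal["rejected"]
        assert frontal["mean_PD"] > frontal["mean_HC"]
        assert not out.set_index("unit").loc["parietal", "rejected"]
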