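"""Permutation tests and the G-test against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, f_oneway

from decanal.errors import InputError
from decanal.variance_tests import (
    build_contingency,
    dispersion_test,
    g_test,
    pairwise_permanova,
    permanova,
)


def brute_force_permanova_f(points, labels):
    """Independent oracle: SS partition from the full distance matrix."""
    pts = np.atleast_2d(points)
    if pts.shape[0] == 1:
        pts = pts.T
    n = pts.shape[0]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    ss_tot = d2.sum() / (2 * n)
    ssw = 0.0
    for lab in set(labels):
        ix = [i for i, l in enumerate(labels) if l == lab]
        ssw += d2[np.ix_(ix, ix)].sum() / (2 * len(ix))
    g = len(set(labels))
    return ((ss_tot - ssw) / (g - 1)) / (ssw / (n - g))


class TestPermanova:
    def test_identical_clouds_no_separation(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((30, 2))
        x = np.vstack([cloud, cloud])
        groups = ["a"] * 30 + ["b"] * 30
        res = permanova(x, groups, B=199, seed=1)
        assert res.pseudo_f < 1e-20
        assert res.p_value > 0.9

    def test_eight_point_example_matches_enumeration(self):
        x = np.array([0, 0, 1, 1, 10, 10, 11, 11], dtype=float)[:, None]
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(x, groups, B=999, seed=0)
        f_oracle = brute_force_permanova_f(x, groups)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-12)
        # exact p from full enumeration of the C(8,4)=70 label assignments
        count = total = 0
        for c in itertools.combinations(range(8), 4):
            labels = ["b"] * 8
            for i in c:
                labels[i] = "a"
            total += 1
            if brute_force_permanova_f(x, labels) >= f_oracle - 1e-9:
                count += 1
        assert count / total == pytest.approx(2 / 70)
        # the sampled permutation p agrees with the enumeration p at B=999
        assert res.p_value == pytest.approx(2 / 70, abs=0.02)

    def test_one_dimensional_anova_identity(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(45) + np.repeat([0.0, 0.5, 1.0], 15)
        groups = np.repeat(["a", "b", "c"], 15)
        res = permanova(y[:, None], groups, B=9, seed=0)
        f_classic = f_oneway(y[:15], y[15:30], y[30:]).statistic
        assert res.pseudo_f == pytest.approx(f_classic, abs=1e-8)

    def test_distance_matrix_input_equivalent(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 3))
        groups = np.repeat(["a", "b", "c"], 10)
        r1 = permanova(x, groups, B=99, seed=5)
        r2 = permanova(squareform(pdist(x)), groups, B=99, seed=5)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)
        assert r1.p_value == r2.p_value

    def test_ss_partition_identity(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 4))
        groups = np.repeat(["a", "b"], 20)
        res = permanova(x, groups, B=9, seed=0)
        assert res.ss_between + res.ss_within == pytest.approx(res.ss_total, rel=1e-8)

    def test_matches_skbio(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(7)
        x = rng.standard_normal((40, 3))
        x[:15] += 0.8
        groups = ["a"] * 15 + ["b"] * 25
        res = permanova(x, groups, B=999, seed=1)
        sk = sk_permanova(DistanceMatrix(squareform(pdist(x))), grouping=groups,
                          permutations=999)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)
        assert res.p_value == pytest.approx(sk["p-value"], abs=0.03)

    def test_p_never_zero(self):
        x = np.array([0, 0, 1, 1, 100, 100, 101, 101], dtype=float)[:, None]
        groups = ["a"] * 4 + ["b"] * 4
        res = permanova(x, groups, B=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_singleton_group_rejected(self):
        with pytest.raises(InputError, match="singleton"):
            permanova(np.zeros((5, 2)), ["a", "a", "a", "a", "b"], B=9)

    def test_invalid_b_rejected(self):
        with pytest.raises(InputError):
            permanova(np.zeros((4, 2)), ["a", "a", "b", "b"], B=0)


class TestPairwise:
    def test_identical_groups_all_null(self):
        rng = np.random.default_rng(4)
        cloud = rng.standard_normal((20, 2))
        x = np.vstack([cloud] * 3)
        groups = np.repeat(["a", "b", "c"], 20)
        out = pairwise_permanova(x, groups, B=99, seed=2)
        assert (out["p_bonferroni"] > 0.9).all()

    def test_displaced_group_detected(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((60, 2))
        x[40:] += 6.0
        groups = np.repeat(["a", "b", "c"], 20)
        out = pairwise_permanova(x, groups, B=199, seed=3).set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "p_bonferroni"] < 0.05
        assert out.loc[("b", "c"), "p_bonferroni"] < 0.05
        assert out.loc[("a", "b"), "p_bonferroni"] > 0.1

    def test_bonferroni_definition(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 2))
        groups = np.repeat(["a", "b", "c"], 10)
        out = pairwise_permanova(x, groups, B=99, seed=4)
        np.testing.assert_allclose(out["p_bonferroni"],
                                   np.minimum(1.0, 3 * out["p_value"]))


class TestDispersion:
    def test_translated_clouds_equal_spread(self):
        rng = np.random.default_rng(7)
        cloud = rng.standard_normal((200, 2))
        x = np.vstack([cloud, cloud + 10.0])
        groups = np.repeat(["a", "b"], 200)
        res = dispersion_test(x, groups, B=199, seed=5)
        assert res.p_value > 0.2

    def test_unequal_spread_detected(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.standard_normal((200, 2)),
                       3.0 * rng.standard_normal((200, 2))])
        groups = np.repeat(["a", "b"], 200)
        res = dispersion_test(x, groups, B=199, seed=6)
        assert res.p_value < 0.01
        assert res.group_mean_distance["b"] > res.group_mean_distance["a"]

    def test_minimal_groups_no_crash(self):
        x = np.array([[0.0, 0], [1, 0], [5, 1], [6, 1]])
        groups = ["a", "a", "b", "b"]
        res = dispersion_test(x, groups, B=19, seed=0)
        assert not np.isnan(res.f_stat)
        assert 0 < res.p_value <= 1


class TestGTest:
    def test_exact_independence(self):
        res = g_test([[10, 10], [10, 10]])
        assert res.g == 0.0
        assert res.p_value == 1.0

    def test_known_2x2_value(self):
        res = g_test([[20, 10], [10, 20]])
        assert res.g == pytest.approx(6.796, abs=1e-3)
        assert res.df == 1

    def test_matches_scipy_log_likelihood(self):
        obs = np.array([[30, 12, 8], [14, 25, 11], [9, 10, 31]])
        res = g_test(obs)
        sp = chi2_contingency(obs, correction=False, lambda_="log-likelihood")
        assert res.g == pytest.approx(sp.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-10)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    @settings(deadline=None, max_examples=50)
    def test_doubling_doubles_g(self, a, b, c, d):
        g1 = g_test([[a, b], [c, d]]).g
        g2 = g_test([[2 * a, 2 * b], [2 * c, 2 * d]]).g
        assert g2 == pytest.approx(2 * g1, rel=1e-9, abs=1e-9)

    def test_contributions_sum_to_g(self):
        res = g_test([[25, 5, 10], [8, 22, 12]])
        assert res.contributions.to_numpy().sum() == pytest.approx(res.g, abs=1e-10)
        # contribution signs track observed-minus-expected
        sign_oe = np.sign(res.observed.to_numpy() - res.expected.to_numpy())
        nonzero = res.contributions.to_numpy() != 0
        assert (np.sign(res.contributions.to_numpy())[nonzero]
                == sign_oe[nonzero]).all()

    def test_margins_preserved(self):
        obs = np.array([[25, 5, 10], [8, 22, 12]])
        res = g_test(obs)
        np.testing.assert_allclose(res.expected.sum(axis=1), obs.sum(axis=1))
        np.testing.assert_allclose(res.expected.sum(axis=0), obs.sum(axis=0))

    def test_chi2_equivalence_large_counts(self):
        rng = np.random.default_rng(9)
        obs = rng.integers(40, 120, size=(4, 3))
        res = g_test(obs)
        x2 = chi2_contingency(obs, correction=False).statistic
        assert res.expected.to_numpy().min() >= 20
        assert abs(res.g - x2) / x2 < 0.05

    def test_zero_cell_contributes_zero(self):
        res = g_test([[0, 10], [10, 10]])
        assert res.contributions.iloc[0, 0] == 0.0

    @pytest.mark.parametrize("bad", [[[5, 0], [7, 0]], [[1]], [[-1, 2], [3, 4]]])
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(InputError):
            g_test(bad)


class TestContingency:
    def test_counts_recovered_exactly(self):
        df = pd.DataFrame({
            "income_category": ["A", "A", "B", "B", "B", "A"],
            "edu_interviewee": [3, 3, 2, 2, 1, 3],
            "residual_category": ["Normal", "Extreme", "Normal", "Normal",
                                  "Outlier", "Normal"],
        })
        ct = build_contingency(df)
        assert ct.loc["A-3", "Normal"] == 2
        assert ct.loc["A-3", "Extreme"] == 1
        assert ct.loc["B-2", "Normal"] == 2
        assert ct.to_numpy().sum() == len(df)

    def test_full_grid_gives_df_22(self, decanalized_survey):
        """4 income x 3 education rows and 3 residual columns -> df = 22
        when every combination is populated."""
        from decanal.survey_io import build_derived_table

        table, _ = decanalized_survey
        ct = build_contingency(build_derived_table(table).table)
        res = g_test(ct)
        expected_df = (ct.shape[0] - 1) * (ct.shape[1] - 1)
        assert res.df == expected_df
        if ct.shape[0] == 12:
            assert res.df == 22

    def test_too_sparse_rejected(self):
        df = pd.DataFrame({
            "income_category": ["A"] * 4,
            "edu_interviewee": [3] * 4,
            "residual_category": ["Normal", "Normal", "Outlier", "Outlier"],
        })
        with pytest.raises(InputError):
            build_contingency(df)
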