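import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from astroquant import expression as ex
from astroquant.expression import CtTable, ExpressionMatrix


def brute_force_score(e: pd.DataFrame):
    """Independent two-loop reimplementation of the gene set score."""
    ng, ns = e.shape
    centered = np.zeros((ng, ns))
    for i in range(ng):
        row_mean = sum(e.iloc[i, j] for j in range(ns)) / ns
        for j in range(ns):
            centered[i, j] = e.iloc[i, j] - row_mean
    scores = [sum(centered[i, j] for i in range(ng)) / ng for j in range(ns)]
    return np.array(scores), centered


class TestGeneSetScore:
    def test_identical_samples_score_zero(self):
        e = pd.DataFrame(np.tile([[3.0], [5.0]], (1, 4)))
        res = ex.gene_set_score(e)
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_single_gene_two_samples_hand_arithmetic(self):
        e = pd.DataFrame([[2.0, 4.0]], index=["g"], columns=["a", "b"])
        res = ex.gene_set_score(e)
        assert list(res.scores) == [-1.0, 1.0]

    def test_matches_bruteforce_oracle_on_random_matrix(self, rng):
        e = pd.DataFrame(rng.normal(10, 3, size=(20, 8)))
        res = ex.gene_set_score(e)
        oracle_scores, oracle_centered = brute_force_score(e)
        np.testing.assert_allclose(res.scores, oracle_scores, atol=1e-12)
        np.testing.assert_allclose(res.centered, oracle_centered, atol=1e-12)

    def test_scores_sum_to_zero(self, rng):
        e = pd.DataFrame(rng.normal(0, 100, size=(13, 9)))
        res = ex.gene_set_score(e)
        assert abs(res.scores.sum()) < 1e-9 * max(1.0, np.abs(e.values).sum())

    def test_invariant_to_per_gene_constant(self, rng):
        e = pd.DataFrame(rng.normal(5, 2, size=(6, 5)))
        shifted = e.add(pd.Series(rng.normal(0, 50, 6), index=e.index), axis=0)
        np.testing.assert_allclose(
            ex.gene_set_score(e).scores, ex.gene_set_score(shifted).scores,
            atol=1e-9,
        )

    def test_equivariant_under_sample_relabeling(self, rng):
        e = pd.DataFrame(
            rng.normal(0, 1, size=(4, 6)), columns=[f"s{i}" for i in range(6)]
        )
        perm = ["s3", "s0", "s5", "s1", "s4", "s2"]
        s1 = ex.gene_set_score(e).scores
        s2 = ex.gene_set_score(e[perm]).scores
        np.testing.assert_allclose(s1[perm], s2)

    def test_missing_values_rejected_with_location(self):
        e = pd.DataFrame([[1.0, np.nan]], index=["g1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="g1"):
            ex.gene_set_score(e)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            np.float64,
            (5, 7),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_zero_sum_property(self, values):
        res = ex.gene_set_score(pd.DataFrame(values))
        assert abs(res.scores.sum()) <= 1e-9 * max(1.0, np.abs(values).sum())


class TestDdct:
    @staticmethod
    def make_table(rng, ns=6):
        samples = [f"s{i}" for i in range(ns)]
        ct = pd.DataFrame(
            {
                s: {
                    "GAPDH": rng.uniform(18, 20),
                    "CDKN1A": rng.uniform(24, 30),
                }
                for s in samples
            }
        )
        groups = pd.Series(
            ["CTRL"] * (ns // 2) + ["AD"] * (ns - ns // 2), index=samples
        )
        return CtTable(ct=ct, housekeeping="GAPDH", groups=groups)

    def test_reference_group_geometric_mean_one(self, rng):
        table = self.make_table(rng)
        fold = ex.ddct_fold(table, "CDKN1A", "CTRL")
        ref = fold[[s for s in fold.index if table.groups[s] == "CTRL"]]
        assert np.exp(np.log(ref).mean()) == pytest.approx(1.0)

    def test_unit_negative_ddct_doubles(self):
        samples = ["r1", "r2", "t1"]
        ct = pd.DataFrame(
            {"r1": [18.0, 25.0], "r2": [18.0, 25.0], "t1": [18.0, 24.0]},
            index=["GAPDH", "TG"],
        )
        groups = pd.Series(["ref", "ref", "case"], index=samples)
        fold = ex.ddct_fold(
            CtTable(ct=ct, housekeeping="GAPDH", groups=groups), "TG", "ref"
        )
        assert fold["t1"] == pytest.approx(2.0)  # ddCt = -1

    def test_matches_spreadsheet_oracle(self, rng):
        table = self.make_table(rng)
        fold = ex.ddct_fold(table, "CDKN1A", "CTRL")
        # hand computation, one sample at a time
        dct = {
            s: table.ct.loc["CDKN1A", s] - table.ct.loc["GAPDH", s]
            for s in table.ct.columns
        }
        ref_mean = np.mean(
            [dct[s] for s in table.ct.columns if table.groups[s] == "CTRL"]
        )
        for s in table.ct.columns:
            assert fold[s] == pytest.approx(2.0 ** (-(dct[s] - ref_mean)))

    def test_empty_reference_group_rejected(self, rng):
        table = self.make_table(rng)
        with pytest.raises(ValueError, match="reference group"):
            ex.ddct_fold(table, "CDKN1A", "nonexistent")

    def test_housekeeping_must_be_present(self):
        ct = pd.DataFrame({"s1": [20.0]}, index=["TG"])
        with pytest.raises(ValueError, match="housekeeping"):
            CtTable(ct=ct, housekeeping="GAPDH",
                    groups=pd.Series(["g"], index=["s1"]))


class TestFoldUtilities:
    @pytest.mark.parametrize(
        "a,b,decimals,expected",
        [
            (1757.0, 199.2, 1, 8.8),
            (65.5, 20.7, 1, 3.2),
            (3415.0, 713.8, 1, 4.8),
            (78.77, 29.28, 2, 2.69),
        ],
    )
    def test_group_mean_ratios(self, a, b, decimals, expected):
        assert ex.fold_change(a, b, decimals) == expected

    def test_identity_fold(self, rng):
        x = rng.uniform(1, 100)
        assert ex.fold_change(x, x, 1) == 1.0

    def test_rounding_is_half_up(self):
        assert ex.fold_change(25.0, 10.0, 0) == 3.0  # 2.5 rounds up
        assert ex.fold_change(35.0, 10.0, 0) == 4.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            ex.fold_change(1.0, 0.0)

    def test_percent_change_examples(self):
        assert ex.percent_change(3415.0, 3765.0, 0) == 10.0
        assert ex.percent_change(100.0, 250.0) == 150.0
        assert ex.percent_change(7.0, 7.0) == 0.0

    def test_percent_change_requires_positive_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            ex.percent_change(0.0, 5.0)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.2, "ns"), (0.049, "*"), (0.009, "**"),
            (0.0009, "***"), (0.00009, "****"),
        ],
    )
    def test_mapping(self, p, expected):
        assert ex.p_to_stars(p) == expected


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = ex.compare_groups([g, list(g)])
        assert res.p_value > 0.9 and res.stars == "ns"

    def test_parametric_branch_for_separated_normals(self, rng):
        chosen_parametric = 0
        significant = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0, 1, 20)
            b = rng.normal(2, 1, 20)
            res = ex.compare_groups([a, b])
            chosen_parametric += res.branch == "parametric"
            significant += res.p_value < 0.05
        # both groups must pass Shapiro at alpha=0.05, so the expected
        # parametric fraction is ~0.95^2 = 0.9025; allow binomial slack
        assert chosen_parametric / n_rep == pytest.approx(0.9025, abs=0.06)
        assert significant / n_rep > 0.99

    def test_nonparametric_branch_for_skewed_data(self, rng):
        a = rng.lognormal(0, 2, 25)
        b = rng.lognormal(0, 2, 25)
        res = ex.compare_groups([a, b])
        assert res.branch == "nonparametric"
        assert res.test_name == "Mann-Whitney U"

    def test_three_normal_groups_use_anova_tukey(self, rng):
        groups = {k: rng.normal(m, 1, 15) for k, m in
                  [("a", 0.0), ("b", 0.5), ("c", 3.0)]}
        res = ex.compare_groups(groups)
        assert res.test_name == "one-way ANOVA + Tukey"
        assert res.posthoc is not None and len(res.posthoc) == 3
        row = res.posthoc.set_index(["group_a", "group_b"]).loc[("a", "c")]
        assert row.p_adj < 0.01

    def test_three_skewed_groups_use_kruskal_dunn(self, rng):
        groups = [rng.lognormal(m, 2, 20) for m in (0.0, 0.0, 3.0)]
        res = ex.compare_groups(groups)
        assert res.test_name == "Kruskal-Wallis + Dunn"
        assert len(res.posthoc) == 3
        assert ((res.posthoc.p_adj >= 0) & (res.posthoc.p_adj <= 1)).all()

    def test_paired_nonnormal_uses_wilcoxon(self, rng):
        a = rng.lognormal(0, 1.5, 15)
        b = a * rng.lognormal(0.5, 1.5, 15)
        res = ex.compare_groups([a, b], paired=True)
        assert res.branch == "paired"
        assert res.test_name == "Wilcoxon signed-rank"

    def test_paired_normal_uses_paired_t(self, rng):
        a = rng.normal(0, 1, 15)
        b = a + rng.normal(1, 0.5, 15)
        res = ex.compare_groups([a, b], paired=True)
        assert res.test_name == "paired t-test"

    def test_tiny_groups_force_nonparametric_with_warning(self):
        with pytest.warns(RuntimeWarning, match="below n=3"):
            res = ex.compare_groups([[1.0, 2.0], [3.0, 4.0]])
        assert res.branch == "nonparametric"

    def test_branch_decision_deterministic(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        r1 = ex.compare_groups([a, b])
        r2 = ex.compare_groups([a, b])
        assert (r1.branch, r1.test_name, r1.p_value) == (
            r2.branch, r2.test_name, r2.p_value
        )


class TestRankList:
    def test_sorted_descending(self, rng):
        s = pd.Series(rng.normal(0, 1, 10), index=[f"g{i}" for i in range(10)])
        df = ex.rank_list(s)
        assert list(df.columns) == ["gene", "statistic"]
        assert (df.statistic.diff().dropna() <= 0).all()
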