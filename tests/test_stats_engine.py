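import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from sipflow.stats_engine import (
    DegenerateTableError,
    bh_adjust,
    chi_square_test,
    mixed_rm_anova,
    oneway_anova,
    posthoc_bonferroni,
    t_test,
)


def mixed_long(rng, n_per_group, a, group_names=("g1", "g2"), effect=0.0):
    rows = []
    s = 0
    for gi, g in enumerate(group_names):
        for _ in range(n_per_group[gi]):
            subj_fx = rng.normal()
            for w in range(a):
                val = rng.normal() + subj_fx + effect * gi * w
                rows.append((f"s{s}", g, f"w{w}", val))
            s += 1
    return pd.DataFrame(rows, columns=["subject", "group", "within", "value"])


class TestTTest:
    def test_identical_groups(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        a, b = t_test(x, y), t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


class TestOnewayAnova:
    def test_df_for_cluster_sizes(self, rng):
        groups = [rng.normal(size=n) for n in (11, 6, 39)]
        assert oneway_anova(groups).df == (2, 53)

    def test_equal_group_means_give_zero_f(self):
        res = oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.statistic == pytest.approx(0.0)

    def test_constant_data_f_zero(self):
        assert oneway_anova([[2.0, 2.0], [2.0, 2.0]]).statistic == 0.0

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=11)
        f = oneway_anova([x, y]).statistic
        t = t_test(x, y).statistic
        assert f == pytest.approx(t**2, abs=1e-9)


class TestMixedAnova:
    @pytest.mark.parametrize(
        "a,sizes,expected_inter,expected_group",
        [
            (5, (32, 24), (4, 216), (1, 54)),      # substance x sex
            (7, (32, 24), (6, 324), (1, 54)),      # day x sex
            (5, (11, 6, 39), (8, 212), (2, 53)),   # substance x cluster
            (7, (11, 6, 39), (12, 318), (2, 53)),  # day x cluster
        ],
    )
    def test_design_df_identities(self, rng, a, sizes, expected_inter, expected_group):
        names = [f"g{i}" for i in range(len(sizes))]
        fit = mixed_rm_anova(mixed_long(rng, sizes, a, names))
        assert fit.effects["interaction"].df == expected_inter
        assert fit.effects["group"].df == expected_group
        assert fit.effects["within"].df == (a - 1, expected_inter[1])

    def test_ss_partition_additive(self, rng):
        fit = mixed_rm_anova(mixed_long(rng, (6, 9), 4, effect=0.3))
        parts = (
            fit.ss["group"] + fit.ss["subjects_within_groups"]
            + fit.ss["within"] + fit.ss["interaction"] + fit.ss["residual"]
        )
        assert parts == pytest.approx(fit.ss["total"], rel=1e-6)

    def test_constant_data_all_f_zero(self):
        df = mixed_long(np.random.default_rng(0), (3, 3), 3)
        df["value"] = 5.0
        fit = mixed_rm_anova(df)
        assert all(r.statistic == 0.0 for r in fit.effects.values())

    def test_hand_computed_two_by_two(self):
        """2 groups x 2 levels, 4 subjects each, integer cell-means decomposition."""
        rows = []
        vals = {
            ("g1", "w0"): [1, 2, 3, 4], ("g1", "w1"): [3, 4, 5, 6],
            ("g2", "w0"): [2, 3, 4, 5], ("g2", "w1"): [8, 9, 10, 11],
        }
        for (g, w), xs in vals.items():
            for i, v in enumerate(xs):
                rows.append((f"{g}s{i}", g, w, float(v)))
        df = pd.DataFrame(rows, columns=["subject", "group", "within", "value"])
        fit = mixed_rm_anova(df)
        # brute-force decomposition from cell means
        y = df["value"].to_numpy()
        grand = y.mean()  # 5.0
        # group means: g1 = 3.5, g2 = 6.5 -> SS_group = 2*4*(1.5^2)*... (a=2)
        assert fit.ss["group"] == pytest.approx(2 * 4 * ((3.5 - 5) ** 2 + (6.5 - 5) ** 2))
        # level means: w0 = 3.0, w1 = 7.0
        assert fit.ss["within"] == pytest.approx(8 * ((3.0 - 5) ** 2 + (7.0 - 5) ** 2))
        # cells: 2.5, 4.5, 3.5, 9.5
        ss_cells = 4 * sum(
            (np.mean(v) - grand) ** 2 for v in vals.values()
        )
        assert fit.ss["interaction"] == pytest.approx(
            ss_cells - fit.ss["group"] - fit.ss["within"]
        )
        # perfectly subject-additive data -> zero residual
        assert fit.ss["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_pingouin_on_balanced_design(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = mixed_long(rng, (8, 8), 5, effect=0.4)
        fit = mixed_rm_anova(df)
        pg = pingouin.mixed_anova(
            df, dv="value", within="within", between="group", subject="subject"
        ).set_index("Source")
        assert fit.effects["group"].statistic == pytest.approx(pg.loc["group", "F"])
        assert fit.effects["within"].statistic == pytest.approx(pg.loc["within", "F"])
        assert fit.effects["interaction"].statistic == pytest.approx(
            pg.loc["Interaction", "F"]
        )
        assert fit.effects["interaction"].p == pytest.approx(
            pg.loc["Interaction", "p_unc"]
        )

    def test_unbalanced_subject_rejected(self, rng):
        df = mixed_long(rng, (3, 3), 3)
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="s0"):
            mixed_rm_anova(df)


class TestPosthoc:
    def test_family_of_one_unadjusted(self, rng):
        df = mixed_long(rng, (5, 5), 3)
        fit = mixed_rm_anova(df)
        res = posthoc_bonferroni(df, fit, [("group", "g1", "g2")])
        assert res[0]["p_adj"] == pytest.approx(res[0]["p"])

    def test_bonferroni_scaling_and_cap(self, rng):
        df = mixed_long(rng, (6, 6), 4, effect=0.5)
        fit = mixed_rm_anova(df)
        contrasts = [("within", f"w{i}", f"w{j}") for i in range(4) for j in range(i + 1, 4)]
        res = posthoc_bonferroni(df, fit, contrasts)
        for r in res:
            assert r["p_adj"] == pytest.approx(min(1.0, len(contrasts) * r["p"]))

    def test_empty_family_rejected(self, rng):
        df = mixed_long(rng, (3, 3), 3)
        fit = mixed_rm_anova(df)
        with pytest.raises(ValueError):
            posthoc_bonferroni(df, fit, [])


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        # ranked: 0.01*3/1=0.03, 0.03*3/2=0.045, 0.04*3/3=0.04; monotone -> 0.04
        assert np.allclose(bh_adjust([0.01, 0.03, 0.04]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.05] * 5), 0.05)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=40)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_monotone_and_not_below_input(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestChiSquare:
    def test_reported_cluster_sex_table(self):
        res = chi_square_test([[7, 4], [1, 5], [24, 15]])
        assert round(res.statistic, 1) == 4.5
        assert res.df == 2
        assert round(res.p, 1) == 0.1

    def test_proportional_rows(self):
        res = chi_square_test([[10, 20], [1, 2]])
        assert res.statistic == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_diagonal_closed_form(self):
        res = chi_square_test([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0) and res.df == 1

    def test_matches_scipy_without_correction(self, rng):
        from scipy.stats import chi2_contingency

        t = rng.integers(1, 30, size=(3, 4))
        res = chi_square_test(t)
        chi2, p, df, _ = chi2_contingency(t, correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p == pytest.approx(p) and res.df == df

    def test_invariant_to_permutation_and_scaling(self, rng):
        t = rng.integers(0, 20, size=(3, 3)) + 1
        base = chi_square_test(t).statistic
        perm = chi_square_test(t[[2, 0, 1]][:, [1, 2, 0]]).statistic
        assert perm == pytest.approx(base)
        assert chi_square_test(3 * t).statistic == pytest.approx(3 * base)

    def test_degenerate_after_dropping_empties(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test([[5, 0], [3, 0]])
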