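import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafrefix.stats_pipeline import (
    compact_letter_display,
    compute_lma,
    compute_water_content,
    group_summary,
    nested_ols,
    simple_regressions,
    tukey_hsd,
    two_way_anova,
)


class TestTraitArithmetic:
    def test_lma_leaf_disc(self):
        # 0.02 g on the 2.27 cm2 punch disc
        assert compute_lma(0.02, 2.27) == pytest.approx(0.02 / 2.27e-4)

    def test_lma_zero_mass(self):
        assert compute_lma(0.0, 2.27) == 0.0

    def test_lma_homogeneity(self):
        assert compute_lma(0.04, 4.54) == pytest.approx(compute_lma(0.02, 2.27))

    def test_lma_bad_area(self):
        with pytest.raises(ValueError):
            compute_lma(0.02, 0.0)

    @pytest.mark.parametrize(
        "fresh,dry,expected",
        [(0.5, 0.5, 0.0), (0.5, 0.0, 100.0), (0.5, 0.2, 60.0)],
    )
    def test_water_content(self, fresh, dry, expected):
        assert compute_water_content(fresh, dry) == pytest.approx(expected)

    def test_water_content_dry_exceeds_fresh(self):
        with pytest.raises(ValueError):
            compute_water_content(0.2, 0.5)


def balanced_toy(means, n_per_cell, sd, seed=0):
    """Balanced two-factor layout from a dict {(a, b): mean}."""
    rng = np.random.default_rng(seed)
    rows = []
    for (a, b), mu in means.items():
        for _ in range(n_per_cell):
            rows.append(dict(species=a, season=b, y=mu + sd * rng.standard_normal()))
    return pd.DataFrame(rows)


def anova_main_effects_oracle(df):
    """Hand-worked sequential decomposition for a balanced two-factor design."""
    y = df["y"].to_numpy()
    grand = y.mean()
    n = len(df)
    ss_a = sum(
        len(d) * (d["y"].mean() - grand) ** 2 for _, d in df.groupby("species")
    )
    ss_b = sum(
        len(d) * (d["y"].mean() - grand) ** 2 for _, d in df.groupby("season")
    )
    a_eff = df.groupby("species")["y"].mean() - grand
    b_eff = df.groupby("season")["y"].mean() - grand
    fitted = grand + df["species"].map(a_eff).to_numpy() + df["season"].map(b_eff).to_numpy()
    ss_res = ((y - fitted) ** 2).sum()
    df_a = df["species"].nunique() - 1
    df_b = df["season"].nunique() - 1
    df_res = n - 1 - df_a - df_b
    ms_res = ss_res / df_res
    return ss_a / df_a / ms_res, ss_b / df_b / ms_res


class TestTwoWayAnova:
    def test_matches_hand_decomposition_balanced_3x2(self):
        means = {
            ("a", "x"): 1.0, ("a", "y"): 2.0,
            ("b", "x"): 3.0, ("b", "y"): 4.0,
            ("c", "x"): 0.5, ("c", "y"): 1.5,
        }
        df = balanced_toy(means, n_per_cell=6, sd=1.0, seed=3)
        res = two_way_anova(df, "y", ("species", "season"), transform="none")
        f_a, f_b = anova_main_effects_oracle(df)
        assert res.F["species"] == pytest.approx(f_a, rel=1e-10)
        assert res.F["season"] == pytest.approx(f_b, rel=1e-10)

    def test_type2_equals_sequential_when_balanced(self):
        df = balanced_toy(
            {("a", "x"): 1, ("a", "y"): 3, ("b", "x"): 2, ("b", "y"): 5},
            n_per_cell=5, sd=0.7, seed=9,
        )
        r2 = two_way_anova(df, "y", ("species", "season"), typ=2, transform="none")
        r1 = two_way_anova(df, "y", ("species", "season"), typ=1, transform="none")
        for f in ("species", "season"):
            assert r2.F[f] == pytest.approx(r1.F[f], rel=1e-10)

    def test_constant_response(self):
        df = balanced_toy({("a", "x"): 2, ("a", "y"): 2, ("b", "x"): 2, ("b", "y"): 2},
                          n_per_cell=4, sd=0.0)
        res = two_way_anova(df, "y", ("species", "season"), transform="none")
        assert res.F["species"] == 0.0 and res.p["species"] == 1.0
        assert res.F["season"] == 0.0 and res.p["season"] == 1.0

    def test_noise_free_effects_detected(self):
        df = balanced_toy({("a", "x"): 0, ("a", "y"): 1, ("b", "x"): 5, ("b", "y"): 6},
                          n_per_cell=4, sd=0.0)
        res = two_way_anova(df, "y", ("species", "season"), transform="none")
        assert res.F["species"] > 1e10 or res.F["species"] == float("inf")
        assert res.p["species"] < 1e-10

    def test_log_transform_applied_on_nonnormal_positive(self):
        rng = np.random.default_rng(4)
        rows = []
        for sp in ("a", "b"):
            for se in ("x", "y"):
                mu = {"a": 1.0, "b": 2.0}[sp]
                rows += [
                    dict(species=sp, season=se, y=float(np.exp(rng.normal(mu, 1.5))))
                    for _ in range(20)
                ]
        df = pd.DataFrame(rows)
        res = two_way_anova(df, "y", ("species", "season"))
        assert res.transformation == "log"
        assert res.shapiro_p < 0.05

    def test_single_level_factor_rejected(self):
        df = balanced_toy({("a", "x"): 1, ("a", "y"): 2}, n_per_cell=3, sd=0.1)
        with pytest.raises(ValueError):
            two_way_anova(df, "y", ("species", "season"))


def toy_groups(means, sds, n, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, (mu, sd) in enumerate(zip(means, sds)):
        name = chr(ord("A") + g)
        rows += [dict(group=name, y=mu + sd * rng.standard_normal()) for _ in range(n)]
    return pd.DataFrame(rows)


class TestTukeyHsd:
    def test_identical_groups_share_a_letter(self):
        df = toy_groups([1.0, 1.0, 1.0], [1, 1, 1], 12, seed=5)
        res = tukey_hsd(df, "y", "group")
        assert set(res.letters.values()) == {"a"}

    def test_two_distant_groups(self):
        df = toy_groups([0.0, 100.0], [1, 1], 10, seed=2)
        res = tukey_hsd(df, "y", "group")
        assert sorted(res.letters.values()) == ["a", "b"]

    def test_three_group_toy(self):
        df = toy_groups([0.0, 0.0, 5.0], [1, 1, 1], 10, seed=7)
        res = tukey_hsd(df, "y", "group")
        # highest-mean group gets "a"; the two null groups share the other letter
        assert res.letters["C"] == "a"
        assert res.letters["A"] == res.letters["B"] == "b"
        assert res.pvalues[("A", "B")] >= 0.05
        assert res.pvalues[("A", "C")] < 0.05

    def test_letters_form_valid_clique_cover(self):
        for seed in range(6):
            df = toy_groups([0, 0.5, 1.2, 3.0, 3.1], [1] * 5, 8, seed=seed)
            res = tukey_hsd(df, "y", "group")
            for i, gi in enumerate(res.groups):
                for gj in res.groups[i + 1:]:
                    shared = set(res.letters[gi]) & set(res.letters[gj])
                    if res.pvalues[(gi, gj)] < res.alpha:
                        assert not shared, (gi, gj)
                    else:
                        assert shared, (gi, gj)

    def test_singleton_group_rejected(self):
        df = pd.DataFrame(dict(group=["A", "A", "B"], y=[1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            tukey_hsd(df, "y", "group")

    def test_insertion_order_independence(self):
        df = toy_groups([0.0, 2.0, 4.0], [1, 1, 1], 10, seed=1)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert tukey_hsd(df, "y", "group").letters == tukey_hsd(shuffled, "y", "group").letters


class TestCompactLetterDisplay:
    def test_chain_structure(self):
        # A~B ns, B~C ns, A~C significant -> A:a, B:ab, C:b
        groups = ["A", "B", "C"]
        p = {
            ("A", "B"): 0.2, ("B", "A"): 0.2,
            ("B", "C"): 0.3, ("C", "B"): 0.3,
            ("A", "C"): 0.01, ("C", "A"): 0.01,
        }
        letters = compact_letter_display(groups, p)
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    @given(st.integers(0, 2 ** 15 - 1))
    @settings(max_examples=60, deadline=None)
    def test_random_pvalue_matrices_give_valid_covers(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        groups = [chr(ord("A") + i) for i in range(k)]
        p = {}
        for i in range(k):
            for j in range(i + 1, k):
                v = float(rng.uniform(0, 0.12))
                p[(groups[i], groups[j])] = p[(groups[j], groups[i])] = v
        letters = compact_letter_display(groups, p)
        for i in range(k):
            for j in range(i + 1, k):
                shared = set(letters[groups[i]]) & set(letters[groups[j]])
                if p[(groups[i], groups[j])] < 0.05:
                    assert not shared
                else:
                    assert shared


def normal_equations(X, y):
    Xc = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(Xc.T @ Xc, Xc.T @ y)


class TestNestedOls:
    def test_exact_linear_fit(self):
        x = np.linspace(0, 10, 20)
        df = pd.DataFrame(dict(Pr=2 + 3 * x, rm=x))
        res = nested_ols(df, model_terms=(("rm",),))[0]
        assert res.terms["rm"][0] == pytest.approx(3.0, abs=1e-10)
        assert res.intercept[0] == pytest.approx(2.0, abs=1e-10)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictor(self):
        df = pd.DataFrame(dict(Pr=[1.0, -2.0, 1.0, -2.0, 1.0, 1.0], rm=[0.0] * 3 + [1.0] * 3))
        df["Pr"] = df["Pr"] - df.groupby("rm")["Pr"].transform("mean")  # zero covariance
        res = nested_ols(df, model_terms=(("rm",),))[0]
        assert res.terms["rm"][0] == pytest.approx(0.0, abs=1e-12)
        assert res.adj_r2 <= 0.0

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(12)
        n = 20
        rm = rng.uniform(0.2, 2.0, n)
        rs = rng.uniform(0.1, 3.0, n)
        lma = rng.uniform(40, 200, n)
        pr = 30 + 5 * rm + 0.6 * rs + 0.05 * lma + rng.normal(0, 1.0, n)
        df = pd.DataFrame(dict(Pr=pr, rm=rm, rs=rs, LMA=lma))
        models = nested_ols(df)
        for res, terms in zip(models, (("rm",), ("rm", "rs"), ("rm", "rs", "LMA"))):
            beta = normal_equations(df[list(terms)].to_numpy(), pr)
            assert res.intercept[0] == pytest.approx(beta[0], rel=1e-10)
            for i, t in enumerate(terms):
                assert res.terms[t][0] == pytest.approx(beta[i + 1], rel=1e-10)
            assert res.df_resid == n - len(terms) - 1

    def test_adj_r2_nondecreasing_on_full_model_data(self):
        rng = np.random.default_rng(3)
        n = 120
        rm = rng.uniform(0.2, 2.0, n)
        rs = rng.uniform(0.1, 3.0, n)
        lma = rng.uniform(40, 200, n)
        pr = 25 + 6 * rm + 1.2 * rs + 0.08 * lma + rng.normal(0, 1.5, n)
        df = pd.DataFrame(dict(Pr=pr, rm=rm, rs=rs, LMA=lma))
        r = [m.adj_r2 for m in nested_ols(df)]
        assert r[0] <= r[1] <= r[2]

    def test_rank_deficient_term_dropped(self):
        rng = np.random.default_rng(5)
        rm = rng.uniform(0.2, 2.0, 30)
        df = pd.DataFrame(dict(Pr=1 + rm, rm=rm, rs=2 * rm))  # rs collinear
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            res = nested_ols(df, model_terms=(("rm", "rs"),))[0]
        assert res.dropped == ("rs",)
        assert "rs" not in res.terms


class TestSimpleRegressions:
    def test_pooled_and_per_species_rows(self):
        rng = np.random.default_rng(8)
        rows = []
        for sp, base in (("s1", 30.0), ("s2", 45.0)):
            rm = rng.uniform(0.3, 2.0, 15)
            rows += [
                dict(species=sp, Pr=base + 5 * v + rng.normal(0, 0.5), rm=v,
                     rs=v * 2, LMA=100 * v)
                for v in rm
            ]
        df = pd.DataFrame(rows)
        reg = simple_regressions(df)
        assert set(reg["predictor"]) == {"rm", "rs", "LMA"}
        assert set(reg["species"]) == {"all", "s1", "s2"}
        pooled_rm = reg[(reg.predictor == "rm") & (reg.species == "all")].iloc[0]
        assert pooled_rm["slope"] > 0


class TestGroupSummary:
    def test_basic(self):
        df = pd.DataFrame(dict(g=["a"] * 3, y=[1.0, 2.0, 3.0]))
        out = group_summary(df, "y", "g")
        assert out.loc[0, "mean"] == pytest.approx(2.0)
        assert out.loc[0, "sd"] == pytest.approx(1.0)
        assert out.loc[0, "n"] == 3

    def test_singleton_sd_missing(self):
        df = pd.DataFrame(dict(g=["a", "b", "b"], y=[1.0, 2.0, 4.0]))
        out = group_summary(df, "y", "g").set_index("g")
        assert np.isnan(out.loc["a", "sd"])
        assert out.loc["b", "sd"] == pytest.approx(np.sqrt(2.0))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            dict(g=rng.choice(list("abc"), 60), y=rng.normal(5, 2, 60))
        )
        out = group_summary(df, "y", "g").set_index("g")
        for g, d in df.groupby("g"):
            v = d["y"].to_numpy()
            mean = v.sum() / len(v)
            sd = np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))
            assert out.loc[g, "mean"] == pytest.approx(mean, rel=1e-12)
            assert out.loc[g, "sd"] == pytest.approx(sd, rel=1e-12)
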