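"""Split-plot ANOVA, sphericity, Holm adjustment, elementary tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meridian.stats import (
    bonferroni,
    gg_epsilon,
    holm,
    mauchly,
    mixed_anova,
    paired_t,
    pearson,
    simple_main_effects,
    splitplot_anova_array,
    unpaired_t,
    unpaired_t_from_stats,
)

from oracles import splitplot_ss_bruteforce


def random_long_table(rng, g=2, n=4, a=3, b=2):
    rows = []
    for gi in range(g):
        for si in range(n):
            pid = f"g{gi}s{si}"
            for ai in range(a):
                for bi in range(b):
                    rows.append(
                        dict(
                            participant=pid,
                            group=f"G{gi}",
                            sf=float(ai),
                            orientation=f"O{bi}",
                            value=rng.normal(),
                        )
                    )
    return pd.DataFrame(rows)


def r_reference_table():
    """The deterministic dataset whose split-plot decomposition was
    cross-computed in R (base aov with Error(participant/(sf*orientation)))."""
    rng = np.random.default_rng(42)
    rows = []
    for gi, g in enumerate(["HAS", "NAS"]):
        for s in range(5):
            pid = f"{g}{s}"
            base = rng.normal(0, 0.5)
            for ai, a in enumerate([0.6, 1.3, 3.0]):
                for bi, b in enumerate(["H", "V"]):
                    val = base + 0.3 * ai + 0.2 * bi + 0.15 * gi * bi \
                        + rng.normal(0, 0.3)
                    rows.append(
                        dict(participant=pid, group=g, sf=a, orientation=b,
                             value=round(val, 6))
                    )
    return pd.DataFrame(rows)


class TestSplitplotCore:
    def test_matches_bruteforce_oracle_on_random_datasets(self, rng):
        """SS/df of the vectorized decomposition vs explicit textbook loops."""
        for _ in range(50):
            y = rng.normal(size=(2, 4, 3, 2))
            mine = splitplot_anova_array(y)
            oracle = splitplot_ss_bruteforce(y)
            assert set(mine) == set(oracle)
            for term, ss_oracle in oracle.items():
                assert mine[term][0] == pytest.approx(ss_oracle, abs=1e-8)

    def test_stratum_decomposition_sums_to_total(self, rng):
        y = rng.normal(size=(2, 6, 5, 2))
        terms = splitplot_anova_array(y)
        total = ((y - y.mean()) ** 2).sum()
        assert sum(ss for ss, _ in terms.values()) == pytest.approx(total, abs=1e-8)
        dfs = sum(df for _, df in terms.values())
        assert dfs == y.size - 1

    def test_single_within_factor_shape(self, rng):
        y = rng.normal(size=(2, 5, 4, 1))
        terms = splitplot_anova_array(y)
        assert set(terms) == {"G", "S(G)", "A", "GA", "AS(G)"}


class TestMixedAnova:
    def test_matches_r_aov_reference(self):
        """Frozen values computed independently in R: base aov on the
        deterministic dataset built by r_reference_table()."""
        res = mixed_anova(r_reference_table(), dv="value").set_index("effect")
        expected = {
            # effect: (SS, df, F, p)
            "group": (0.30837984019, 1, 0.60973, 0.45737),
            "sf": (3.32157575050, 2, 29.68468, 4.1248e-06),
            "orientation": (1.323766794402, 1, 18.47083, 0.0026237),
            "group × sf": (0.01323188835, 2, 0.11825, 0.88924),
            "group × orientation": (0.000055432404, 1, 0.00077, 0.9784940),
            "sf × orientation": (0.039885686535, 2, 0.25769, 0.77598),
            "group × sf × orientation": (0.125222811091, 2, 0.80903, 0.46270),
        }
        for effect, (ss, df, f_val, p) in expected.items():
            row = res.loc[effect]
            assert row["SS"] == pytest.approx(ss, rel=1e-9)
            assert row["df"] == df
            # F and p are frozen at R's printed precision (5 decimals)
            assert row["F"] == pytest.approx(f_val, rel=1e-3, abs=5e-6)
            assert row["p"] == pytest.approx(p, rel=1e-3, abs=5e-6)

    def test_matches_pingouin_one_within_design(self, rng):
        pg = pytest.importorskip("pingouin")
        table = random_long_table(rng, g=2, n=8, a=4, b=1).drop(
            columns="orientation"
        ).drop_duplicates(subset=["participant", "sf"])
        mine = mixed_anova(table, dv="value", within=["sf"]).set_index("effect")
        theirs = pg.mixed_anova(
            table, dv="value", within="sf", between="group",
            subject="participant",
        ).set_index("Source")
        for mine_key, pg_key in [("group", "group"), ("sf", "sf"),
                                 ("group × sf", "Interaction")]:
            assert mine.loc[mine_key, "SS"] == pytest.approx(
                theirs.loc[pg_key, "SS"], rel=1e-9
            )
            assert mine.loc[mine_key, "F"] == pytest.approx(
                theirs.loc[pg_key, "F"], rel=1e-9
            )
            assert mine.loc[mine_key, "p"] == pytest.approx(
                theirs.loc[pg_key, "p_unc"], rel=1e-9
            )

    def test_eta_squared_definition(self, rng):
        res = mixed_anova(random_long_table(rng, n=5), dv="value")
        for _, row in res.iterrows():
            assert row["eta2p"] == pytest.approx(
                row["SS"] / (row["SS"] + row["error_SS"])
            )
            assert 0 <= row["eta2p"] <= 1

    def test_two_level_within_factor_has_unit_epsilon_and_w(self, rng):
        res = mixed_anova(random_long_table(rng, n=6), dv="value").set_index(
            "effect"
        )
        assert res.loc["orientation", "gg_epsilon"] == 1.0
        assert res.loc["orientation", "mauchly_W"] == 1.0
        assert res.loc["orientation", "mauchly_p"] == 1.0

    def test_epsilon_bounds(self, rng):
        res = mixed_anova(random_long_table(rng, n=8, a=5), dv="value")
        within = res[res["effect"] == "sf"].iloc[0]
        assert 1 / 4 <= within["gg_epsilon"] <= 1.0

    def test_constant_table_degenerates_cleanly(self):
        table = random_long_table(np.random.default_rng(0), n=4)
        table["value"] = 2.0
        res = mixed_anova(table, dv="value")
        assert (res["SS"].abs() < 1e-20).all()
        assert (res["eta2p"] == 0).all()

    def test_gg_correction_application_policy(self, rng):
        res = mixed_anova(random_long_table(rng, n=6, a=4), dv="value",
                          gg_when="always").set_index("effect")
        assert res.loc["sf", "p_report"] == res.loc["sf", "gg_p"]
        res2 = mixed_anova(random_long_table(rng, n=6, a=4), dv="value",
                           gg_when="never").set_index("effect")
        assert res2.loc["sf", "p_report"] == res2.loc["sf", "p"]

    def test_incomplete_table_rejected_with_participant_named(self, rng):
        table = random_long_table(rng)
        table = table.drop(table.index[0])
        with pytest.raises(ValueError, match="g0s0"):
            mixed_anova(table, dv="value")

    def test_unequal_group_sizes_rejected(self, rng):
        table = random_long_table(rng)
        table = table[table["participant"] != "g0s0"]
        with pytest.raises(ValueError, match="group sizes"):
            mixed_anova(table, dv="value")

    def test_missing_values_rejected_with_message(self, rng):
        table = random_long_table(rng)
        table.loc[table.index[3], "value"] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova(table, dv="value")


class TestSphericity:
    def test_matches_pingouin_single_group(self, rng):
        pg = pytest.importorskip("pingouin")
        data = rng.normal(size=(20, 5)) @ np.diag([1.0, 1.0, 2.0, 3.0, 0.5])
        df = pd.DataFrame(data)
        w, p = mauchly(data)
        ref = pg.sphericity(df)
        assert w == pytest.approx(ref.W, rel=1e-9)
        # pingouin uses a higher-order chi-square term; p agrees loosely
        assert p == pytest.approx(ref.pval, rel=0.25)
        assert gg_epsilon(data) == pytest.approx(
            float(pg.epsilon(df, correction="gg")), rel=1e-9
        )

    def test_two_levels_trivially_spherical(self, rng):
        data = rng.normal(size=(10, 2))
        assert mauchly(data) == (1.0, 1.0)
        assert gg_epsilon(data) == 1.0

    def test_rank_one_covariance_hits_lower_bound(self, rng):
        import warnings

        data = np.outer(rng.normal(size=20), [1.0, 2.0, 3.0, 4.0, 5.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # W may be flagged singular
            assert gg_epsilon(data) == pytest.approx(1 / 4)

    def test_spherical_population_epsilon_near_one(self, rng):
        data = rng.normal(size=(400, 4))
        assert gg_epsilon(data) > 0.95

    def test_mauchly_calibrated_under_compound_symmetry(self):
        """Rejection rate at alpha = .05 within binomial tolerance of
        nominal for compound-symmetric Gaussian data (n=20, k=5)."""
        rng = np.random.default_rng(0)
        n_rep = 1000
        rejections = 0
        for _ in range(n_rep):
            data = rng.normal(size=(20, 5)) + rng.normal(size=(20, 1))
            _w, p = mauchly(data)
            rejections += p < 0.05
        rate = rejections / n_rep
        tol = 3 * math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < tol

    def test_mauchly_power_against_heteroscedastic_contrasts(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(500):
            data = rng.normal(size=(30, 5)) * np.array([0.3, 0.5, 1, 2, 4])
            _w, p = mauchly(data)
            hits += p < 0.05
        assert hits / 500 >= 0.95


class TestHolm:
    def test_worked_examples(self):
        adjusted = holm([0.003, 0.3, 0.4, 0.5, 0.6])
        assert adjusted[0] == pytest.approx(0.015)
        adjusted = holm([0.009, 0.1, 0.2, 0.3, 0.4])
        assert adjusted[0] == pytest.approx(0.045)

    def test_single_p_unchanged(self):
        assert holm([0.04])[0] == pytest.approx(0.04)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm([0.5, 1.2])
        with pytest.raises(ValueError):
            holm([-0.1])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10)
    )
    def test_holm_contract(self, pvals):
        """Adjusted >= raw, <= Bonferroni, monotone in rank order, and
        identical to the statsmodels reference implementation."""
        from statsmodels.stats.multitest import multipletests

        adjusted = holm(pvals)
        p = np.asarray(pvals)
        assert np.all(adjusted >= p - 1e-15)
        assert np.all(adjusted <= np.minimum(len(p) * p, 1.0) + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(adjusted, ref, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        assert np.allclose(holm(p)[perm], holm(p[perm]))

    def test_bonferroni(self):
        assert np.allclose(bonferroni([0.01, 0.4]), [0.02, 0.8])
        assert bonferroni([0.9, 0.9])[0] == 1.0


class TestSimpleMainEffects:
    def test_two_level_rm_f_equals_squared_paired_t(self, rng):
        table = random_long_table(rng, g=1, n=10, a=1, b=2)
        res = simple_main_effects(
            table, stratify_by=["sf"], test_factor="orientation", dv="value"
        )
        wide = table.pivot(index="participant", columns="orientation",
                           values="value")
        t_res = paired_t(wide["O0"], wide["O1"])
        assert res["F"].iloc[0] == pytest.approx(t_res.statistic ** 2, abs=1e-8)
        assert res["p"].iloc[0] == pytest.approx(t_res.p_raw, abs=1e-10)

    def test_between_factor_f_equals_squared_unpaired_t(self, rng):
        table = random_long_table(rng, g=2, n=8, a=1, b=1)
        res = simple_main_effects(
            table, stratify_by=["sf"], test_factor="group", dv="value"
        )
        g0 = table.loc[table["group"] == "G0", "value"]
        g1 = table.loc[table["group"] == "G1", "value"]
        t_res = unpaired_t(g0, g1)
        assert res["F"].iloc[0] == pytest.approx(t_res.statistic ** 2, abs=1e-8)

    def test_antisymmetric_stratum_gives_zero_f(self):
        rows = []
        for s in range(6):
            v = (s + 1) * 0.1
            rows.append(dict(participant=f"s{s}", sf=1.0, orientation="H",
                             value=v, group="G"))
            rows.append(dict(participant=f"s{s}", sf=1.0, orientation="V",
                             value=-v, group="G"))
        # H and V column means are +/- the same value; recenter so the
        # mean difference is zero -> zero factor SS
        table = pd.DataFrame(rows)
        table.loc[table["orientation"] == "V", "value"] += 2 * 0.35
        res = simple_main_effects(
            table, stratify_by=["sf"], test_factor="orientation", dv="value"
        )
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_family_adjustment_delegates_to_holm(self, rng):
        table = random_long_table(rng, g=1, n=8, a=5, b=2)
        res = simple_main_effects(
            table, stratify_by=["sf"], test_factor="orientation", dv="value"
        )
        assert len(res) == 5
        assert np.allclose(res["p_adjusted"], holm(res["p"].to_numpy()))


class TestElementaryTests:
    def test_paired_t_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_paired_t_constant_nonzero_difference_is_missing(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)

    def test_pearson_exact_linear(self):
        res = pearson([1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0])
        assert res.statistic == pytest.approx(1.0)

    def test_pearson_zero_variance_missing(self):
        res = pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)

    def test_unpaired_t_from_group_summary_moments(self):
        """Cylindrical-error group contrast from summary statistics
        (means -2.80 vs -0.234 D, SEMs 0.28 vs 0.05, n = 16) lands near
        the hand-computed pooled t of about -9.0."""
        res = unpaired_t_from_stats(
            -2.80, 0.28 * 4, 16, -0.234, 0.05 * 4, 16
        )
        assert res.df == 30
        assert -9.5 < res.statistic < -8.5
        assert res.p_raw < 0.001

    def test_unpaired_t_matches_scipy_df_welch(self, rng):
        x, y = rng.normal(size=12), rng.normal(1.0, 2.0, size=9)
        res = unpaired_t(x, y, equal_var=False)
        assert res.df < 19  # Welch df below the pooled df

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])
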