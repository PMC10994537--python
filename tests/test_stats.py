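import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tspopet import (
    bh_fdr,
    descriptive_tests,
    groupwise_tukey_by_voi,
    spearman,
    tukey_hsd,
    two_way_anova,
    voi_table,
    voxelwise_ttest,
)
from tspopet.stats import classify_d


class TestBhFdr:
    def test_stepup_on_four_values(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(10)), 1.0)

    def test_single_value_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_order_invariant(self, ps):
        p = np.array(ps)
        q = bh_fdr(p)
        assert np.all(q <= 1) and np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        shuffled = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_fdr(p[shuffled]), q[shuffled])


class TestVoxelwiseTtest:
    def _maps(self, arrays):
        return [np.asarray(a, float).reshape(1, 1, 1) for a in arrays]

    def test_identical_groups_null(self):
        a = self._maps([1.0, 2.0, 3.0])
        mask = np.ones((1, 1, 1), bool)
        res = voxelwise_ttest(a, a, mask)
        assert res.p[0, 0, 0] == pytest.approx(1.0)
        assert res.z[0, 0, 0] == 0.0

    def test_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = voxelwise_ttest(self._maps(a), self._maps(b), np.ones((1, 1, 1), bool))
        # closed form: means 2 and 5, pooled var 1, se = sqrt(2/3)
        t_expected = (2 - 5) / np.sqrt(2.0 / 3.0)
        p_expected = 2 * sps.t.sf(abs(t_expected), 4)
        assert res.t[0, 0, 0] == pytest.approx(t_expected)
        assert res.p[0, 0, 0] == pytest.approx(p_expected)
        d_expected = (2 - 5) / 1.0
        assert res.d[0, 0, 0] == pytest.approx(d_expected)

    def test_zero_variance_voxel_warns_and_p1(self):
        a = self._maps([1.0, 1.0, 1.0])
        b = self._maps([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = voxelwise_ttest(a, b, np.ones((1, 1, 1), bool))
        assert res.p[0, 0, 0] == 1.0

    def test_z_nonzero_only_where_significant(self, rng):
        shape = (8, 8, 4)
        mask = np.ones(shape, bool)
        a = [rng.normal(0, 1, shape) for _ in range(8)]
        b = [rng.normal(0, 1, shape) + 2.0 for _ in range(8)]
        res = voxelwise_ttest(a, b, mask)
        inside = mask & (res.q <= 0.05)
        outside = mask & (res.q > 0.05)
        assert np.all(res.z[outside] == 0)
        assert np.all(res.z[inside] != 0)
        assert np.all(res.q[mask] >= res.p[mask] - 1e-12)

    def test_needs_two_subjects_per_group(self):
        with pytest.raises(ValueError):
            voxelwise_ttest(self._maps([1.0]), self._maps([1.0, 2.0]),
                            np.ones((1, 1, 1), bool))


class TestEffectSizeClasses:
    @given(st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, d):
        c = classify_d(np.array([d]))[0]
        if abs(d) < 0.80:
            assert c == 1
        elif abs(d) <= 1.20:
            assert c == 2
        else:
            assert c == 3


class TestVoiTable:
    def test_noiseless_values_equal_truth(self, noiseless_phantom):
        _, lm, params = noiseless_phantom
        bp_map = np.zeros(lm.shape)
        for name in params:
            bp_map[lm.mask(name)] = params[name].bp
        subjects = pd.DataFrame(
            [{"id": "s0", "group": "control", "genotype": "HAB",
              "outcome": "favourable", "crs_r": 23}]
        )
        from tspopet.synthetic import DEFAULT_VOI_LIST

        tab = voi_table({"s0": bp_map}, lm, list(DEFAULT_VOI_LIST), subjects)
        assert len(tab) == 14  # 13 hypothesis VOIs + control region
        for _, row in tab.iterrows():
            assert row.bp == pytest.approx(params[row.voi].bp)
        assert not tab.lesioned.any()

    def test_lesion_overlap_flags_row(self, noiseless_phantom):
        _, lm, params = noiseless_phantom
        bp_map = np.zeros(lm.shape)
        subjects = pd.DataFrame(
            [{"id": "s0", "group": "traumatic", "genotype": "HAB",
              "outcome": "unfavourable", "crs_r": 3}]
        )
        lesion = lm.mask("thalamus").copy()
        tab = voi_table(
            {"s0": bp_map}, lm, ["thalamus", "putamen"], subjects,
            lesion_masks={"s0": lesion},
        )
        assert tab.set_index("voi").loc["thalamus", "lesioned"]
        assert not tab.set_index("voi").loc["putamen", "lesioned"]

    def test_missing_voi_raises(self, noiseless_phantom):
        _, lm, _ = noiseless_phantom
        subjects = pd.DataFrame([{"id": "s0", "group": "control", "genotype": "HAB"}])
        with pytest.raises(KeyError):
            voi_table({"s0": np.zeros(lm.shape)}, lm, ["amygdala"], subjects)


def _toy_table(cell_means, n_per_cell=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for (g, v), mu in cell_means.items():
        for _ in range(n_per_cell):
            rows.append(
                {"id": f"s{i}", "group": g, "voi": v, "genotype": "HAB",
                 "bp": mu + rng.normal(0, noise) if noise else mu}
            )
            i += 1
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_response_all_null(self):
        tab = _toy_table({("a", "x"): 1.0, ("a", "y"): 1.0,
                          ("b", "x"): 1.0, ("b", "y"): 1.0})
        res = two_way_anova(tab, covariate=None)
        assert np.all(res.F == 0)
        assert np.all(res.p == 1)

    def test_balanced_2x2_matches_hand_computed_sums_of_squares(self):
        # cell means with additive structure plus noise
        tab = _toy_table(
            {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 4.0},
            n_per_cell=5, noise=0.5, seed=42,
        )
        res = two_way_anova(tab, covariate=None, interaction=True).set_index("factor")
        # independent oracle: classical balanced two-way ANOVA from cell means
        y = tab.bp.to_numpy()
        g = (tab.group == "b").to_numpy()
        v = (tab.voi == "y").to_numpy()
        n = len(y)
        grand = y.mean()
        ss_g = sum(len(y[g == lev]) * (y[g == lev].mean() - grand) ** 2 for lev in (0, 1))
        ss_v = sum(len(y[v == lev]) * (y[v == lev].mean() - grand) ** 2 for lev in (0, 1))
        cells = {}
        for gl in (0, 1):
            for vl in (0, 1):
                cells[(gl, vl)] = y[(g == gl) & (v == vl)].mean()
        ss_cells = sum(
            5 * (cells[(gl, vl)] - grand) ** 2 for gl in (0, 1) for vl in (0, 1)
        )
        ss_int = ss_cells - ss_g - ss_v
        ss_err = sum(
            ((y[(g == gl) & (v == vl)] - cells[(gl, vl)]) ** 2).sum()
            for gl in (0, 1) for vl in (0, 1)
        )
        ms_err = ss_err / (n - 4)
        assert res.loc["C(group)", "F"] == pytest.approx(ss_g / 1 / ms_err, rel=1e-8)
        assert res.loc["C(voi)", "F"] == pytest.approx(ss_v / 1 / ms_err, rel=1e-8)
        assert res.loc["C(group):C(voi)", "F"] == pytest.approx(
            ss_int / 1 / ms_err, rel=1e-8
        )

    def test_single_level_factor_raises(self):
        tab = _toy_table({("a", "x"): 1.0, ("a", "y"): 2.0})
        with pytest.raises(ValueError):
            two_way_anova(tab, covariate=None)

    def test_genotype_covariate_enters_model(self):
        tab = _toy_table(
            {("a", "x"): 1.0, ("a", "y"): 2.0, ("b", "x"): 3.0, ("b", "y"): 4.0},
            n_per_cell=5, noise=0.3, seed=1,
        )
        tab.loc[::2, "genotype"] = "MAB"
        res = two_way_anova(tab)
        assert "C(genotype)" in set(res.factor)


class TestTukey:
    def test_two_groups_equal_pooled_t(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 10)
        tab = pd.DataFrame(
            {"group": ["a"] * 8 + ["b"] * 10, "bp": np.concatenate([a, b])}
        )
        res = tukey_hsd(tab, "group")
        _, p_t = sps.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.p_adj.iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_identical_means_p_near_one(self):
        tab = pd.DataFrame(
            {"group": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
             "bp": [1.0, 2, 3, 4] * 3}
        )
        res = tukey_hsd(tab, "group")
        assert np.all(res.p_adj > 0.999)

    def test_three_groups_match_brute_force_studentized_range(self, rng):
        groups = {g: rng.normal(mu, 1, 7) for g, mu in (("a", 0), ("b", 1), ("c", 3))}
        tab = pd.DataFrame(
            {"group": sum([[g] * 7 for g in groups], []),
             "bp": np.concatenate(list(groups.values()))}
        )
        res = tukey_hsd(tab, "group").set_index(["level_1", "level_2"])
        # independent recomputation of the q statistic and its tail probability
        k, df = 3, 18
        mse = np.mean([np.var(v, ddof=1) for v in groups.values()])
        for g1, g2 in itertools.combinations(groups, 2):
            q = abs(groups[g1].mean() - groups[g2].mean()) / np.sqrt(mse / 7)
            p = sps.studentized_range.sf(q, k, df)
            assert res.loc[(g1, g2), "p_adj"] == pytest.approx(p, rel=1e-8)

    def test_adjusted_p_not_below_unadjusted_for_three_groups(self, rng):
        groups = {g: rng.normal(0, 1, 6) for g in "abc"}
        tab = pd.DataFrame(
            {"group": sum([[g] * 6 for g in groups], []),
             "bp": np.concatenate(list(groups.values()))}
        )
        res = tukey_hsd(tab, "group").set_index(["level_1", "level_2"])
        for g1, g2 in itertools.combinations(groups, 2):
            _, p_raw = sps.ttest_ind(groups[g1], groups[g2])
            assert res.loc[(g1, g2), "p_adj"] >= p_raw - 1e-9

    def test_single_level_raises(self):
        tab = pd.DataFrame({"group": ["a"] * 5, "bp": np.arange(5.0)})
        with pytest.raises(ValueError):
            tukey_hsd(tab, "group")

    def test_by_voi_returns_within_voi_pairs_from_joint_family(self, rng):
        rows = []
        for g in ("ctrl", "anox"):
            for v in ("thal", "prec"):
                for i in range(6):
                    shift = 2.0 if (g, v) == ("anox", "thal") else 0.0
                    rows.append({"group": g, "voi": v, "bp": rng.normal(shift, 0.5)})
        tab = pd.DataFrame(rows)
        res = groupwise_tukey_by_voi(tab)
        assert set(res.voi) == {"thal", "prec"}
        thal = res[res.voi == "thal"].iloc[0]
        prec = res[res.voi == "prec"].iloc[0]
        assert thal.p_adj < 0.05 < prec.p_adj


class TestSpearman:
    def test_perfectly_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4, rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_exact_p_matches_full_enumeration_at_n5(self):
        x = [1, 2, 3, 4, 5]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        rho, p = spearman(x, y)
        # independent enumeration of all 120 rank permutations
        rx = np.array(x, float)
        null = []
        for perm in itertools.permutations(range(5)):
            ry = np.array(perm, float)
            null.append(np.corrcoef(rx, ry)[0, 1])
        p_expected = np.mean(np.abs(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(p_expected)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        rho_sp, p_sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestDescriptiveTests:
    def test_chi2_perfect_separation(self):
        df = pd.DataFrame(
            {"group": ["a"] * 10 + ["b"] * 10, "sex": ["m"] * 10 + ["f"] * 10}
        )
        res = descriptive_tests(df, categorical_cols=["sex"])
        row = res.iloc[0]
        assert row.test == "chi2"
        assert row.statistic == pytest.approx(20.0)

    def test_identical_distributions_rarely_significant(self, rng):
        hits = 0
        for i in range(20):
            df = pd.DataFrame(
                {
                    "group": ["a"] * 15 + ["b"] * 15,
                    # heavy-tailed so the Shapiro gate routes to Kruskal
                    "age": rng.standard_cauchy(30),
                }
            )
            res = descriptive_tests(df, numeric_cols=["age"])
            if res.iloc[0].p < 0.05:
                hits += 1
        assert hits <= 2  # >= 90% of replicates non-significant

    def test_routing_is_recorded(self, rng):
        df = pd.DataFrame(
            {"group": ["a"] * 30 + ["b"] * 30, "crs": rng.normal(size=60)}
        )
        res = descriptive_tests(df, numeric_cols=["crs"])
        assert res.iloc[0].test in ("anova", "kruskal")
        assert np.isfinite(res.iloc[0].shapiro_min_p)

    def test_empty_group_raises(self):
        df = pd.DataFrame({"group": pd.Categorical(["a"] * 3, categories=["a", "b"])})
        df["x"] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError):
            descriptive_tests(df, numeric_cols=["x"])
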