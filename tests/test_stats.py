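"""Cluster statistics, mixed RM-ANOVA, effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobipipe.stats import (
    bonferroni,
    cluster_contrast_suite,
    cohens_d,
    cohens_d_paired,
    gg_epsilon,
    mixed_rm_anova,
    pairwise_posthoc,
    partial_eta_sq,
    pointwise_t_map,
    runlength_mask,
    student_t_two_sample,
)


# ---------------------------------------------------------------------------
# pointwise t maps and the run-length criterion
# ---------------------------------------------------------------------------


class TestPointwiseT:
    def test_identical_stacks_give_zero_t_unit_p(self, rng):
        A = rng.normal(0, 1, (5, 2, 50))
        with pytest.warns(UserWarning, match="zero variance"):
            cmap = pointwise_t_map(A, A.copy(), "paired")
        np.testing.assert_array_equal(cmap.t_values, 0)
        np.testing.assert_array_equal(cmap.p_values, 1)
        assert not cmap.mask.any()

    def test_constant_difference_triggers_zero_variance_rule(self):
        A = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        B = np.array([0.0, 1.0, 2.0]).reshape(3, 1, 1)
        with pytest.warns(UserWarning, match="zero variance"):
            cmap = pointwise_t_map(A, B, "paired")
        assert cmap.p_values[0, 0] == 1.0

    def test_matches_textbook_paired_t(self):
        A = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        B = np.array([0.0, 1.0, 2.0, 5.0]).reshape(4, 1, 1)
        cmap = pointwise_t_map(A, B, "paired")
        # diffs [1,1,1,-1]: mean .5, sd 1 -> t = .5 / (1/2) = 1, df 3
        assert cmap.t_values[0, 0] == pytest.approx(1.0)
        from scipy.stats import t as tdist

        assert cmap.p_values[0, 0] == pytest.approx(2 * tdist.sf(1.0, 3))

    def test_two_sample_matches_scipy(self, rng):
        A = rng.normal(0, 1, (6, 1, 4))
        B = rng.normal(0.5, 1, (8, 1, 4))
        cmap = pointwise_t_map(A, B, "two_sample")
        from scipy.stats import ttest_ind

        t, p = ttest_ind(A[:, 0, :], B[:, 0, :], axis=0)
        np.testing.assert_allclose(cmap.t_values[0], t, rtol=1e-12)
        np.testing.assert_allclose(cmap.p_values[0], p, rtol=1e-12)


class TestRunLength:
    def test_nine_consecutive_samples_all_rejected(self):
        p = np.ones((1, 40))
        p[0, 5:14] = 0.01  # 9 samples
        assert not runlength_mask(p, 0.05, 10).any()

    def test_ten_consecutive_samples_all_kept(self):
        p = np.ones((1, 40))
        p[0, 5:15] = 0.01  # 10 samples
        mask = runlength_mask(p, 0.05, 10)
        assert mask[0, 5:15].all()
        assert mask.sum() == 10

    def test_runs_do_not_span_channels(self):
        p = np.ones((2, 12))
        p[0, 6:] = 0.01   # 6 sub-alpha at end of ch 0
        p[1, :6] = 0.01   # 6 at start of ch 1
        assert not runlength_mask(p, 0.05, 10).any()

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), alpha=st.sampled_from([0.01, 0.05]),
           run=st.sampled_from([5, 10, 15]))
    def test_monotone_in_alpha_and_run_length(self, seed, alpha, run):
        p = np.random.default_rng(seed).random((4, 80))
        base = runlength_mask(p, alpha, run)
        assert not (runlength_mask(p, alpha / 2, run) & ~base).any()
        assert not (runlength_mask(p, alpha, run + 3) & ~base).any()

    def test_null_simulation_filtered_rate_below_pointwise(self):
        """On white-noise nulls the mask passes far fewer cells than p<alpha."""
        rng = np.random.default_rng(7)
        masked = sub_alpha = total = 0
        for _rep in range(100):
            A = rng.normal(0, 1, (20, 16, 461))
            B = rng.normal(0, 1, (20, 16, 461))
            cmap = pointwise_t_map(A, B, "paired")
            masked += cmap.mask.sum()
            sub_alpha += (cmap.p_values < cmap.alpha).sum()
            total += cmap.p_values.size
        assert sub_alpha / total == pytest.approx(0.05, abs=0.01)
        assert masked < sub_alpha
        assert masked / total < 0.05


class TestClusterSuite:
    def _cells(self, effect_uv=0.0, noise=1.0, n_sub=12, seed=0,
               groups=("TD", "ASD"), affected=("TD",)):
        rng = np.random.default_rng(seed)
        t_ms = np.arange(461) / 512 * 1000 - 100
        channels = ["FCz", "Cz", "CPz", "Pz"]
        bump = np.exp(-((t_ms - 420) ** 2) / (2 * 40**2))
        spatial = np.array([0.2, 0.5, 1.0, 0.8])
        cells = {}
        for group in groups:
            for cond in ("S-NF-T", "W-NF-T", "W-F-T"):
                hit = rng.normal(0, noise, (n_sub, 4, 461))
                cr = rng.normal(0, noise, (n_sub, 4, 461))
                if group in affected:
                    cr = cr + effect_uv * spatial[:, None] * bump[None, :]
                cells[(group, cond)] = {"Hit": hit, "CR": cr}
        return cells, t_ms, channels

    def test_injected_p3_effect_found_where_injected(self):
        cells, t_ms, channels = self._cells(effect_uv=3.0, seed=1)
        maps = cluster_contrast_suite(cells, channel_labels=channels,
                                      time_ms=t_ms)
        assert len(maps) == 9
        cpz = channels.index("CPz")
        window = (t_ms >= 350) & (t_ms <= 500)
        for cond in ("S-NF-T", "W-NF-T", "W-F-T"):
            within = maps[("TD", cond)]
            assert within.mask[cpz, window].any()
            between = maps[("TD_vs_ASD", cond)]
            assert between.mask[cpz, window].any()

    def test_identical_groups_between_maps_near_empty(self):
        cells, t_ms, channels = self._cells(effect_uv=0.0, seed=2)
        maps = cluster_contrast_suite(cells, channel_labels=channels,
                                      time_ms=t_ms)
        for cond in ("S-NF-T", "W-NF-T", "W-F-T"):
            frac = maps[("TD_vs_ASD", cond)].mask.mean()
            assert frac < 0.05

    def test_zero_noise_zero_effect_all_maps_empty(self):
        cells, t_ms, channels = self._cells(effect_uv=0.0, noise=0.0, seed=3)
        with pytest.warns(UserWarning, match="zero variance"):
            maps = cluster_contrast_suite(cells, channel_labels=channels,
                                          time_ms=t_ms)
        assert all(not m.mask.any() for m in maps.values())

    def test_missing_cell_skips_map_with_reason(self):
        cells, t_ms, channels = self._cells(seed=4)
        del cells[("ASD", "W-F-T")]
        with pytest.warns(UserWarning, match="skipped"):
            maps = cluster_contrast_suite(cells, channel_labels=channels,
                                          time_ms=t_ms)
        assert ("ASD", "W-F-T") not in maps
        assert ("TD_vs_ASD", "W-F-T") not in maps
        assert len(maps) == 7


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------


def balanced_anova_oracle(Y, group_of, within_levels):
    """Brute-force SS decomposition for BALANCED mixed designs.

    Independent of the implementation: classical uncorrected-totals
    inclusion-exclusion on cell totals, valid when every group has the same
    number of subjects.  ``Y`` is subjects x cells with cells ordered as the
    cartesian product of ``within_levels``; ``group_of`` assigns each
    subject row to a group label.
    """
    n_sub, n_cells = Y.shape
    sizes = [len(l) for l in within_levels]
    assert np.prod(sizes) == n_cells
    cells = list(itertools.product(*[range(s) for s in sizes]))
    groups = sorted(set(group_of))
    rows = []
    for s in range(n_sub):
        for ci, cell in enumerate(cells):
            rows.append((s, group_of[s], *cell, Y[s, ci]))
    w_names = [f"w{j}" for j in range(len(sizes))]
    df = pd.DataFrame(rows, columns=["S", "B", *w_names, "y"])

    def U(factors):
        if not factors:
            return df["y"].sum() ** 2 / len(df)
        tot = df.groupby(list(factors))["y"].agg(["sum", "count"])
        return float((tot["sum"] ** 2 / tot["count"]).sum())

    ss = {}
    ss["B"] = U(["B"]) - U([])
    ss["S(B)"] = U(["S"]) - U(["B"])
    for j, w in enumerate(w_names):
        ss[w] = U([w]) - U([])
        ss[f"B:{w}"] = U(["B", w]) - U(["B"]) - U([w]) + U([])
        ss[f"{w}:S(B)"] = U(["S", w]) - U(["S"]) - U(["B", w]) + U(["B"])
    if len(w_names) == 2:
        a, b = w_names
        ss[f"{a}:{b}"] = U([a, b]) - U([a]) - U([b]) + U([])
        ss[f"B:{a}:{b}"] = (U(["B", a, b]) - U(["B", a]) - U(["B", b])
                            - U([a, b]) + U(["B"]) + U([a]) + U([b]) - U([]))
        ss[f"{a}:{b}:S(B)"] = (U(["S", a, b]) - U(["S", a]) - U(["S", b])
                               - U(["B", a, b]) + U(["S"]) + U(["B", a])
                               + U(["B", b]) - U(["B"]))
    return ss


def _random_design(rng, n_within=1):
    n_per_group = int(rng.integers(3, 7))
    sizes = [int(rng.integers(2, 4)) for _ in range(n_within)]
    levels = [[f"w{j}l{i}" for i in range(s)] for j, s in enumerate(sizes)]
    groups = ["G1"] * n_per_group + ["G2"] * n_per_group
    n_cells = int(np.prod(sizes))
    Y = rng.normal(0, 1, (len(groups), n_cells)) + \
        rng.normal(0, 1, (len(groups), 1))
    return Y, groups, levels


def _long_format(Y, groups, levels):
    rows = []
    cells = list(itertools.product(*levels))
    for s, g in enumerate(groups):
        for ci, cell in enumerate(cells):
            row = {"subject": f"s{s}", "group": g, "y": Y[s, ci]}
            for j, lev in enumerate(cell):
                row[f"w{j}"] = lev
            rows.append(row)
    return pd.DataFrame(rows)


class TestMixedAnovaOracle:
    @pytest.mark.parametrize("n_within", [1, 2])
    def test_matches_brute_force_ss_on_random_balanced_designs(self, n_within):
        rng = np.random.default_rng(42 + n_within)
        for _rep in range(50):
            Y, groups, levels = _random_design(rng, n_within)
            oracle = balanced_anova_oracle(Y, groups, levels)
            df = _long_format(Y, groups, levels)
            within = [f"w{j}" for j in range(n_within)]
            tab = mixed_rm_anova(
                df, "y", "subject", within, "group",
                order={**{f"w{j}": levels[j] for j in range(n_within)},
                       "group": ["G1", "G2"]},
            ).set_index("effect")
            name_map = {"group": "B"}
            for j in range(n_within):
                name_map[f"w{j}"] = f"w{j}"
                name_map[f"group:w{j}"] = f"B:w{j}"
            if n_within == 2:
                name_map["w0:w1"] = "w0:w1"
                name_map["group:w0:w1"] = "B:w0:w1"
            for mine, theirs in name_map.items():
                assert tab.loc[mine, "SS"] == pytest.approx(
                    oracle[theirs], rel=1e-8, abs=1e-10), (mine, _rep)
            # error strata
            assert tab.attrs["subject_error"]["SS"] == pytest.approx(
                oracle["S(B)"], rel=1e-8)
            for j in range(n_within):
                assert tab.loc[f"w{j}", "SS_error"] == pytest.approx(
                    oracle[f"w{j}:S(B)"], rel=1e-8)

    def test_matches_spss_style_type3_reference_values(self):
        """Frozen cross-check: car::Anova (type III, contr.sum) univariate
        output for this exact dataset."""
        rng = np.random.default_rng(1)
        rows = []
        for g, n in (("TD", 8), ("ASD", 10)):
            for s in range(n):
                base = rng.normal(0, 1)
                for ci, c in enumerate(["A", "B", "C"]):
                    rows.append({
                        "subject": f"{g}{s}", "group": g, "cond": c,
                        "y": base + 0.5 * ci
                        + (0.3 if g == "TD" else 0) * ci
                        + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        tab = mixed_rm_anova(
            df, "y", "subject", "cond", "group",
            order={"group": ["TD", "ASD"], "cond": ["A", "B", "C"]},
        ).set_index("effect")
        assert tab.loc["group", "SS"] == pytest.approx(1.4974, abs=2e-4)
        assert tab.loc["group", "F"] == pytest.approx(0.3501, abs=2e-4)
        assert tab.loc["cond", "SS"] == pytest.approx(12.5995, abs=2e-4)
        assert tab.loc["cond", "F"] == pytest.approx(9.0487, abs=2e-4)
        assert tab.loc["cond", "p_uncorrected"] == pytest.approx(
            0.000768, abs=2e-6)
        assert tab.loc["cond", "gg_epsilon"] == pytest.approx(
            0.9988181, abs=2e-6)
        assert tab.loc["group:cond", "SS"] == pytest.approx(2.3878, abs=2e-4)
        assert tab.loc["group:cond", "F"] == pytest.approx(1.7149, abs=2e-4)
        assert tab.loc["group:cond", "p_uncorrected"] == pytest.approx(
            0.196118, abs=2e-6)

    def test_type_one_error_rates_on_null_data(self):
        """Uncorrected per-effect rejection rate ~ alpha on null simulations."""
        rng = np.random.default_rng(2024)
        n_sims = 1000
        rejections = None
        for _i in range(n_sims):
            Y = rng.normal(0, 1, (12, 6)) + rng.normal(0, 1, (12, 1))
            groups = ["G1"] * 5 + ["G2"] * 7
            levels = [["r1", "r2"], ["c1", "c2", "c3"]]
            df = _long_format(Y, groups, levels)
            tab = mixed_rm_anova(df, "y", "subject", ["w0", "w1"], "group")
            p = tab.set_index("effect")["p_uncorrected"]
            rejections = (p < 0.05).astype(int) if rejections is None \
                else rejections + (p < 0.05).astype(int)
        rates = rejections / n_sims
        for effect, rate in rates.items():
            assert 0.03 <= rate <= 0.07, (effect, rate)

    def test_incomplete_cells_raise(self):
        df = _long_format(np.zeros((4, 6)), ["G1", "G1", "G2", "G2"],
                          [["a", "b"], ["x", "y", "z"]])
        df = df[~((df["subject"] == "s0") & (df["w1"] == "z"))]
        with pytest.raises(ValueError, match="incomplete"):
            mixed_rm_anova(df, "y", "subject", ["w0", "w1"], "group")


class TestEpsilonAndEta:
    def test_two_level_factor_epsilon_is_one(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert gg_epsilon(S) == 1.0

    def test_compound_symmetry_epsilon_is_one(self):
        k = 3
        S = np.eye(k) * 2.0 + 0.5 * (np.ones((k, k)) - np.eye(k))
        assert gg_epsilon(S) == pytest.approx(1.0, abs=1e-6)

    def test_rank_one_covariance_hits_lower_bound(self):
        v = np.array([1.0, -2.0, 1.0])  # orthogonal to the constant vector
        assert gg_epsilon(np.outer(v, v)) == pytest.approx(0.5, abs=1e-12)

    def test_partial_eta_squared_arithmetic(self):
        assert partial_eta_sq(10.0, 30.0) == 0.25

    def test_epsilon_identity_on_anova_with_compound_symmetric_population(self):
        # a 2-level within factor always reports epsilon exactly 1
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 1, (10, 2))
        df = _long_format(Y, ["G1"] * 5 + ["G2"] * 5, [["a", "b"]])
        tab = mixed_rm_anova(df, "y", "subject", "w0", "group")
        eps = tab.set_index("effect").loc["w0", "gg_epsilon"]
        assert eps == pytest.approx(1.0, abs=1e-6)


class TestEffectSizes:
    def test_equal_means_give_zero(self):
        assert cohens_d(5, 1.2, 10, 5, 1.4, 12).value == 0.0
        t, df, _p = student_t_two_sample(5, 1.2, 10, 5, 1.4, 12)
        assert t == 0.0 and df == 20

    def test_stride_time_variability_group_effect(self):
        d = cohens_d(2.599, 1.41, 18, 3.830, 1.41, 17)
        assert d.value == pytest.approx(-0.873, abs=1e-3)

    def test_walking_speed_t_and_d(self):
        t, df, _p = student_t_two_sample(1.47, 0.531, 11, 1.89, 0.329, 12)
        assert df == 21
        assert t == pytest.approx(-2.296, abs=0.01)
        d = cohens_d(1.89, 0.329, 12, 1.47, 0.531, 11)
        assert abs(d.value) == pytest.approx(0.959, abs=0.005)

    def test_antisymmetric_in_group_order(self):
        a = cohens_d(2.0, 1.0, 10, 3.0, 2.0, 12).value
        b = cohens_d(3.0, 2.0, 12, 2.0, 1.0, 10).value
        assert a == pytest.approx(-b, rel=1e-12)

    def test_paired_d(self):
        assert cohens_d_paired(1.5, 3.0, 10).value == 0.5


class TestBonferroniAndPosthoc:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(bonferroni([0.02, 0.5], m=3), [0.06, 1.0])

    @settings(deadline=None, max_examples=30)
    @given(p=st.floats(0, 1), m=st.integers(1, 20))
    def test_adjusted_never_below_raw(self, p, m):
        assert bonferroni([p], m=m)[0] >= p

    def test_paired_posthoc_table(self, rng):
        df = pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(10)], 3),
            "cond": ["A", "B", "C"] * 10,
            "y": rng.normal(0, 1, 30) + np.tile([0.0, 0.5, 1.0], 10),
        })
        out = pairwise_posthoc(df, "y", "cond", "subject", paired=True)
        assert len(out) == 3
        assert (out["p_bonferroni"] >= out["p"]).all()
        row = out.set_index(["level_a", "level_b"]).loc[("A", "C")]
        assert row["t"] < 0
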