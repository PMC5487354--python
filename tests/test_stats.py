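"""Statistical-inference tests: ANOVA against paired-t / brute-force /
statsmodels oracles, permutation calibration, KS screen, and power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pointkin import (
    MissingCellError,
    PermConfig,
    cell_means,
    cluster_permutation_ftest,
    cluster_permutation_ttest,
    ks_normality,
    partial_eta_squared,
    rm_anova,
    rm_anova_power,
)
from pointkin.stats import _max_cluster_masses, _pointwise_rm_f


def random_table(rng, n_subj=13, levels=(2, 2, 3), dv="y"):
    rows = []
    for s in range(n_subj):
        for combo in itertools.product(*[range(k) for k in levels]):
            rows.append(
                {
                    "subject": s,
                    **{f"f{i}": f"l{c}" for i, c in enumerate(combo)},
                    dv: rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestCellMeans:
    def test_single_trial_per_cell_passthrough(self):
        rng = np.random.default_rng(0)
        df = random_table(rng, n_subj=3).rename(
            columns={"f0": "action", "f1": "addressee", "f2": "sign"}
        )
        means = cell_means(df, ["y"])
        assert len(means) == 3 * 12
        merged = means.merge(
            df, on=["subject", "action", "addressee", "sign"], suffixes=("_m", "")
        )
        np.testing.assert_allclose(merged["y_m"], merged["y"])

    def test_duplicated_trials_leave_means_unchanged(self):
        rng = np.random.default_rng(1)
        df = random_table(rng, n_subj=2).rename(
            columns={"f0": "action", "f1": "addressee", "f2": "sign"}
        )
        doubled = pd.concat([df, df], ignore_index=True)
        a = cell_means(df, ["y"])
        b = cell_means(doubled, ["y"])
        np.testing.assert_allclose(a["y"], b["y"])

    def test_missing_cell_error_names_subject_and_cell(self):
        rng = np.random.default_rng(2)
        df = random_table(rng, n_subj=2).rename(
            columns={"f0": "action", "f1": "addressee", "f2": "sign"}
        )
        drop = (df["subject"] == 1) & (df["action"] == "l0") & (df["addressee"] == "l1") & (df["sign"] == "l2")
        with pytest.raises(MissingCellError, match="1"):
            cell_means(df[~drop], ["y"])


class TestRmAnova:
    def test_two_level_factor_equals_paired_t_squared(self):
        # oracle: F = t^2 for a single 2-level within factor
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 13
            a, b = rng.normal(size=n), rng.normal(size=n)
            df = pd.DataFrame(
                {
                    "subject": np.tile(np.arange(n), 2),
                    "cond": np.repeat(["a", "b"], n),
                    "y": np.concatenate([a, b]),
                }
            )
            res = rm_anova(df, dv="y", within=("cond",))
            t, p = sps.ttest_rel(a, b)
            assert res["cond"]["F"] == pytest.approx(t**2, rel=1e-10)
            assert res["cond"]["p"] == pytest.approx(p, rel=1e-10)
            assert res["cond"]["df1"] == 1 and res["cond"]["df2"] == n - 1

    def test_matches_statsmodels_anova_rm(self):
        # independent implementation cross-check on the full 2x2x3 design
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(4)
        df = random_table(rng, n_subj=13)
        res = rm_anova(df, dv="y", within=("f0", "f1", "f2"))
        sm = AnovaRM(df, depvar="y", subject="subject", within=["f0", "f1", "f2"]).fit()
        for effect in sm.anova_table.index:
            ours = res[effect]
            theirs = sm.anova_table.loc[effect]
            assert ours["F"] == pytest.approx(theirs["F Value"], rel=1e-8)
            assert ours["df1"] == theirs["Num DF"]
            assert ours["df2"] == theirs["Den DF"]
            assert ours["p"] == pytest.approx(theirs["Pr > F"], rel=1e-8, abs=1e-12)

    def test_brute_force_sums_of_squares(self):
        # oracle: direct double-centred residual computation for a
        # one-factor design with 3 levels
        rng = np.random.default_rng(5)
        n, m = 9, 3
        Y = rng.normal(size=(n, m))
        g = Y.mean()
        ss_eff = n * np.sum((Y.mean(axis=0) - g) ** 2)
        resid = Y - Y.mean(axis=0) - Y.mean(axis=1, keepdims=True) + g
        ss_err = np.sum(resid**2)
        F_oracle = (ss_eff / (m - 1)) / (ss_err / ((n - 1) * (m - 1)))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), m),
                "cond": np.tile([f"l{j}" for j in range(m)], n),
                "y": Y.ravel(),
            }
        )
        res = rm_anova(df, dv="y", within=("cond",))
        assert res["cond"]["F"] == pytest.approx(F_oracle, rel=1e-9)
        assert res["cond"]["eta_p2"] == pytest.approx(
            ss_eff / (ss_eff + ss_err), rel=1e-9
        )

    def test_zero_condition_differences_give_zero_f(self):
        n = 8
        base = np.random.default_rng(6).normal(size=n)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(n), 2),
                "cond": np.repeat(["a", "b"], n),
                "y": np.concatenate([base, base]),
            }
        )
        res = rm_anova(df, dv="y", within=("cond",))
        assert res["cond"]["F"] == pytest.approx(0.0, abs=1e-18)

    def test_eta_identity_from_f_and_dfs(self):
        # eta_p2 = F*df1 / (F*df1 + df2)
        assert partial_eta_squared(16.49, 1, 12) == pytest.approx(0.579, abs=5e-4)
        assert partial_eta_squared(12.14, 1, 12) == pytest.approx(0.503, abs=5e-4)
        assert partial_eta_squared(3.77, 2, 24) == pytest.approx(0.239, abs=5e-4)


class TestKSNormality:
    def test_normal_sample_rarely_rejected(self):
        rng = np.random.default_rng(7)
        hits = sum(
            ks_normality(rng.normal(size=200)).pvalue > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(8)
        res = ks_normality(rng.uniform(size=1000))
        assert res.pvalue < 0.01

    def test_constant_values_degenerate(self):
        res = ks_normality(np.full(10, 3.14))
        assert res.degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestClusterHelpers:
    def test_max_cluster_mass_matches_manual_enumeration(self):
        T = np.array(
            [
                [0.0, 3.0, 4.0, 0.0, 5.0, 0.0],
                [6.0, 0.0, 0.0, 2.5, 2.5, 2.5],
                [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            ]
        )
        out = _max_cluster_masses(T, threshold=2.0, two_sided=False)
        np.testing.assert_allclose(out, [7.0, 7.5, 0.0])
        out2 = _max_cluster_masses(-T, threshold=2.0, two_sided=True)
        np.testing.assert_allclose(out2, [7.0, 7.5, 0.0])

    def test_pointwise_f_agrees_with_rm_anova(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 3, 4))
        F = _pointwise_rm_f(X)
        for k in range(4):
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(10), 3),
                    "cond": np.tile(["a", "b", "c"], 10),
                    "y": X[:, :, k].ravel(),
                }
            )
            res = rm_anova(df, dv="y", within=("cond",))
            assert F[k] == pytest.approx(res["cond"]["F"], rel=1e-9)


class TestClusterPermutation:
    def test_identical_conditions_produce_no_clusters(self):
        diffs = np.zeros((10, 100))
        res = cluster_permutation_ttest(diffs, PermConfig(n_permutations=200, seed=0))
        assert res.clusters == []

    def test_detects_injected_window(self):
        rng = np.random.default_rng(10)
        n, K = 13, 100
        diffs = rng.normal(0, 1.0, size=(n, K))
        diffs[:, 30:70] += 2.0  # strong effect confined to samples 30-69
        res = cluster_permutation_ttest(diffs, PermConfig(n_permutations=1000, seed=1))
        sig = [c for c in res.clusters if c.p < 0.05 and c.sign > 0]
        assert sig
        big = max(sig, key=lambda c: c.mass)
        overlap = max(0, min(big.stop, 70) - max(big.start, 30))
        assert overlap / 40 >= 0.8

    def test_type_i_error_calibrated_at_alpha(self):
        # Monte-Carlo under the null: the rate of min cluster p <= 0.05
        # over 300 simulations must sit inside the binomial 95% interval
        rng = np.random.default_rng(11)
        n_sim, n, K = 300, 13, 50
        false_pos = 0
        for s in range(n_sim):
            diffs = rng.normal(size=(n, K))
            res = cluster_permutation_ttest(
                diffs, PermConfig(n_permutations=500, seed=1000 + s)
            )
            if res.min_p <= 0.05:
                false_pos += 1
        rate = false_pos / n_sim
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= ci + 1e-9

    def test_invariant_to_consistent_time_relabeling(self):
        # reversing the time axis for every subject permutes cluster spans
        # but leaves masses and p-values unchanged
        rng = np.random.default_rng(12)
        diffs = rng.normal(size=(8, 60))
        diffs[:, 10:25] += 1.5
        cfg = PermConfig(n_permutations=400, seed=3)
        a = cluster_permutation_ttest(diffs, cfg)
        b = cluster_permutation_ttest(diffs[:, ::-1], cfg)
        assert sorted(round(c.mass, 9) for c in a.clusters) == sorted(
            round(c.mass, 9) for c in b.clusters
        )
        assert sorted(c.p for c in a.clusters) == pytest.approx(
            sorted(c.p for c in b.clusters)
        )

    def test_exact_enumeration_for_small_n(self):
        rng = np.random.default_rng(13)
        diffs = rng.normal(size=(6, 30)) + 1.0
        res = cluster_permutation_ttest(diffs, PermConfig(n_permutations=200, seed=0))
        assert res.exact
        assert res.n_permutations == 64
        for c in res.clusters:
            assert c.p >= 1 / 64

    def test_f_variant_detects_level_differences(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(12, 3, 80))
        X[:, 2, 40:60] += 1.5
        res = cluster_permutation_ftest(X, PermConfig(n_permutations=300, seed=5))
        assert any(c.p < 0.05 for c in res.clusters)


class TestPower:
    def test_reference_design_powers(self):
        assert rm_anova_power(0.2, 13, 2, corr=0.5) > 0.9
        assert rm_anova_power(0.43, 10, 2, corr=0.5) > 0.99

    def test_null_effect_power_equals_alpha(self):
        assert rm_anova_power(0.0, 13, 2) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_n_and_effect_size(self):
        powers_n = [rm_anova_power(0.2, n, 2) for n in (5, 8, 13, 20, 40)]
        assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
        powers_e = [rm_anova_power(e, 13, 2) for e in (0.05, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(powers_e, powers_e[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rm_anova_power(1.2, 13)
        with pytest.raises(ValueError):
            rm_anova_power(0.2, 1)
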