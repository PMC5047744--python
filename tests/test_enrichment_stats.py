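"""Welch tests, normality gating, variability threshold, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from histoquant.enrichment_stats import (
    DegenerateVarianceError,
    fold_change_table,
    global_log2_compare,
    pearson_matrix,
    shapiro_gate,
    variability_threshold,
    welch_test,
)
from histoquant.quantification import AbundanceTable, TIDY_COLUMNS
from histoquant.synthetic_data import default_config, simulate_replicates


def _table(rows):
    return AbundanceTable(pd.DataFrame(rows, columns=TIDY_COLUMNS))


class TestWelch:
    def test_identical_groups(self):
        r = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_antisymmetric_in_group_order(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 7)
        r1, r2 = welch_test(a, b), welch_test(b, a)
        assert r1.t == pytest.approx(-r2.t, abs=1e-12)
        assert r1.df == pytest.approx(r2.df, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_enrichment_in_second_group_gives_negative_t(self, rng):
        inp = rng.normal(0.1, 0.01, 4)
        pull = rng.normal(0.5, 0.05, 4)
        assert welch_test(inp, pull).t < 0

    def test_matches_reference_implementations(self, rng):
        """1000 random group pairs: t/df/p equal scipy's Welch test and a
        directly coded Welch-Satterthwaite formula to 1e-9."""
        for _ in range(1000):
            na, nb = rng.integers(2, 12, 2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), nb)
            r = welch_test(a, b)
            t_sp, p_sp = sps.ttest_ind(a, b, equal_var=False)
            assert r.t == pytest.approx(t_sp, abs=1e-9)
            assert r.p == pytest.approx(p_sp, abs=1e-9)
            sa, sb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            df_ref = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
            assert r.df == pytest.approx(df_ref, abs=1e-9)

    def test_degenerate_variance(self):
        r = welch_test([2.0, 2.0], [2.0, 2.0])
        assert r.degenerate and r.p == 1.0
        with pytest.raises(DegenerateVarianceError):
            welch_test([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [1.0, 2.0])


class TestShapiroGate:
    def test_inapplicable_below_three(self):
        r = shapiro_gate([0.1, 0.2])
        assert not r.applicable and not r.normal

    def test_degenerate_equal_values(self):
        r = shapiro_gate([0.3, 0.3, 0.3, 0.3])
        assert not r.applicable and "identical" in r.reason

    def test_normal_sample_passes(self, rng):
        r = shapiro_gate(rng.normal(0, 1, 100))
        assert r.applicable and r.normal

    def test_p_uniform_under_null(self):
        """Shapiro-Wilk p-values on normal samples are U(0,1) (KS check)."""
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            pvals.append(shapiro_gate(rng.normal(0, 1, 20)).p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestVariabilityThreshold:
    @staticmethod
    def _pair_table(ratios):
        rows = []
        for i, r in enumerate(ratios):
            t = r / (1 + r)
            rows.append((f"s{i}", "input", i, "H2A_12-17", "H2A_12-17_T", t, False))
            rows.append((f"s{i}", "input", i, "H2A_12-17", "H2A_12-17_S", 1 - t, False))
        return _table(rows)

    def test_identical_ratios_zero_threshold(self):
        res = variability_threshold(self._pair_table([1.1, 1.1, 1.1]))
        assert res.spread == pytest.approx(0.0, abs=1e-12)
        assert res.threshold == pytest.approx(0.0, abs=1e-12)

    def test_spread_twenty_percent_gives_point_four(self):
        # ratios 0.8 and 1.2 around mean 1.0: max deviation exactly 20%
        res = variability_threshold(self._pair_table([0.8, 1.2]))
        assert res.spread == pytest.approx(0.20)
        assert res.threshold == pytest.approx(0.40)

    def test_missing_pair_falls_back(self):
        rows = [("s0", "input", 0, "H3_18-26", "H3_18-26:unmod", 1.0, False)]
        with pytest.warns(UserWarning, match="falling back"):
            res = variability_threshold(_table(rows))
        assert res.fallback and res.threshold == 0.40

    def test_sd_mode(self):
        res = variability_threshold(self._pair_table([0.8, 1.0, 1.2]), mode="sd")
        assert res.spread == pytest.approx(np.std([0.8, 1.0, 1.2], ddof=1) / 1.0)

    def test_synthetic_ratio_cv_matches_lognormal_model(self):
        """Under per-unit log-normal CV-0.2 noise the T/S ratio CV is
        sqrt(exp(2 ln(1+0.2^2)) - 1) ~ 0.285; check over 300 seeds."""
        cvs = []
        for seed in range(300):
            cfg = default_config(seed=seed)
            table, _ = simulate_replicates(cfg)
            res = variability_threshold(table, mode="sd")
            cvs.append(res.spread)
        expected = np.sqrt(np.exp(2 * np.log1p(0.04)) - 1)
        assert np.mean(cvs) == pytest.approx(expected, rel=0.1)


class TestFoldChangeTable:
    @staticmethod
    def _two_condition_table(input_vals, pull_vals, form="H3_18-26:K18acK23ac"):
        rows = []
        for i, v in enumerate(input_vals):
            rows.append((f"input_r{i}", "input", i, "H3_18-26", form, v, False))
        for i, v in enumerate(pull_vals):
            rows.append((f"pull_r{i}", "pull", i, "H3_18-26", form, v, False))
        return _table(rows)

    def test_equal_means_fold_one(self):
        t = self._two_condition_table([0.1, 0.2, 0.3, 0.2], [0.2, 0.1, 0.2, 0.3])
        out = fold_change_table(t, [("input", "pull")], threshold=0.4)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)
        assert not out.loc[0, "exceeds_technical"]

    def test_zero_input_mean_infinite_fold(self):
        t = self._two_condition_table([0.0, 0.0, 0.0], [0.1, 0.2, 0.15])
        out = fold_change_table(t, [("input", "pull")], threshold=0.4)
        assert np.isinf(out.loc[0, "fold_change"])
        assert out.loc[0, "exceeds_technical"]

    def test_unknown_condition_errors(self):
        t = self._two_condition_table([0.1] * 3, [0.1] * 3)
        with pytest.raises(KeyError, match="unknown condition"):
            fold_change_table(t, [("input", "nope")], threshold=0.4)

    def test_n2_groups_get_ranges_not_tests(self):
        t = self._two_condition_table([0.1, 0.12, 0.11, 0.13], [0.4, 0.5])
        out = fold_change_table(t, [("input", "pull")], threshold=0.4)
        assert np.isnan(out.loc[0, "t"]) and np.isnan(out.loc[0, "p"])
        assert out.loc[0, "range_pulldown"] == pytest.approx(0.1)

    def test_recovers_injected_five_fold_effect(self):
        """Mean estimated fold over 200 simulations brackets the injected
        post-normalization truth."""
        folds, truths = [], []
        for seed in range(200):
            cfg = default_config(
                seed=seed,
                backbones=("H3_18-26",),
                true_abundances={
                    "H3_18-26": {
                        "H3_18-26:unmod": 0.55,
                        "H3_18-26:K18ac": 0.05,
                        "H3_18-26:K23ac": 0.30,
                        "H3_18-26:K18acK23ac": 0.10,
                    }
                },
                n_replicates={"input": 4, "BRD4short": 4},
                effect_sizes={"BRD4short": {"H3_18-26:K18acK23ac": 5.0}},
            )
            table, truth = simulate_replicates(cfg)
            out = fold_change_table(table, [("input", "BRD4short")], threshold=0.4)
            row = out[out["form"] == "H3_18-26:K18acK23ac"].iloc[0]
            folds.append(row["fold_change"])
            truths.append(
                truth["condition_means"]["BRD4short"]["H3_18-26"]["H3_18-26:K18acK23ac"] / 0.10
            )
        assert np.mean(folds) == pytest.approx(np.mean(truths), rel=0.05)

    def test_gated_welch_type_one_error_calibrated(self):
        """Null (no effect, n=4 vs 4, CV 0.2): rejection rate within 2 MC
        standard errors of alpha = 0.05 over 1000 simulations."""
        n_sim = 1000
        rejections = 0
        for seed in range(n_sim):
            cfg = default_config(
                seed=seed,
                backbones=("H3_18-26",),
                true_abundances={
                    "H3_18-26": {
                        "H3_18-26:unmod": 0.55,
                        "H3_18-26:K18ac": 0.05,
                        "H3_18-26:K23ac": 0.30,
                        "H3_18-26:K18acK23ac": 0.10,
                    }
                },
                n_replicates={"input": 4, "BRD4short": 4},
                effect_sizes={"BRD4short": {}},
            )
            table, _ = simulate_replicates(cfg)
            from histoquant.enrichment_stats import welch_test

            a = table.group_values("input", "H3_18-26:K18acK23ac")
            b = table.group_values("BRD4short", "H3_18-26:K18acK23ac")
            if welch_test(a, b).p < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 2 * se


class TestPearsonMatrix:
    @staticmethod
    def _samples_table(vectors):
        rows = []
        forms = [f"H3_18-26:{x}" for x in ("unmod", "K18ac", "K23ac", "K18acK23ac")]
        for s, vec in vectors.items():
            vec = np.asarray(vec, dtype=float)
            vec = vec / vec.sum()
            for f, v in zip(forms, vec):
                rows.append((s, s.split("_")[0], 1, "H3_18-26", f, v, False))
        return _table(rows)

    def test_symmetric_unit_diagonal(self):
        t = self._samples_table({"a_1": [1, 2, 3, 4], "b_1": [4, 3, 2, 1], "c_1": [1, 3, 2, 4]})
        m = pearson_matrix(t)
        assert np.allclose(m.r, m.r.T, equal_nan=True)
        assert np.allclose(np.diag(m.r), 1.0)
        for i in m.samples:
            for j in m.samples:
                lo, hi = m.ci_lower.loc[i, j], m.ci_upper.loc[i, j]
                if np.isfinite(lo):
                    assert lo <= m.r.loc[i, j] <= hi

    def test_affine_related_samples_have_r_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t = self._samples_table({"a_1": x, "b_1": 2 * x + 3})
        m = pearson_matrix(t)
        assert m.r.loc["a_1", "b_1"] == pytest.approx(1.0)

    def test_too_few_common_forms_flagged(self):
        rows = [
            ("a", "a", 1, "H3_18-26", "H3_18-26:unmod", 0.5, False),
            ("a", "a", 1, "H3_18-26", "H3_18-26:K18ac", 0.5, False),
            ("b", "b", 1, "H3_18-26", "H3_18-26:unmod", 0.5, False),
            ("b", "b", 1, "H3_18-26", "H3_18-26:K18ac", 0.5, False),
        ]
        m = pearson_matrix(_table(rows))
        assert np.isnan(m.r.loc["a", "b"])

    def test_p_uniform_under_null(self):
        """Independent random abundance vectors: correlation p-values U(0,1)."""
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            t = self._samples_table(
                {"a_1": rng.uniform(0.1, 1, 4) * 0 + rng.uniform(0.1, 1, 4),
                 "b_1": rng.uniform(0.1, 1, 4)}
            )
            p = pearson_matrix(t).p.loc["a_1", "b_1"]
            if np.isfinite(p):
                pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_below_limit_excluded_pairwise(self):
        rows = [
            ("a", "a", 1, "H3_18-26", "H3_18-26:unmod", 0.5, False),
            ("a", "a", 1, "H3_18-26", "H3_18-26:K18ac", 0.2, False),
            ("a", "a", 1, "H3_18-26", "H3_18-26:K23ac", 0.3, False),
            ("a", "a", 1, "H3_18-26", "H3_18-26:K18acK23ac", 0.0, True),
            ("b", "b", 1, "H3_18-26", "H3_18-26:unmod", 0.4, False),
            ("b", "b", 1, "H3_18-26", "H3_18-26:K18ac", 0.3, False),
            ("b", "b", 1, "H3_18-26", "H3_18-26:K23ac", 0.3, False),
            ("b", "b", 1, "H3_18-26", "H3_18-26:K18acK23ac", 0.0, False),
        ]
        m = pearson_matrix(_table(rows))
        assert m.n.loc["a", "b"] == 3  # the below-limit form dropped


class TestGlobalLog2:
    @staticmethod
    def _one_sample(name, fracs):
        rows = []
        forms = ["H3_18-26:unmod", "H3_18-26:K18ac", "H3_18-26:K23ac", "H3_18-26:K18acK23ac"]
        for f, v in zip(forms, fracs):
            rows.append((name, name, 1, "H3_18-26", f, v, False))
        return _table(rows)

    def test_unchanged_form_is_zero(self):
        t0 = self._one_sample("t0", [0.4, 0.1, 0.3, 0.2])
        out = global_log2_compare(t0, self._one_sample("t1", [0.4, 0.1, 0.3, 0.2]))
        assert np.allclose(out.dropna(), 0.0)

    def test_twofold_decrease_maps_to_plus_one(self):
        t0 = self._one_sample("t0", [0.4, 0.2, 0.2, 0.2])
        t1 = self._one_sample("t1", [0.5, 0.1, 0.2, 0.2])
        out = global_log2_compare(t0, t1)
        assert out["H3_18-26:K18ac"] == pytest.approx(1.0)

    def test_constructed_global_shift(self):
        """Uniformly scaling the non-reference forms injects a common shift."""
        base = np.array([0.25, 0.25, 0.25, 0.25])
        t0 = self._one_sample("t0", base)
        shifted = base * np.array([1, 0.5, 0.5, 0.5])
        t1 = self._one_sample("t1", shifted / shifted.sum())
        out = global_log2_compare(t0, t1)
        forms = ["H3_18-26:K18ac", "H3_18-26:K23ac", "H3_18-26:K18acK23ac"]
        vals = out[forms]
        assert np.allclose(vals, vals.iloc[0])
        assert vals.iloc[0] > 0  # decreases map to positive values
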