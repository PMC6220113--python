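"""Univariate arm: LMM, Wilcoxon, t-test, Fisher, FDR, Friedewald, labels."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import pmet
from pmet.errors import ConfigurationError, DesignError
from pmet.univariate import (
    classify_weight_gain,
    fdr_bh,
    fisher_exact_2x2,
    friedewald_ldl,
    lmm_time_effect,
    two_sample_t,
    univariate_table,
    wilcoxon_signed_rank,
)

from conftest import matrix_from_arrays, paired_matrix


def wilcoxon_enum_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    mu = ranks.sum() / 2.0
    w_obs = ranks[d > 0].sum()
    total = 0
    count = 0
    for signs in itertools.product((1, -1), repeat=d.size):
        w = ranks[np.array(signs) > 0].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def fisher_enum_p(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    arr = np.asarray(table, dtype=int)
    r1 = arr[0].sum()
    r2 = arr[1].sum()
    c1 = arr[:, 0].sum()
    n = arr.sum()
    dist = stats.hypergeom(n, r1, c1)
    p_obs = dist.pmf(arr[0, 0])
    total = 0.0
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        pa = dist.pmf(a)
        if pa <= p_obs * (1 + 1e-7):
            total += pa
    return min(1.0, float(total))


class TestLmm:
    def test_identical_timepoints_degenerate(self):
        values = np.tile(np.exp(np.random.default_rng(0).normal(size=(8, 1))), (2, 1))
        m = matrix_from_arrays(values, [f"P{i}" for i in range(8)] * 2,
                               [0] * 8 + [6] * 8)
        res = lmm_time_effect(m, "m0", 0, 6)
        assert res.time_effect == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.degenerate

    def test_balanced_data_equals_mean_paired_difference(self):
        rng = np.random.default_rng(1)
        m = paired_matrix(rng, n_patients=20, n_vars=2)
        res = lmm_time_effect(m, "m0", 0, 6)
        logs = np.log(m.values["m0"].to_numpy())
        tps = m.sample_meta["timepoint_months"].to_numpy()
        expected = logs[tps == 6].reshape(-1).mean() - logs[tps == 0].mean()
        # balanced complete design: REML fixed effect is the paired mean
        assert res.time_effect == pytest.approx(expected, abs=1e-8)
        assert res.n_patients_used == 20

    def test_patients_with_single_timepoint_are_retained(self):
        rng = np.random.default_rng(2)
        m = paired_matrix(rng, n_patients=12, n_vars=1)
        m.values.iloc[1, 0] = np.nan  # P00 loses its 6-month visit
        res = lmm_time_effect(m, "m0", 0, 6)
        assert res.n_patients_used == 12
        assert 0.0 <= res.p_value <= 1.0

    def test_non_positive_values_raise(self):
        rng = np.random.default_rng(3)
        m = paired_matrix(rng, n_patients=8, n_vars=1)
        m.values.iloc[0, 0] = 0.0
        with pytest.raises(ConfigurationError):
            lmm_time_effect(m, "m0", 0, 6)


class TestWilcoxon:
    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank(np.zeros(10))
        assert res.p_value == 1.0 and res.degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_exact_p_matches_sign_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1.0, n)
        while np.unique(np.abs(d)).size < n or (d == 0).any():
            d = rng.normal(0.4, 1.0, n)
        res = wilcoxon_signed_rank(d)
        assert res.p_value == pytest.approx(wilcoxon_enum_p(d), abs=1e-12)

    def test_strong_shift_is_significant(self):
        rng = np.random.default_rng(4)
        d = np.abs(rng.normal(2.0, 0.5, 50)) + 0.1
        assert wilcoxon_signed_rank(d).p_value < 0.001

    def test_too_few_nonzero_raises(self):
        with pytest.raises(DesignError):
            wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, -2.0, 0.5]))


class TestTwoSampleT:
    def test_identical_groups(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = two_sample_t(v, g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        g_swapped = np.array(["b"] * 10 + ["a"] * 10)
        r1 = two_sample_t(v, g)
        r2 = two_sample_t(v, g_swapped)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)

    def test_matches_pooled_variance_formula(self):
        a = np.array([4.1, 5.2, 6.3, 5.8])
        b = np.array([3.9, 4.0, 5.1])
        v = np.concatenate([a, b])
        g = np.array(["a"] * 4 + ["b"] * 3)
        res = two_sample_t(v, g)
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p = 2 * stats.t.sf(abs(t), a.size + b.size - 2)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_degenerate_group_raises(self):
        with pytest.raises(DesignError):
            two_sample_t(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestFisher:
    def test_central_table_has_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            tab = rng.integers(0, 11, (2, 2))
            if tab.sum() <= 40 and (tab.sum(0) > 0).all() and (tab.sum(1) > 0).all():
                break
        res = fisher_exact_2x2(tab)
        assert res.p_value == pytest.approx(fisher_enum_p(tab), abs=1e-10)

    @pytest.mark.parametrize(
        "table", [[[1, -2], [3, 4]], [[1.5, 2], [3, 4]], [[0, 0], [3, 4]]]
    )
    def test_invalid_tables_raise(self, table):
        with pytest.raises(ConfigurationError):
            fisher_exact_2x2(table)


class TestFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.03]), [0.03])

    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_step_up_definition_and_permutation_invariance(self, pvals):
        p = np.asarray(pvals)
        q = fdr_bh(p)
        # independent step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j
        order = np.argsort(p, kind="stable")
        m = p.size
        sorted_q = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(sorted_q, 1.0)
        np.testing.assert_allclose(q, expected, atol=1e-12)
        perm = np.random.default_rng(0).permutation(m)
        np.testing.assert_allclose(fdr_bh(p[perm]), q[perm], atol=1e-12)

    def test_blocks_are_independent(self):
        p = np.array([0.01, 0.5, 0.02, 0.9])
        blocks = np.array(["A", "A", "B", "B"])
        q = fdr_bh(p, blocks)
        qa = fdr_bh(p[:2])
        np.testing.assert_allclose(q[:2], qa)
        p2 = p.copy()
        p2[2:] = [0.001, 0.001]  # changing block B must not move block A
        q2 = fdr_bh(p2, blocks)
        np.testing.assert_allclose(q2[:2], q[:2])

    def test_out_of_range_p_raises(self):
        with pytest.raises(ConfigurationError):
            fdr_bh([0.5, 1.2])


class TestClinicalHelpers:
    def test_friedewald_worked_example(self):
        assert friedewald_ldl(5.0, 1.2, 1.1) == pytest.approx(3.3)

    def test_friedewald_zero_tg(self):
        assert friedewald_ldl(5.0, 1.2, 0.0) == pytest.approx(3.8)

    def test_friedewald_validity_bound(self):
        with pytest.raises(ConfigurationError):
            friedewald_ldl(5.0, 1.2, 5.0)

    def test_weight_gain_boundary(self):
        clin = pd.DataFrame(
            {
                "patient_id": ["A", "B", "C"],
                "weight_kg_0": [70.0, 70.0, 70.0],
                "weight_kg_6": [71.5, 71.49, np.nan],
            }
        )
        out = classify_weight_gain(clin)
        assert out["A"] == "gainer"
        assert out["B"] == "non_gainer"
        assert out["C"] == "unknown"

    def test_missing_baseline_raises(self):
        clin = pd.DataFrame(
            {"patient_id": ["A"], "weight_kg_0": [np.nan], "weight_kg_6": [70.0]}
        )
        with pytest.raises(ConfigurationError):
            classify_weight_gain(clin)


class TestUnivariateTable:
    def test_table_shape_and_fdr(self):
        rng = np.random.default_rng(6)
        m = paired_matrix(rng, n_patients=15, n_vars=5)
        table = univariate_table(m, "MS", 0, 6, test="lmm")
        assert list(table.columns) == ["variable", "block", "test", "statistic", "p", "q"]
        assert len(table) == 5
        assert (table["q"] >= table["p"] - 1e-12).all()
        wtab = univariate_table(m, "LIPO", 0, 6, test="wilcoxon")
        assert (wtab["test"] == "wilcoxon").all()
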