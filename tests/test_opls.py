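"""Multilevel OPLS-DA engine: pairing, fit, VIP, grouped CV, permutations."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import pmet
from pmet.errors import ConfigurationError, DesignError, FitError, PredictionError
from pmet.opls import (
    DiscriminantDataset,
    PairedDataset,
    PermutationResult,
    _assign_folds,
    build_paired_dataset,
    cross_validate,
    fit_opls_da,
    permutation_test,
    predict,
    scale_columns,
    select_components,
    vip_scores,
)

from conftest import matrix_from_arrays, paired_matrix


def null_paired(rng, n_patients=20, n_vars=10):
    diffs = rng.normal(0.0, 1.0, (n_patients, n_vars))
    return PairedDataset.from_differences(
        diffs, [f"P{i:03d}" for i in range(n_patients)], [f"v{j}" for j in range(n_vars)]
    )


class TestPairedDataset:
    def test_rows_are_antisymmetric_mirrors(self):
        rng = np.random.default_rng(0)
        ds = build_paired_dataset(paired_matrix(rng), 0, 6)
        np.testing.assert_allclose(ds.X[0::2], -ds.X[1::2])
        assert (ds.y[0::2] == 1).all() and (ds.y[1::2] == -1).all()
        assert (ds.patients[0::2] == ds.patients[1::2]).all()

    def test_identical_timepoints_give_zero_rows(self):
        values = np.tile(np.exp(np.random.default_rng(1).normal(size=(6, 4))), (2, 1))
        patients = [f"P{i}" for i in range(6)] * 2
        tps = [0] * 6 + [6] * 6
        m = matrix_from_arrays(values, patients, tps)
        ds = build_paired_dataset(m, 0, 6)
        np.testing.assert_allclose(ds.X, 0.0)

    def test_incomplete_patients_excluded_and_listed(self):
        rng = np.random.default_rng(2)
        m = paired_matrix(rng, n_patients=9)
        keep = ~(
            (m.sample_meta["patient_id"] == "P08")
            & (m.sample_meta["timepoint_months"] == 6)
        )
        m2 = matrix_from_arrays(
            m.values[keep.to_numpy()].to_numpy(),
            m.sample_meta.loc[keep, "patient_id"].tolist(),
            m.sample_meta.loc[keep, "timepoint_months"].tolist(),
        )
        ds = build_paired_dataset(m2, 0, 6)
        assert ds.n_patients == 8
        assert ds.excluded_patients == ["P08"]

    def test_too_few_patients_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(DesignError):
            build_paired_dataset(paired_matrix(rng, n_patients=5), 0, 6)

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(4)
        m = paired_matrix(rng)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(ConfigurationError):
            build_paired_dataset(m, 0, 6)

    def test_study_scale_design(self, default_cohort):
        # 53 patients with both MS timepoints -> 106 mirrored rows, 7 excluded
        ds = build_paired_dataset(
            default_cohort["ms_complete"], 0, 6,
            patients=default_cohort["clinical"]["patient_id"].tolist(),
        )
        assert ds.X.shape[0] == 106
        assert ds.n_patients == 53
        assert len(ds.excluded_patients) == 7


class TestScaling:
    def test_centering(self):
        X = np.array([[1.0], [3.0]])
        Xs, recipe = scale_columns(X, unit_variance=False)
        np.testing.assert_allclose(Xs[:, 0], [-1.0, 1.0])

    def test_autoscaled_column_has_unit_sd(self):
        rng = np.random.default_rng(5)
        Xs, _ = scale_columns(rng.normal(3.0, 7.0, (40, 3)))
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_constant_column_flagged_not_divided(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        Xs, recipe = scale_columns(X)
        assert recipe.constant_columns[0] and not recipe.constant_columns[1]
        assert recipe.scales[0] == 1.0
        np.testing.assert_allclose(Xs[:, 0], 0.0)


class TestFit:
    def test_zero_orth_equals_pls1(self):
        # OPLS-DA with no orthogonal components must coincide with a
        # one-component PLS1 regression under identical scaling
        rng = np.random.default_rng(6)
        for _ in range(20):
            X = rng.normal(size=(30, 15))
            y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
            model = fit_opls_da(X, y, 0, unit_variance=False)
            pls = PLSRegression(n_components=1, scale=False).fit(X, y)
            t_ref = pls.x_scores_[:, 0]
            sign = np.sign(t_ref @ model.t)
            np.testing.assert_allclose(model.t, sign * t_ref, atol=1e-8)

    def test_orthogonal_scores_uncorrelated_with_labels(self):
        rng = np.random.default_rng(7)
        ds = null_paired(rng, 25, 12)
        for n_orth in (1, 2, 3):
            model = fit_opls_da(ds.X, ds.y, n_orth)
            for a in range(n_orth):
                t_o = model.T_o[:, a]
                assert abs(np.corrcoef(t_o, ds.y)[0, 1]) < 1e-8
            gram = model.T_o.T @ model.T_o
            off = gram - np.diag(np.diag(gram))
            assert np.abs(off).max() < 1e-8
        assert np.linalg.norm(model.w) == pytest.approx(1.0)

    def test_orthogonal_filtering_recovers_predictive_correlation(self):
        # structured y-orthogonal variation dilutes the single-component
        # score; one orthogonal component should restore it
        rng = np.random.default_rng(8)
        n, p = 60, 20
        y = np.tile([1.0, -1.0], n // 2)
        a = rng.normal(size=p)
        b = rng.normal(size=p)
        b -= (b @ a) / (a @ a) * a  # structured direction orthogonal to signal
        g = rng.normal(size=n) * 4.0
        g -= g.mean()
        g -= (g @ y) / (y @ y) * y  # structured scores orthogonal to labels
        X = np.outer(y, a) + np.outer(g, b) + rng.normal(0, 0.3, (n, p))
        c0 = abs(np.corrcoef(fit_opls_da(X, y, 0).t, y)[0, 1])
        c1 = abs(np.corrcoef(fit_opls_da(X, y, 1).t, y)[0, 1])
        assert c1 >= c0

    def test_rank_exhaustion_raises(self):
        X = np.outer(np.tile([1.0, -1.0], 4), np.ones(3))
        y = np.tile([1.0, -1.0], 4)
        with pytest.raises(FitError):
            fit_opls_da(X, y, 2, unit_variance=False)


class TestPredict:
    def test_training_labels_reproduced_on_separable_data(self):
        rng = np.random.default_rng(9)
        y = np.repeat([1.0, -1.0], 15)
        X = np.outer(y, [1.0, 0.5, -0.3]) + rng.normal(0, 0.05, (30, 3))
        model = fit_opls_da(X, y, 0)
        _, labels = predict(model, X)
        np.testing.assert_array_equal(labels, y)

    def test_class_mean_vector_classified_positive(self):
        rng = np.random.default_rng(10)
        y = np.repeat([1.0, -1.0], 15)
        X = np.outer(y, [1.0, 0.5, -0.3]) + rng.normal(0, 0.05, (30, 3))
        model = fit_opls_da(X, y, 1)
        _, labels = predict(model, X[y > 0].mean(axis=0))
        assert labels[0] == 1.0

    def test_training_scores_match_stored_scores(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 8))
        y = np.tile([1.0, -1.0], 10)
        model = fit_opls_da(X, y, 0)
        scores, _ = predict(model, X)
        np.testing.assert_allclose(scores, model.t, atol=1e-8)

    def test_column_mismatch_raises(self):
        rng = np.random.default_rng(12)
        model = fit_opls_da(rng.normal(size=(10, 5)), np.tile([1.0, -1.0], 5), 0)
        with pytest.raises(PredictionError):
            predict(model, rng.normal(size=(3, 4)))


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        y = np.tile([1.0, -1.0], 8)
        X = np.outer(y, np.ones(4))
        model = fit_opls_da(X, y, 0, unit_variance=False)
        np.testing.assert_allclose(vip_scores(model).to_numpy(), 1.0, atol=1e-10)

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(13)
        for n_orth in (0, 1, 2):
            X = rng.normal(size=(24, 10))
            y = np.tile([1.0, -1.0], 12)
            model = fit_opls_da(X, y, n_orth)
            vip = vip_scores(model).to_numpy()
            assert (vip >= 0).all()
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)

    def test_signal_variables_outrank_null_variables(self):
        rng = np.random.default_rng(14)
        hits = 0
        for _ in range(100):
            diffs = rng.normal(0, 1, (30, 20))
            diffs[:, :4] += 1.0
            ds = PairedDataset.from_differences(
                diffs, [f"P{i}" for i in range(30)], [f"v{j}" for j in range(20)]
            )
            vip = vip_scores(fit_opls_da(ds.X, ds.y, 0)).to_numpy()
            if np.median(vip[:4]) > np.median(vip[4:]):
                hits += 1
        assert hits >= 95


class TestSelectComponents:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([0.40, 0.30, 0.32, 0.25], 1),
            ([0.40, 0.30, 0.20], 2),
            ([0.30, 0.30, 0.40], 0),
            ([0.25], 0),
            ([0.5, 0.5, 0.5], 2),
            ([0.2, 0.3, 0.1], 0),
        ],
    )
    def test_first_local_minimum(self, curve, expected):
        assert select_components(curve) == expected

    def test_result_is_valid_index(self):
        rng = np.random.default_rng(15)
        for _ in range(50):
            curve = rng.random(rng.integers(1, 8))
            idx = select_components(curve)
            assert 0 <= idx < curve.size


class TestCrossValidation:
    def test_label_column_gives_perfect_accuracy(self):
        rng = np.random.default_rng(16)
        n = 40
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        X = np.column_stack([y, 0.3 * rng.normal(size=(n, 5))])
        ds = DiscriminantDataset(X, y, np.array([f"P{i}" for i in range(n)]),
                                 [f"v{j}" for j in range(6)])
        cv = cross_validate(ds, max_orth=2, n_folds=10, n_iter=3, seed=0,
                            unit_variance=False)
        np.testing.assert_allclose(1.0 - cv.error_curve, 1.0)
        assert cv.accuracy == 1.0

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(17)
        ds = null_paired(rng, n_patients=200, n_vars=50)
        cv = cross_validate(ds, max_orth=1, n_folds=10, n_iter=2, seed=1)
        assert 0.4 <= cv.accuracy <= 0.6

    def test_planted_effect_reaches_high_accuracy(self):
        rng = np.random.default_rng(18)
        n = 50
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.normal(size=(n, 100))
        X[:, :10] += np.outer(y, np.full(10, 1.0))  # Cohen's d = 2
        ds = DiscriminantDataset(X, y, np.array([f"P{i}" for i in range(n)]),
                                 [f"v{j}" for j in range(100)])
        cv = cross_validate(ds, max_orth=2, n_folds=10, n_iter=3, seed=2)
        assert cv.accuracy >= 0.9

    def test_error_equals_balanced_misclassification(self):
        rng = np.random.default_rng(19)
        ds = null_paired(rng, 20, 8)
        cv = cross_validate(ds, max_orth=2, n_folds=5, n_iter=2, seed=3)
        np.testing.assert_allclose(
            cv.error_curve, 1.0 - (cv.sensitivity_curve + cv.specificity_curve) / 2
        )
        assert 0 <= cv.chosen_n_orth <= 2

    def test_fewer_patients_than_folds_raises(self):
        rng = np.random.default_rng(20)
        with pytest.raises(DesignError):
            cross_validate(null_paired(rng, 8, 4), n_folds=10)

    def test_folds_partition_patients(self):
        rng = np.random.default_rng(21)
        patients = np.repeat([f"P{i}" for i in range(23)], 2)
        fold_of = _assign_folds(patients, {}, 10, rng, stratify=False)
        assert set(fold_of) == set(f"P{i}" for i in range(23))
        assert set(fold_of.values()) <= set(range(10))
        labels = {f"P{i}": 1.0 if i % 3 else -1.0 for i in range(23)}
        fold_strat = _assign_folds(np.array(list(labels)), labels, 5, rng, stratify=True)
        assert set(fold_strat) == set(labels)


class TestMultilevelSymmetry:
    def test_swapping_timepoint_roles_negates_scores_and_flips_labels(self):
        rng = np.random.default_rng(22)
        m = paired_matrix(rng, n_patients=12, n_vars=8)
        fwd = build_paired_dataset(m, 0, 6)
        rev = build_paired_dataset(m, 6, 0)
        np.testing.assert_allclose(rev.X, -fwd.X, atol=1e-12)
        np.testing.assert_array_equal(rev.y, fwd.y)
        m_fwd = fit_opls_da(fwd.X, fwd.y, 1, variables=fwd.variables)
        m_rev = fit_opls_da(rev.X, rev.y, 1, variables=rev.variables)
        probes = rng.normal(size=(5, 8))
        s_fwd, l_fwd = predict(m_fwd, probes)
        s_rev, l_rev = predict(m_rev, probes)
        np.testing.assert_allclose(s_rev, -s_fwd, atol=1e-8)
        np.testing.assert_array_equal(l_rev, -l_fwd)


class TestPermutation:
    def test_p_value_formula_from_accuracies(self):
        perms = np.full(1000, 0.6)
        res = PermutationResult.from_accuracies(1.0, perms)
        assert res.p_value == 0.0
        assert res.p_label == "<0.001"
        res = PermutationResult.from_accuracies(0.6, perms)
        assert res.p_value == 1.0
        res = PermutationResult.from_accuracies(0.7, np.linspace(0, 1, 101))
        assert res.p_value == pytest.approx(31 / 101)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigurationError):
            PermutationResult.from_accuracies(0.5, np.array([]))
        rng = np.random.default_rng(23)
        with pytest.raises(ConfigurationError):
            permutation_test(null_paired(rng, 12, 4), n_perm=0, n_folds=4, n_iter=1)

    def test_small_run_properties(self):
        rng = np.random.default_rng(24)
        ds = null_paired(rng, 12, 6)
        res = permutation_test(ds, n_perm=19, max_orth=1, n_folds=4, n_iter=1, seed=5)
        assert 0.0 <= res.p_value <= 1.0
        assert res.permuted_accuracies.shape == (19,)
        n_ge = np.sum(res.permuted_accuracies >= res.observed_accuracy - 1e-12)
        assert res.p_value == pytest.approx(n_ge / 19)

    def test_separable_data_yields_minimal_p(self):
        rng = np.random.default_rng(25)
        diffs = rng.normal(0, 0.1, (14, 5)) + 3.0
        ds = PairedDataset.from_differences(
            diffs, [f"P{i}" for i in range(14)], [f"v{j}" for j in range(5)]
        )
        res = permutation_test(ds, n_perm=39, max_orth=0, n_folds=7, n_iter=2, seed=6)
        assert res.observed_accuracy == 1.0
        assert res.p_label.startswith("<")
        assert res.p_value <= 0.05
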