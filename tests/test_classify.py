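import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from spiraldct import (
    ClassifierKind,
    CVMode,
    EvalConfig,
    FeatureMatrix,
    Method,
    NormMode,
    SelectionMode,
    combine_feature_sets,
    grid_search,
    kfold_cv,
    loocv,
    normalize_features,
)
from spiraldct.classify import KNN_K_GRID, L_GRID, SVM_COST_GRID, SVM_SCALE_GRID
from spiraldct.pipeline import feature_matrix_from_samples
from spiraldct.synthetic_spirals import CohortSpec, generate_cohort

from .oracles import knn_predict_direct, loo_accuracy_direct


def _clusters(rng, n=40, d=3, sep=10.0):
    """Two well-separated Gaussian clusters (gap = sep standard deviations)."""
    half = n // 2
    X = np.vstack([rng.normal(0, 1, (half, d)), rng.normal(sep, 1, (n - half, d))])
    y = np.array(["CONTROL"] * half + ["ET"] * (n - half))
    return FeatureMatrix(X, [f"f{i}" for i in range(d)], y)


def _cfg(kind, **kw):
    return EvalConfig(classifier=kind, normalization=NormMode.UNIT_NORM_TRAINFOLD, **kw)


class TestNormalization:
    def test_column_scaled_to_unit_norm(self):
        fm = FeatureMatrix(np.array([[3.0], [4.0]]), ["a"], np.array(["ET", "CONTROL"]))
        out, norms = normalize_features(fm)
        np.testing.assert_allclose(out.values[:, 0], [0.6, 0.8])
        assert norms[0] == pytest.approx(5.0)

    def test_every_output_column_has_unit_norm(self, rng):
        fm = FeatureMatrix(rng.normal(size=(20, 6)), [f"f{i}" for i in range(6)],
                           rng.choice(["ET", "CONTROL"], 20))
        out, _ = normalize_features(fm)
        np.testing.assert_allclose(np.linalg.norm(out.values, axis=0), 1.0, atol=1e-12)

    def test_zero_column_warns_and_stays_zero(self, rng):
        vals = np.column_stack([rng.normal(size=10), np.zeros(10)])
        fm = FeatureMatrix(vals, ["a", "z"], np.array(["ET"] * 5 + ["CONTROL"] * 5))
        with pytest.warns(UserWarning):
            out, _ = normalize_features(fm)
        assert np.all(out.values[:, 1] == 0)

    def test_trainfold_scaling_differs_on_held_out_samples(self, rng):
        # scale fitted on the training fold applied to the test sample need
        # not produce unit-norm columns over the whole cohort
        fm = _clusters(rng, n=10)
        res = loocv(fm, _cfg(ClassifierKind.LDA))
        assert res.accuracy == 100.0  # sanity that the mode is exercised


class TestSeparableCase:
    @pytest.mark.parametrize(
        "kind,extra",
        [
            (ClassifierKind.LDA, {}),
            (ClassifierKind.KNN, {"knn_k": 3}),
            (ClassifierKind.SVM_RBF, {"svm_cost": 10.0, "svm_scale": 1.0}),
        ],
    )
    def test_loo_and_kfold_are_perfect(self, rng, kind, extra):
        fm = _clusters(rng)
        assert loocv(fm, _cfg(kind, **extra)).accuracy == 100.0
        assert kfold_cv(fm, _cfg(kind, **extra), seed=0).accuracy == 100.0


class TestLOOAgainstBruteForce:
    def test_lda_matches_per_sample_retrain(self, rng):
        fm = _clusters(rng, n=24, sep=2.0)
        got = loocv(fm, EvalConfig(classifier=ClassifierKind.LDA)).accuracy
        fmn, _ = normalize_features(fm)

        def fp(Xtr, ytr, xte):
            return LinearDiscriminantAnalysis().fit(Xtr, ytr).predict(xte)[0]

        assert got == loo_accuracy_direct(fp, fmn.values, fmn.labels)

    def test_svm_matches_per_sample_retrain(self, rng):
        fm = _clusters(rng, n=24, sep=1.5)
        cfg = EvalConfig(classifier=ClassifierKind.SVM_RBF, svm_cost=10.0, svm_scale=0.5)
        got = loocv(fm, cfg).accuracy
        fmn, _ = normalize_features(fm)

        def fp(Xtr, ytr, xte):
            clf = SVC(C=10.0, kernel="rbf", gamma=1.0 / 0.5**2)
            return clf.fit(Xtr, ytr).predict(xte)[0]

        assert got == loo_accuracy_direct(fp, fmn.values, fmn.labels)

    @pytest.mark.parametrize("k", [1, 3, 4])
    def test_knn_matches_per_sample_retrain(self, rng, k):
        fm = _clusters(rng, n=20, sep=1.0)
        got = loocv(fm, EvalConfig(classifier=ClassifierKind.KNN, knn_k=k)).accuracy
        fmn, _ = normalize_features(fm)

        def fp(Xtr, ytr, xte):
            return knn_predict_direct(Xtr, ytr, xte, k)

        assert got == loo_accuracy_direct(fp, fmn.values, fmn.labels)


class TestNullAndDegenerateBehaviour:
    def test_random_labels_give_chance_accuracy(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            X = rng.normal(size=(40, 3))
            y = rng.permutation(np.array(["ET"] * 20 + ["CONTROL"] * 20))
            fm = FeatureMatrix(X, ["a", "b", "c"], y)
            accs.append(loocv(fm, EvalConfig(classifier=ClassifierKind.LDA)).accuracy)
        assert abs(np.mean(accs) - 50.0) <= 20.0

    def test_knn_with_all_training_samples_votes_for_the_other_class(self, rng):
        # LOO on a balanced cohort: the held-out sample's own class is the
        # training minority, so k = n-1 predicts the opposite class
        X = rng.normal(size=(12, 2))
        y = np.array(["ET"] * 6 + ["CONTROL"] * 6)
        fm = FeatureMatrix(X, ["a", "b"], y)
        res = loocv(fm, EvalConfig(classifier=ClassifierKind.KNN, knn_k=11))
        assert res.accuracy == 0.0


class TestKFold:
    def test_fold_assignment_is_seed_deterministic(self, rng):
        fm = _clusters(rng, n=30, sep=1.0)
        cfg = EvalConfig(classifier=ClassifierKind.LDA, cv=CVMode.KFOLD10)
        r1 = kfold_cv(fm, cfg, seed=7)
        r2 = kfold_cv(fm, cfg, seed=7)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)

    def test_small_class_reduces_fold_count_with_warning(self, rng):
        X = rng.normal(size=(12, 2))
        X[:4] += 8
        y = np.array(["ET"] * 4 + ["CONTROL"] * 8)
        fm = FeatureMatrix(X, ["a", "b"], y)
        with pytest.warns(UserWarning, match="folds"):
            res = kfold_cv(fm, EvalConfig(classifier=ClassifierKind.LDA), seed=0)
        assert len(res.y_pred) == 12


class TestResultConsistency:
    def test_accuracy_equals_confusion_tally(self, rng):
        fm = _clusters(rng, n=30, sep=1.0)
        res = loocv(fm, EvalConfig(classifier=ClassifierKind.KNN, knn_k=5))
        cm = res.confusion
        assert res.accuracy == pytest.approx(100.0 * (cm.TP + cm.TN) / cm.total)
        assert cm.total == fm.n_samples

    def test_feature_column_order_is_irrelevant_to_svm(self, rng):
        fm = _clusters(rng, n=24, sep=1.5)
        perm = fm.subset([2, 0, 1])
        cfg = EvalConfig(classifier=ClassifierKind.SVM_RBF, svm_cost=100.0, svm_scale=0.4)
        np.testing.assert_array_equal(
            loocv(fm, cfg).y_pred, loocv(perm, cfg).y_pred
        )


class TestGrids:
    def test_printed_grids(self):
        assert L_GRID == (10, 15, 16, 17, 18, 20, 21, 22, 23, 25, 30, 50)
        assert KNN_K_GRID == tuple(range(1, 34, 2))
        assert len(SVM_COST_GRID) == 10 and len(SVM_SCALE_GRID) == 11

    def test_off_grid_values_warn(self):
        with pytest.warns(UserWarning, match="outside the study grid"):
            EvalConfig(L=13).validate_grids()

    def test_single_cell_grid_equals_direct_call(self, rng):
        fm = _clusters(rng, n=20, sep=1.0)
        cfg = EvalConfig(classifier=ClassifierKind.SVM_RBF)
        out = grid_search({17: fm}, cfg, cost_grid=[10.0], scale_grid=[0.5])
        direct = loocv(fm, EvalConfig(classifier=ClassifierKind.SVM_RBF,
                                      svm_cost=10.0, svm_scale=0.5))
        assert out.best_accuracy == direct.accuracy
        assert out.table.shape == (1, 1)

    def test_table_dimensions_match_requested_grids(self, rng):
        fm = _clusters(rng, n=20, sep=1.0)
        out = grid_search({10: fm, 17: fm}, EvalConfig(classifier=ClassifierKind.KNN),
                          knn_grid=(1, 3, 5))
        assert out.table.shape == (3, 2)
        lda = grid_search({10: fm, 17: fm}, EvalConfig(classifier=ClassifierKind.LDA))
        assert lda.table.shape == (1, 2)

    def test_generator_matched_order_beats_overlong_reconstruction(self):
        # tremor sits above the first 17 coefficients; reconstructing with 50
        # swallows part of it into the approximation, weakening the residue
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            samples, _ = generate_cohort(CohortSpec(n_et=8, n_control=8, seed=4000 + seed))
            accs = {}
            for L in (17, 50):
                fm = feature_matrix_from_samples(samples, Method.RESIDUE, L)
                cfg = EvalConfig(classifier=ClassifierKind.LDA,
                                 selection_mode=SelectionMode.RELIEFF_GLOBAL,
                                 n_features=5, relieff_neighbors=5)
                accs[L] = loocv(fm, cfg).accuracy
            wins += accs[17] >= accs[50]
        assert wins >= 0.7 * n_seeds


class TestCombinedFeatures:
    def test_zero_radius_features_returns_residue_columns(self, small_cohort_residue_fm, small_cohort_radius_fm):
        out = combine_feature_sets(small_cohort_residue_fm, small_cohort_radius_fm,
                                   radius_features=())
        assert out.n_features == 5
        assert out.feature_names == ["MNF_residue", "WAMP_residue", "MAV_residue",
                                     "MFL_residue", "FD_residue"]

    def test_study_combined_set_has_seven_columns(self, small_cohort_residue_fm, small_cohort_radius_fm):
        out = combine_feature_sets(small_cohort_residue_fm, small_cohort_radius_fm)
        assert out.n_features == 7
        assert out.feature_names[-2:] == ["MFL_radius", "FD_radius"]

    def test_mismatched_samples_rejected(self, small_cohort_residue_fm, small_cohort_radius_fm):
        bad = FeatureMatrix(
            small_cohort_radius_fm.values[:-1],
            small_cohort_radius_fm.feature_names,
            small_cohort_radius_fm.labels[:-1],
            small_cohort_radius_fm.subject_ids[:-1],
        )
        with pytest.raises(ValueError):
            combine_feature_sets(small_cohort_residue_fm, bad)
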