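"""MPr model fitting, threshold choice, metrics, and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from oracles import oracle_auc, oracle_bacc, oracle_best_threshold_bacc

from memprop import (MPrModel, balanced_accuracy, choose_threshold, fit_mpr,
                     loo_cross_validate, make_regression_instance, predict_mpr,
                     roc_auc, train_model)
from memprop.energy import EnergyFeatureMatrix
from memprop.errors import DegenerateFitError, ManifestError, MempropError


def _features_from_matrix(X, columns):
    index = pd.MultiIndex.from_arrays(
        [np.full(len(X), "A"), np.arange(1, len(X) + 1),
         np.full(len(X), "")], names=["chain", "resnum", "icode"])
    df = pd.DataFrame(X, columns=columns, index=index)
    return EnergyFeatureMatrix(features=df, aa=["ALA"] * len(X),
                               beta=0.0, gamma=0.0, config_hash="")


class TestFit:
    def test_noiseless_recovery(self):
        feats, O, alpha, aN = make_regression_instance(
            2000, noise_sd=0.0, seed=1, clip=False)
        model = fit_mpr(feats, O)
        np.testing.assert_allclose(model.coef, alpha, atol=1e-8)
        assert model.intercept == pytest.approx(aN, abs=1e-8)

    def test_noisy_recovery_within_three_standard_errors(self):
        n = 10_000
        feats, O, alpha, aN = make_regression_instance(
            n, noise_sd=0.1, seed=2, clip=False)
        model = fit_mpr(feats, O)
        se = 0.1 / np.sqrt(n)  # orthonormal-design standard error per coef
        assert (np.abs(model.coef - alpha) < 3 * se + 3 * se).all()

    def test_all_zero_features_give_intercept_only(self):
        cols = ["ss.TM", "ss.EM", "logL"]
        X = np.zeros((50, 3))
        feats = _features_from_matrix(X, cols)
        O = np.array([1.0] * 20 + [0.0] * 30)
        model = fit_mpr(feats, O)
        assert (model.coef == 0).all()
        assert model.intercept == pytest.approx(O.mean())

    def test_single_label_training_rejected(self):
        feats, O, *_ = make_regression_instance(100, seed=3)
        with pytest.raises(DegenerateFitError):
            fit_mpr(feats, np.ones(100))


class TestPredict:
    def _model(self, cols, coef, intercept):
        return MPrModel(column_order=cols, coef=np.asarray(coef, float),
                        intercept=intercept, beta=0.0, gamma=0.0,
                        phi0=0.5, sigma_TM=0.2, sigma_EM=0.2)

    def test_intercept_only(self):
        cols = ["ss.TM", "ss.EM", "logL"]
        feats = _features_from_matrix(np.zeros((7, 3)), cols)
        model = self._model(cols, [0, 0, 0], 0.3)
        prof = predict_mpr(model, feats)
        np.testing.assert_allclose(prof.table["mpr"], 0.3)

    def test_length_term(self):
        cols = ["ss.TM", "ss.EM", "logL"]
        X = np.zeros((4, 3))
        X[:, 2] = 1.0  # ln L = 1, i.e. L = e
        feats = _features_from_matrix(X, cols)
        model = self._model(cols, [0, 0, 1.0], 0.0)
        prof = predict_mpr(model, feats)
        np.testing.assert_allclose(prof.table["mpr"], 1.0)

    def test_label_rule(self):
        cols = ["x.TM", "x.EM", "logL"]
        X = np.zeros((3, 3))
        X[:, 0] = [0.2, 0.5, 0.9]
        feats = _features_from_matrix(X, cols)
        model = self._model(cols, [1.0, 0, 0], 0.0)
        prof = predict_mpr(model, feats)
        assert list(prof.table["label"]) == ["EM", "TM", "TM"]  # >= phi0

    def test_column_mismatch_raises(self):
        cols = ["ss.TM", "ss.EM", "logL"]
        feats = _features_from_matrix(np.zeros((3, 3)),
                                      ["sd.TM", "sd.EM", "logL"])
        model = self._model(cols, [0, 0, 0], 0.0)
        with pytest.raises(ManifestError):
            model.scores(feats)

    def test_serialization_round_trip_bit_identical(self, tmp_path):
        feats, O, *_ = make_regression_instance(500, noise_sd=0.05, seed=4)
        model = fit_mpr(feats, O)
        model.save(tmp_path / "model")
        loaded = MPrModel.load(tmp_path / "model")
        assert (loaded.coef == model.coef).all()
        assert loaded.intercept == model.intercept
        assert loaded.phi0 == model.phi0
        a = predict_mpr(model, feats).table["mpr"]
        b = predict_mpr(loaded, feats).table["mpr"]
        assert (a == b).all()


class TestThreshold:
    def test_separable_case_returns_midpoint(self):
        phi0 = choose_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert phi0 == pytest.approx(0.5)

    def test_interleaved_scores_bacc_half(self):
        scores = [0.1, 0.2, 0.3, 0.4]
        labels = [1, 0, 1, 0]
        phi0 = choose_threshold(scores, labels)
        pred = (np.asarray(scores) >= phi0).astype(int)
        assert balanced_accuracy(pred, labels) == pytest.approx(0.5)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            scores = rng.normal(size=200)
            labels = rng.integers(0, 2, 200)
            if len(np.unique(labels)) < 2:
                continue
            phi0 = choose_threshold(scores, labels)
            pred = (scores >= phi0).astype(int)
            assert oracle_bacc(pred, labels) == pytest.approx(
                oracle_best_threshold_bacc(scores, labels), abs=1e-12)

    def test_beats_any_user_threshold(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=150)
        labels = (scores + rng.normal(size=150) > 0).astype(int)
        phi0 = choose_threshold(scores, labels)
        best = balanced_accuracy((scores >= phi0).astype(int), labels)
        for thr in rng.normal(size=25):
            other = balanced_accuracy((scores >= thr).astype(int), labels)
            assert best >= other - 1e-12

    def test_single_label_rejected(self):
        with pytest.raises(DegenerateFitError):
            choose_threshold([0.1, 0.2], [1, 1])


class TestMetrics:
    def test_perfect_prediction(self):
        assert balanced_accuracy([1, 0, 1], [1, 0, 1]) == 1.0

    def test_arithmetic(self):
        # sensitivity 0.8 (4/5 TM right), specificity 0.6 (3/5 EM right)
        truth = [1] * 5 + [0] * 5
        pred = [1, 1, 1, 1, 0] + [0, 0, 0, 1, 1]
        assert balanced_accuracy(pred, truth) == pytest.approx(0.7)

    def test_matches_confusion_recount(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            truth = rng.integers(0, 2, 100)
            pred = rng.integers(0, 2, 100)
            if len(np.unique(truth)) < 2:
                continue
            assert balanced_accuracy(pred, truth) == pytest.approx(
                oracle_bacc(pred, truth), abs=1e-12)

    def test_bacc_permutation_invariant(self):
        rng = np.random.default_rng(19)
        truth = rng.integers(0, 2, 80)
        pred = rng.integers(0, 2, 80)
        perm = rng.permutation(80)
        assert balanced_accuracy(pred, truth) == pytest.approx(
            balanced_accuracy(pred[perm], truth[perm]), abs=1e-12)

    def test_auc_separated_and_ties(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_auc_matches_pair_counting(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            scores = np.round(rng.normal(size=50), 1)  # force some ties
            labels = rng.integers(0, 2, 50)
            if len(np.unique(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                oracle_auc(scores, labels), abs=1e-12)

    def test_auc_monotone_transform_invariant(self):
        rng = np.random.default_rng(29)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(2.0 * scores) + 5.0, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_metric_errors(self):
        with pytest.raises(MempropError):
            balanced_accuracy([], [])
        with pytest.raises(DegenerateFitError):
            balanced_accuracy([1, 0], [1, 1])
        with pytest.raises(DegenerateFitError):
            roc_auc([0.1, 0.9], [0, 0])


class TestOLSOptimality:
    def test_local_optimum(self):
        """Perturbing any fitted coefficient never decreases the cost."""
        feats, O, *_ = make_regression_instance(400, noise_sd=0.2, seed=31)
        model = fit_mpr(feats, O)
        X = feats.features.to_numpy()
        base = ((X @ model.coef + model.intercept - O) ** 2).sum()
        for k in range(len(model.coef)):
            for eps in (1e-3, -1e-3):
                coef = model.coef.copy()
                coef[k] += eps
                cost = ((X @ coef + model.intercept - O) ** 2).sum()
                assert cost >= base - 1e-9

    def test_affine_feature_shift_leaves_scores_invariant(self):
        feats, O, *_ = make_regression_instance(300, noise_sd=0.1, seed=37)
        m1 = fit_mpr(feats, O)
        s1 = m1.scores(feats)
        shifted = feats.features.copy()
        shifted["sd.TM"] = shifted["sd.TM"] + 7.5
        feats2 = EnergyFeatureMatrix(features=shifted, aa=feats.aa,
                                     beta=0, gamma=0, config_hash="")
        m2 = fit_mpr(feats2, O)
        s2 = m2.scores(feats2)
        np.testing.assert_allclose(s1, s2, atol=1e-8)


class TestCrossValidation:
    def test_needs_three_proteins(self, small_dataset):
        with pytest.raises(MempropError):
            loo_cross_validate(small_dataset[:2])

    def test_identical_proteins_fold_suites(self, small_dataset, config):
        """With 3 copies of one protein, each fold's suite is the 2-copy suite."""
        from memprop import build_potential_suite
        desc, labels = small_dataset[0]
        triple = [(desc, labels)] * 3
        report = loo_cross_validate(triple, config, grid=[0.0])
        assert len(report.folds) == 3
        ref = build_potential_suite([(desc, labels)] * 2, config.combos, config)
        # the pooled predictions are well-defined and identical across folds
        per = report.per_residue
        first = per[per.structure_id == per.structure_id.iloc[0]]["mpr"]
        for sid in per.structure_id.unique():
            np.testing.assert_allclose(
                per[per.structure_id == sid]["mpr"].to_numpy(),
                first.to_numpy(), atol=1e-12)

    def test_fold_equivalence(self, small_dataset, config):
        """Manually excluding a protein reproduces its fold bit-exactly."""
        from memprop.energy import feature_matrix_from_profiles, raw_profiles
        from memprop.model import _all_counts, _grid_fit, _sum_counts, \
            _suite_from_counts
        grid = [0.0, 0.5]
        report = loo_cross_validate(small_dataset, config, grid=grid)
        held = small_dataset[1][0].structure_id
        train = [p for p in small_dataset if p[0].structure_id != held]
        counts = _all_counts(train, config)
        suite = _suite_from_counts(_sum_counts(counts), config, [])
        model, (beta, gamma) = _grid_fit(train, suite, grid)
        desc = small_dataset[1][0]
        feats = feature_matrix_from_profiles(
            desc, raw_profiles(desc, suite), suite.combos, beta, gamma,
            config.hash())
        manual = model.scores(feats)
        from_report = report.per_residue[
            report.per_residue.structure_id == held]["mpr"].to_numpy()
        assert (manual == from_report).all()

    def test_train_model_round_trip(self, small_dataset, tmp_path, config):
        trained = train_model(small_dataset, config, grid=[0.0, 0.5])
        trained.save(tmp_path / "archive")
        loaded = type(trained).load(tmp_path / "archive")
        prof_a = trained.score_structure(small_dataset[0][0])
        prof_b = loaded.score_structure(small_dataset[0][0])
        assert (prof_a.table["mpr"] == prof_b.table["mpr"]).all()
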