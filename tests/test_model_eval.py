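"""Feature assembly, SVM training, cross-validation and metrics."""

import numpy as np
import pytest

from spliceid import (
    DomainVocabulary,
    EncodingError,
    EvalMetrics,
    FeatureConfig,
    PssmSource,
    SelectionResult,
    ValidationError,
    assemble_features,
    evaluate,
    grid_search,
    kfold_cv,
    load_bundle,
    predict,
    save_bundle,
    train_svm,
)
from spliceid.alphabet import DIPEPTIDES
from spliceid.model_eval import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, encode_record
from spliceid.synthetic import SyntheticSpec, generate_dataset, generate_pssms
from tests.conftest import make_record


def separable_blobs(n=10, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0.0, 0.3, size=(n, 2)), rng.normal(5.0, 0.3, size=(n, 2))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_pos=30, n_neg=60, length_range=(60, 120), seed=7)
    pos, neg = generate_dataset(spec)
    return pos, neg, spec


class TestEvalMetrics:
    def test_worked_confusion_case(self):
        m = EvalMetrics(tp=50, fn=15, tn=90, fp=10)
        assert m.sensitivity == pytest.approx(76.92, abs=0.005)
        assert m.specificity == pytest.approx(90.00, abs=0.005)
        assert m.accuracy == pytest.approx(84.85, abs=0.005)

    def test_perfect_predictions(self):
        m = EvalMetrics.from_predictions(np.array([0, 1, 1]), np.array([0, 1, 1]))
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_all_negative_predictor_on_balanced_data(self):
        y = np.array([0] * 10 + [1] * 10)
        m = EvalMetrics.from_predictions(y, np.zeros(20))
        assert m.sensitivity == 0.0
        assert m.specificity == 100.0
        assert m.accuracy == 50.0

    def test_identities_recomputable_from_confusion(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = EvalMetrics(int(tp), int(tn), int(fp), int(fn))
            assert m.sensitivity == pytest.approx(100 * tp / (tp + fn))
            assert m.specificity == pytest.approx(100 * tn / (tn + fp))
            assert m.accuracy == pytest.approx(
                100 * (tp + tn) / (tp + tn + fp + fn)
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            EvalMetrics(tp=-1, tn=0, fp=0, fn=0)


class TestAssembleFeatures:
    def test_block_widths(self, small_dataset):
        pos, neg, spec = small_dataset
        records = pos + neg
        X, y = assemble_features(records, FeatureConfig(blocks=("aac",)))
        assert X.shape == (90, 20)
        assert y.sum() == 30
        X, _ = assemble_features(records, FeatureConfig(blocks=("dpc",)))
        assert X.shape == (90, 400)

    def test_hybrid_width_is_sum_of_blocks(self, small_dataset):
        pos, neg, spec = small_dataset
        selection = SelectionResult(selected=tuple(DIPEPTIDES[:64]), alpha=0.05, stats=())
        vocab = DomainVocabulary(
            entries=tuple((f"IPR{i:06d}", 10) for i in range(15)),
            min_support_exclusive=5,
        )
        pssms = generate_pssms(pos + neg, noise=1.0, seed=spec.seed)
        config = FeatureConfig(
            blocks=("sig_dpc", "pssm", "domain"),
            selection=selection,
            vocabulary=vocab,
            pssms=PssmSource.from_mapping(pssms),
        )
        assert config.width == 64 + 400 + 15 == 479
        X, _ = assemble_features(pos + neg, config)
        assert X.shape == (90, 479)

    def test_block_order_is_canonical_regardless_of_input_order(self):
        config = FeatureConfig(blocks=("dpc", "aac"))
        assert config.blocks == ("aac", "dpc")

    def test_missing_pssm_names_the_record(self, small_dataset):
        pos, neg, _ = small_dataset
        config = FeatureConfig(
            blocks=("pssm",), pssms=PssmSource.from_mapping({})
        )
        with pytest.raises(EncodingError, match=pos[0].id):
            assemble_features([pos[0]], config)

    def test_unlabelled_records_rejected_when_labels_required(self):
        rec = make_record("ACDE", label="unknown")
        with pytest.raises(ValidationError):
            assemble_features([rec], FeatureConfig(blocks=("aac",)))

    def test_config_requires_resources_for_active_blocks(self):
        with pytest.raises(ValidationError):
            FeatureConfig(blocks=("sig_dpc",))
        with pytest.raises(ValidationError):
            FeatureConfig(blocks=("domain",))
        with pytest.raises(ValidationError):
            FeatureConfig(blocks=())


class TestTrainSvm:
    def test_separable_clusters_reach_training_accuracy_100(self):
        X, y = separable_blobs()
        bundle = train_svm(X, y, C=1.0, gamma=0.5, seed=0)
        assert (bundle.svc.predict(X) == y).all()

    def test_single_class_labels_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValidationError):
            train_svm(X, np.zeros(5), C=1.0, gamma=0.5)

    @pytest.mark.parametrize("C,gamma", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_nonpositive_parameters_rejected(self, C, gamma):
        X, y = separable_blobs()
        with pytest.raises(ValidationError):
            train_svm(X, y, C=C, gamma=gamma)

    def test_width_inconsistent_with_config_rejected(self):
        X, y = separable_blobs()
        with pytest.raises(ValidationError):
            train_svm(X, y, C=1.0, gamma=0.5, config=FeatureConfig(blocks=("aac",)))

    def test_retraining_is_deterministic(self):
        X, y = separable_blobs(seed=3)
        probe = np.random.default_rng(9).normal(2.5, 2.0, size=(30, 2))
        a = train_svm(X, y, C=2.0, gamma=0.25, seed=1)
        b = train_svm(X, y, C=2.0, gamma=0.25, seed=1)
        assert np.array_equal(a.svc.predict(probe), b.svc.predict(probe))
        assert a.svc.decision_function(probe) == pytest.approx(
            b.svc.decision_function(probe)
        )


class TestKFoldCV:
    def test_folds_partition_the_data(self):
        X, y = separable_blobs(n=50, seed=1)
        result = kfold_cv(X, y, C=1.0, gamma=0.5, k=5, seed=2)
        assert len(result.folds) == 5
        counts = np.bincount(result.fold_assignment)
        assert (counts == 20).all()  # n=100 balanced, five folds of 20
        assert (result.fold_assignment >= 0).all()

    def test_stratification_within_one_sample(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(110, 3))
        y = np.array([1] * 30 + [0] * 80)
        result = kfold_cv(X, y, C=1.0, gamma=0.5, k=5, seed=0)
        for fold in range(5):
            fold_pos = int(y[result.fold_assignment == fold].sum())
            assert abs(fold_pos - 6) <= 1

    def test_pooled_equals_sum_of_fold_confusions(self):
        X, y = separable_blobs(n=25, seed=4)
        result = kfold_cv(X, y, C=1.0, gamma=0.5, k=5, seed=0)
        total = np.array([(m.tp, m.tn, m.fp, m.fn) for m in result.folds]).sum(axis=0)
        pooled = (result.pooled.tp, result.pooled.tn, result.pooled.fp, result.pooled.fn)
        assert tuple(total) == pooled

    def test_separable_data_has_pooled_accuracy_100(self):
        X, y = separable_blobs(n=25, seed=4)
        result = kfold_cv(X, y, C=4.0, gamma=0.5, k=5, seed=0)
        assert result.pooled.accuracy == 100.0

    def test_class_smaller_than_k_rejected(self):
        X, y = separable_blobs(n=3)
        with pytest.raises(ValidationError):
            kfold_cv(X, y, C=1.0, gamma=0.5, k=5, seed=0)
        with pytest.raises(ValidationError):
            kfold_cv(X, y, C=1.0, gamma=0.5, k=1, seed=0)


class TestGridSearch:
    def test_single_point_grid_returns_that_point(self):
        X, y = separable_blobs(n=20, seed=5)
        result = grid_search(X, y, C_grid=[2.0], gamma_grid=[0.125], seed=0)
        assert (result.best_C, result.best_gamma) == (2.0, 0.125)

    def test_duplicate_grid_values_equivalent_to_deduplicated(self):
        X, y = separable_blobs(n=20, seed=5)
        a = grid_search(X, y, C_grid=[1.0, 1.0, 4.0], gamma_grid=[0.5, 0.5], seed=0)
        b = grid_search(X, y, C_grid=[1.0, 4.0], gamma_grid=[0.5], seed=0)
        assert (a.best_C, a.best_gamma) == (b.best_C, b.best_gamma)
        assert a.cv.pooled == b.cv.pooled

    def test_separable_data_with_adequate_grid_reaches_100(self):
        X, y = separable_blobs(n=25, seed=6)
        result = grid_search(X, y, C_grid=[0.03125, 4.0], gamma_grid=[0.5], seed=0)
        assert result.cv.pooled.accuracy == 100.0

    def test_ties_break_to_smaller_C_then_gamma(self):
        X, y = separable_blobs(n=25, seed=6)
        result = grid_search(
            X, y, C_grid=[4.0, 16.0], gamma_grid=[0.25, 0.5], seed=0
        )
        accs = {(C, g): acc for C, g, acc in result.table}
        best_acc = max(accs.values())
        ties = sorted(key for key, acc in accs.items() if acc == best_acc)
        assert (result.best_C, result.best_gamma) == ties[0]

    def test_same_seed_reproduces_winner_and_folds(self):
        X, y = separable_blobs(n=30, seed=8)
        a = grid_search(X, y, C_grid=[1.0, 8.0], gamma_grid=[0.1, 1.0], seed=5)
        b = grid_search(X, y, C_grid=[1.0, 8.0], gamma_grid=[0.1, 1.0], seed=5)
        assert (a.best_C, a.best_gamma) == (b.best_C, b.best_gamma)
        assert np.array_equal(a.cv.fold_assignment, b.cv.fold_assignment)
        assert a.table == b.table

    def test_empty_grid_rejected(self):
        X, y = separable_blobs()
        with pytest.raises(ValidationError):
            grid_search(X, y, C_grid=[], gamma_grid=[0.5], seed=0)

    def test_default_grids_follow_powers_of_two(self):
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**15
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-15 and DEFAULT_GAMMA_GRID[-1] == 2.0**3


class TestEvaluatePredict:
    @pytest.fixture()
    def trained(self, small_dataset):
        pos, neg, _ = small_dataset
        config = FeatureConfig(blocks=("aac",))
        X, y = assemble_features(pos + neg, config)
        return train_svm(X, y, C=8.0, gamma=8.0, seed=0, config=config), pos, neg

    def test_evaluate_returns_consistent_metrics(self, trained):
        bundle, pos, neg = trained
        m = evaluate(bundle, pos + neg)
        assert m.tp + m.tn + m.fp + m.fn == len(pos) + len(neg)
        assert m.accuracy == pytest.approx(
            100 * (m.tp + m.tn) / (len(pos) + len(neg))
        )

    def test_predict_on_training_points_of_separable_fit(self, trained):
        bundle, pos, neg = trained
        preds = predict(bundle, pos + neg)
        assert len(preds) == len(pos) + len(neg)
        assert all(p.label in ("positive", "negative") for p in preds)
        assert all(p.score is not None for p in preds)

    def test_predict_empty_list(self, trained):
        bundle, _, _ = trained
        assert predict(bundle, []) == []

    def test_record_missing_pssm_marked_failed_others_predicted(self, small_dataset):
        pos, neg, spec = small_dataset
        records = pos[:5] + neg[:5]
        pssms = generate_pssms(records[1:], noise=1.0, seed=3)
        config = FeatureConfig(blocks=("pssm",), pssms=PssmSource.from_mapping(pssms))
        X = np.stack([encode_record(r, config) for r in records[1:]])
        y = np.array([1 if r.label == "positive" else 0 for r in records[1:]])
        bundle = train_svm(X, y, C=1.0, gamma=0.1, seed=0, config=config)
        preds = predict(bundle, records)
        assert preds[0].failed and records[0].id in preds[0].error
        assert all(not p.failed for p in preds[1:])

    def test_bundle_round_trip(self, trained, tmp_path):
        bundle, pos, neg = trained
        path = tmp_path / "model.bundle"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        a = predict(bundle, pos[:5])
        b = predict(loaded, pos[:5])
        assert [(p.id, p.label) for p in a] == [(p.id, p.label) for p in b]
        assert [p.score for p in a] == pytest.approx([p.score for p in b])
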