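import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from pulseaf.errors import ParameterError, StratificationError
from pulseaf.model_eval import (
    ConfusionCounts,
    ConvNetAFClassifier,
    ModelSpec,
    TrainConfig,
    build_model,
    compute_auc,
    compute_metrics,
    evaluate,
    finetune,
    load_model,
    save_model,
    train_cv,
)


def _separable(n, rng, gap=3.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, 12)), rng.normal(gap, 1, (n // 2, 12))])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return X, y


class TestMetrics:
    def test_worked_example_counts(self):
        # 42 of 54 AF correct, 170 of 192 NSR correct
        rep = compute_metrics(ConfusionCounts(tp=42, fp=22, fn=12, tn=170))
        assert rep.sensitivity == pytest.approx(100 * 42 / 54)
        assert round(rep.sensitivity, 2) == 77.78
        assert round(rep.specificity, 2) == 88.54
        assert round(rep.accuracy, 2) == 86.18
        assert round(rep.f1, 2) == 71.19

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=50, fp=0, fn=0, tn=50))
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.f1) == (
            100.0, 100.0, 100.0, 100.0,
        )

    def test_zero_denominator_flags_not_crashes(self):
        rep = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert np.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined

    def test_identities_against_per_instance_counting(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            p = rng.integers(0, 2, 50)
            counts = ConfusionCounts.from_predictions(y, p)
            # brute-force per-instance tally
            tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
            fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
            assert (counts.tp, counts.fn) == (tp, fn)
            rep = compute_metrics(counts)
            if tp + fn:
                assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
            assert rep.accuracy == pytest.approx(100 * np.mean(y == p))

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)


class TestAUC:
    def test_perfect_ordering(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert compute_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pairwise_hand_example(self):
        # 4 positive-negative pairs, 3 correctly ordered -> 0.75
        assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_monotone_transform_invariance(self, rng):
        s = rng.standard_normal(100)
        y = rng.integers(0, 2, 100)
        if y.sum() in (0, 100):
            y[0] = 1 - y[0]
        assert compute_auc(np.exp(s), y) == pytest.approx(compute_auc(s, y))

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            s = rng.standard_normal(60)
            y = np.r_[np.zeros(30), np.ones(30)].astype(int)
            assert compute_auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_flagged(self):
        with pytest.raises(StratificationError):
            compute_auc([0.1, 0.9], [1, 1])


class TestModelConstruction:
    def test_output_is_probability(self, rng):
        clf = build_model(ModelSpec(), seed=0)
        p = clf.predict_proba(rng.standard_normal((5, 12)))
        assert p.shape == (5, 2)
        assert np.all((p > 0) & (p < 1))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_same_seed_identical_initial_weights(self):
        w1 = build_model(ModelSpec(), seed=3).network_.get_weights()
        w2 = build_model(ModelSpec(), seed=3).network_.get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_zero_input_finite(self):
        clf = build_model(ModelSpec(), seed=1)
        p = clf.predict_proba(np.zeros((1, 12)))
        assert np.all(np.isfinite(p))

    def test_layer_shapes(self):
        # 12 -> (4 conv blocks, same padding) 12 -> pool 6 -> flatten 192 -> 8 -> 1
        clf = build_model(ModelSpec(), seed=0)
        x = np.zeros((2, 12, 1))
        net = clf.network_
        shapes = []
        for layer in net.layers:
            x = layer.forward(x, training=False)
            shapes.append(x.shape)
        assert shapes[-4] == (2, 192)  # flatten output
        assert shapes[-3] == (2, 8)    # hidden dense
        assert shapes[-1] == (2, 1)
        # conv blocks keep length 12; pooling halves it to 6
        assert shapes[0] == (2, 12, 256)
        assert shapes[-5] == (2, 6, 32)

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ParameterError):
            ConvNetAFClassifier().initialize(2)

    def test_sklearn_clone_compatible(self):
        clf = ConvNetAFClassifier(epochs=3, random_state=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


class TestTraining:
    def test_separable_gaussians_high_holdout_accuracy(self, rng):
        X, y = _separable(400, rng)
        res = train_cv(X, y, TrainConfig(epochs=10, seed=1))
        assert res.holdout_report.accuracy >= 95.0
        assert len(res.fold_reports) == 5

    def test_shuffled_labels_chance_level(self, rng):
        X, y = _separable(400, rng)
        y_shuf = rng.permutation(y)
        res = train_cv(X, y_shuf, TrainConfig(epochs=5, seed=2))
        assert 40.0 <= res.holdout_report.accuracy <= 60.0

    def test_reproducible_fold_metrics(self, rng):
        X, y = _separable(120, rng)
        cfg = TrainConfig(epochs=3, seed=5)
        r1 = train_cv(X, y, cfg)
        r2 = train_cv(X, y, cfg)
        for a, b in zip(r1.fold_reports, r2.fold_reports):
            assert a.to_dict() == b.to_dict()

    def test_training_reduces_loss(self, rng):
        X, y = _separable(100, rng)
        clf = ConvNetAFClassifier(epochs=10, random_state=0).fit(X, y)
        assert clf.loss_curve_[-1] < clf.loss_curve_[0]

    def test_invalid_labels_rejected(self, rng):
        X = rng.normal(size=(10, 12))
        with pytest.raises(ParameterError):
            ConvNetAFClassifier(epochs=1).fit(X, np.arange(10))


class TestFinetune:
    def test_zero_epoch_finetune_is_noop(self, rng):
        X, y = _separable(120, rng)
        clf = ConvNetAFClassifier(epochs=5, random_state=0).fit(X, y)
        cfg = TrainConfig(seed=3, finetune_epochs=0)
        res = finetune(clf, X, y, cfg, scaler_policy="none")
        base = evaluate(clf, X, y)
        assert res.pooled_report.to_dict() == base.to_dict()

    def test_finetune_adapts_to_shift(self, rng):
        X, y = _separable(200, rng)
        clf = ConvNetAFClassifier(epochs=10, random_state=0).fit(X, y)
        # shifted cohort: offset feature means degrade the frozen model
        Xs, ys = _separable(160, rng)
        Xs = Xs + 4.0
        pre = evaluate(clf, Xs, ys)
        res = finetune(clf, Xs, ys, TrainConfig(seed=1, finetune_epochs=10),
                       scaler_policy="refit")
        assert res.pooled_report.accuracy >= pre.accuracy
        assert len(res.fold_reports) == 4

    def test_too_few_minority_samples(self, rng):
        X, _ = _separable(20, rng)
        y = np.array([1] * 2 + [0] * 18)
        clf = ConvNetAFClassifier(epochs=1, random_state=0).fit(X[:10], y[:10] * 0)
        with pytest.raises(StratificationError):
            finetune(clf, X, y, TrainConfig(finetune_folds=4))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = _separable(80, rng)
        res = train_cv(X, y, TrainConfig(epochs=3, seed=0))
        save_model(tmp_path / "m", res.model, res.scaler)
        model, scaler = load_model(tmp_path / "m")
        Xs = res.scaler.transform(X)
        np.testing.assert_allclose(
            model.predict_proba(scaler.transform(X)),
            res.model.predict_proba(Xs),
            atol=1e-12,
        )
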