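"""Loss, confusion counts, metric arithmetic, AUC and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caafenet.network import build_variant, count_parameters
from caafenet.synthetic import SynthConfig, generate_arrays
from caafenet.train_eval import (
    ConfusionCounts,
    TrainConfig,
    compute_metrics,
    confusion_from_predictions,
    f1_score,
    nll_from_log_probs,
    nll_gradient,
    roc_auc,
    run_ablation,
    train_model,
)


class TestNLL:
    def test_confident_correct_predictions_give_near_zero_loss(self):
        logp = np.log(np.array([[1 - 1e-9, 1e-9], [1e-9, 1 - 1e-9]]))
        assert nll_from_log_probs(logp, [0, 1]) < 1e-6

    def test_uniform_two_class_loss_is_log_two(self):
        logp = np.full((4, 2), -np.log(2))
        np.testing.assert_allclose(nll_from_log_probs(logp, [0, 1, 0, 1]),
                                   np.log(2))

    def test_three_sample_batch_matches_scalar_oracle(self, rng):
        logits = rng.normal(size=(3, 4))
        logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
        labels = [2, 0, 3]
        expected = -(logp[0, 2] + logp[1, 0] + logp[2, 3]) / 3.0
        np.testing.assert_allclose(nll_from_log_probs(logp, labels),
                                   expected, atol=1e-12)

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            nll_from_log_probs(np.zeros((2, 2)), [0, 2])

    def test_gradient_is_minus_one_over_n_at_truth(self):
        g = nll_gradient(np.zeros((4, 2)), [0, 1, 1, 0])
        assert g[0, 0] == -0.25 and g[1, 1] == -0.25
        assert g.sum() == -1.0


class TestConfusion:
    def test_perfect_predictions(self):
        truth = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        c = confusion_from_predictions(truth, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (4, 6, 0, 0)

    def test_all_positive_classifier(self):
        truth = [1] * 7 + [0] * 3
        c = confusion_from_predictions([1] * 10, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (7, 3, 0, 0)

    def test_random_fixture_matches_pairwise_counter(self, rng):
        pred = rng.integers(0, 2, 50)
        truth = rng.integers(0, 2, 50)
        c = confusion_from_predictions(pred, truth)
        tp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 1)
        tn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 0)
        fp = sum(1 for p, t in zip(pred, truth) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(pred, truth) if p == 0 and t == 1)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_from_predictions([1, 0], [1])


class TestMetrics:
    @pytest.mark.parametrize("precision,recall,f1", [
        (93.51, 96.84, 95.15),   # strongest classifier row
        (68.38, 100.0, 81.22),   # degenerate all-positive rows
        (70.94, 98.42, 82.45),
        (90.44, 97.23, 93.71),
        (89.71, 96.44, 92.95),
        (90.00, 92.49, 91.23),
    ])
    def test_harmonic_mean_reproduces_published_f1(self, precision, recall,
                                                   f1):
        assert round(f1_score(precision, recall), 2) == f1

    def test_counts_fixture(self):
        report = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        np.testing.assert_allclose(report.accuracy, 70.0)
        np.testing.assert_allclose(report.precision, 75.0)
        np.testing.assert_allclose(report.recall, 60.0)
        np.testing.assert_allclose(report.f1, 200.0 / 3.0)

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_zero_denominator_flags_degenerate(self):
        report = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert report.degenerate
        assert report.precision == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 50))
    def test_metric_identities(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        c = ConfusionCounts(tp, tn, fp, fn)
        report = compute_metrics(c)
        # F1 from (P, R) equals F1 from counts directly
        if 2 * tp + fp + fn > 0:
            direct = 100.0 * 2 * tp / (2 * tp + fp + fn)
            np.testing.assert_allclose(report.f1, direct, atol=1e-9)
        # accuracy invariant under swapping the positive class
        swapped = compute_metrics(ConfusionCounts(tn, tp, fn, fp))
        np.testing.assert_allclose(report.accuracy, swapped.accuracy)
        # F1 between min and max of (P, R)
        lo = min(report.precision, report.recall)
        hi = max(report.precision, report.recall)
        assert lo - 1e-9 <= report.f1 <= hi + 1e-9

    def test_all_positive_precision_equals_prevalence(self, rng):
        truth = rng.integers(0, 2, 200)
        while len(np.unique(truth)) < 2:
            truth = rng.integers(0, 2, 200)
        report = compute_metrics(
            confusion_from_predictions(np.ones_like(truth), truth))
        assert report.recall == 100.0
        np.testing.assert_allclose(report.precision, 100.0 * truth.mean())
        np.testing.assert_allclose(report.accuracy, report.precision)


def _pair_count_auc(scores, labels):
    scores = np.asarray(scores)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_label_independent_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_tied_fixture_matches_pair_counting_oracle(self):
        scores = [0.1, 0.4, 0.4, 0.8, 0.35, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        np.testing.assert_allclose(roc_auc(scores, labels),
                                   _pair_count_auc(scores, labels),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()),
                    min_size=4, max_size=20))
    def test_rank_statistic_equals_pair_counting(self, pairs):
        scores = [round(p[0], 2) for p in pairs]  # induce ties
        labels = [int(p[1]) for p in pairs]
        if len(set(labels)) < 2:
            return
        np.testing.assert_allclose(roc_auc(scores, labels),
                                   _pair_count_auc(scores, labels),
                                   atol=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.random(60), 1)
        labels = rng.integers(0, 2, 60)
        np.testing.assert_allclose(roc_auc(scores, labels),
                                   roc_auc_score(labels, scores), atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            roc_auc([0.5, 0.6], [1, 1])


@pytest.fixture(scope="module")
def tiny_data():
    """In-memory synthetic mini-set at 16x16 grouped by patient."""
    cfg = SynthConfig(n_patients=10, slices_per_patient=2, image_size=16,
                      seed=0)
    images, labels, pids = generate_arrays(cfg)
    unique = sorted(set(pids))
    train_p, val_p, test_p = unique[:-4], unique[-4:-2], unique[-2:]
    idx = {s: [i for i, p in enumerate(pids) if p in group]
           for s, group in (("train", train_p), ("val", val_p),
                            ("test", test_p))}
    return {s: (images[idx[s]], labels[idx[s]]) for s in idx}


class TestTraining:
    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_data):
        model = build_variant("resnet18*", seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if "running" not in k}
        cfg = TrainConfig(lr=0.0, epochs=1, augment=False, seed=0)
        train_model(model, *tiny_data["train"], *tiny_data["val"], cfg)
        after = model.state_dict()
        for key, value in before.items():
            np.testing.assert_array_equal(value, after[key])

    def test_history_length_equals_epochs(self, tiny_data):
        model = build_variant("resnet18*", seed=0)
        cfg = TrainConfig(epochs=2, augment=False, seed=0)
        history = train_model(model, *tiny_data["train"],
                              *tiny_data["val"], cfg)
        assert len(history) == 2
        assert len(history.val_accuracy) == 2
        assert 0 <= history.best_epoch < 2

    def test_epoch_one_loss_reproducible(self, tiny_data):
        losses = []
        for _ in range(2):
            model = build_variant("resnet18*", seed=1)
            cfg = TrainConfig(epochs=1, augment=False, seed=1)
            history = train_model(model, *tiny_data["train"],
                                  *tiny_data["val"], cfg)
            losses.append(history.train_loss[0])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_empty_split_rejected(self, tiny_data):
        model = build_variant("resnet18*", seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train_model(model, np.empty((0, 1, 16, 16)), np.empty(0),
                        *tiny_data["val"], TrainConfig(epochs=1))


class TestAblation:
    def test_report_shape_and_parameter_ordering(self, tiny_data):
        cfg = TrainConfig(epochs=1, augment=False, seed=0)
        table = run_ablation(["resnet18*", "full"], tiny_data, cfg)
        assert list(table["Model"]) == ["ResNet18*", "CAAFE-ResNet18*"]
        assert set(table.columns) >= {"Accuracy (%)", "Precision (%)",
                                      "Recall (%)", "F1 score (%)"}
        counts = dict(zip(table["Model"], table["Parameters"]))
        assert counts["CAAFE-ResNet18*"] > counts["ResNet18*"]
        assert counts["ResNet18*"] == count_parameters(
            build_variant("resnet18*"))

    def test_report_reproducible_across_runs(self, tiny_data):
        cfg = TrainConfig(epochs=1, augment=False, seed=0)
        a = run_ablation(["resnet18*"], tiny_data, cfg)
        b = run_ablation(["resnet18*"], tiny_data, cfg)
        assert a.equals(b)
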