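import numpy as np
import pytest
from scipy.special import logsumexp
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    recall_score,
    roc_auc_score,
)

from surfmae.config import PatchConfig, TrainConfig
from surfmae.nn import Tensor
from surfmae.training import (
    PPIFinetuner,
    Pretrainer,
    balanced_accuracy,
    balanced_cross_entropy,
    binary_cross_entropy_with_logits,
    classification_metrics,
    cross_entropy,
    roc_auc,
    select_best,
)


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_exhaustive_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (
                pos[:, None] == neg[None, :]).sum()
            expected = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestClassificationMetrics:
    def test_confusion_matrix_example(self):
        # TP=2 FP=1 FN=1 TN=6: acc (2+6)/10, recall 2/3, F1 = 2*2/(2*2+1+1)
        labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.2, 0.7, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        m = classification_metrics(scores, labels)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100)
        m = classification_metrics(scores, labels)
        pred = (scores >= 0.5).astype(int)
        assert m["recall"] == pytest.approx(recall_score(labels, pred))
        assert m["f1"] == pytest.approx(f1_score(labels, pred))

    def test_degenerate_all_negative_predictions(self):
        m = classification_metrics([0.1, 0.2, 0.3], [1, 0, 1])
        assert m["recall"] == 0.0 and m["f1"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])


class TestBalancedAccuracy:
    def test_two_class_recalls(self):
        # class 0 recall 1.0 (2/2), class 1 recall 0.5 (1/2)
        assert balanced_accuracy([0, 0, 1, 0], [0, 0, 1, 1], 2) == pytest.approx(0.75)

    def test_uniform_classes_equal_plain_accuracy(self):
        pred = [0, 1, 2, 0, 1, 2]
        labels = [0, 1, 2, 0, 2, 1]
        assert balanced_accuracy(pred, labels, 3) == pytest.approx(np.mean(
            np.array(pred) == np.array(labels)))

    def test_seven_class_diagonal_example(self):
        labels = np.repeat(np.arange(7), 3)
        pred = labels.copy()
        pred[labels == 6] = 0  # class 6 fully missed
        assert balanced_accuracy(pred, labels, 7) == pytest.approx(6 / 7)
        assert balanced_accuracy(pred, labels, 7) == pytest.approx(
            balanced_accuracy_score(labels, pred))

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([0, 0], [0, 0], 2)


class TestBalancedCrossEntropy:
    def test_zero_logits_give_ln2(self):
        logits = Tensor(np.zeros(100))
        labels = np.array([1] * 10 + [0] * 90)
        loss = balanced_cross_entropy(logits, labels, seed=0)
        assert loss.item() == pytest.approx(np.log(2))

    def test_perfect_separation_near_zero(self):
        labels = np.array([1] * 5 + [0] * 20)
        logits = Tensor(np.where(labels == 1, 30.0, -30.0))
        assert balanced_cross_entropy(logits, labels, seed=0).item() < 1e-3

    def test_balancing_subsamples_majority(self):
        # independent recomputation with the same seeded subsample rule
        rng = np.random.default_rng(0)
        logits_np = rng.normal(size=60)
        labels = np.array([1] * 10 + [0] * 50)
        loss = balanced_cross_entropy(Tensor(logits_np), labels, seed=7).item()
        check_rng = np.random.default_rng(7)
        neg = check_rng.choice(np.flatnonzero(labels == 0), size=10, replace=False)
        idx = np.concatenate([np.flatnonzero(labels == 1), neg])
        z, y = logits_np[idx], labels[idx]
        expected = np.mean(np.logaddexp(0, z) - z * y)
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_cross_entropy(Tensor(np.zeros(4)), [1, 1, 1, 1], seed=0)

    def test_bce_with_logits_stable_for_large_inputs(self):
        logits = Tensor(np.array([800.0, -800.0]))
        loss = binary_cross_entropy_with_logits(logits, np.array([1.0, 0.0]))
        assert loss.item() == pytest.approx(0.0, abs=1e-12)


class TestCrossEntropy:
    def test_matches_logsumexp_form(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            z = rng.normal(scale=4, size=7)
            y = int(rng.integers(7))
            expected = logsumexp(z) - z[y]
            assert cross_entropy(Tensor(z), y).item() == pytest.approx(expected)


class TestSelectBest:
    @pytest.mark.parametrize("losses,expected", [
        ([1.0, 0.7, 0.8], 2),
        ([0.5, 0.5], 1),
        ([3.0, 2.0, 1.0], 3),
    ])
    def test_examples(self, losses, expected):
        assert select_best(losses) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


@pytest.fixture(scope="module")
def two_clouds():
    from surfmae.experiments import make_pretrain_clouds

    return make_pretrain_clouds(2, seed=5)


class TestPretrainer:
    def test_loss_curve_bit_reproducible(self, two_clouds, tiny_model_cfg):
        pc = PatchConfig(g=16, k_prime=8, m=0.5)
        tc = TrainConfig(batch_size=1)
        a = Pretrainer(two_clouds, tiny_model_cfg, pc, tc, seed=3).fit(epochs=3)
        b = Pretrainer(two_clouds, tiny_model_cfg, pc, tc, seed=3).fit(epochs=3)
        assert a.loss_curve == b.loss_curve
        assert a.best_epoch == b.best_epoch

    def test_masking_arithmetic_in_patchsets(self, two_clouds, tiny_model_cfg):
        from surfmae.patches import apply_mask

        pc = PatchConfig(g=32, k_prime=8, m=0.6)
        trainer = Pretrainer(two_clouds, tiny_model_cfg, pc, seed=0)
        masked = apply_mask(trainer._patchsets[0], 0.6, seed=0)
        assert masked.n_masked == 19 and masked.n_visible == 13

    def test_empty_dataset_rejected(self, tiny_model_cfg):
        with pytest.raises(ValueError):
            Pretrainer([], tiny_model_cfg, PatchConfig(g=8, k_prime=4, m=0.5))

    def test_mismatched_point_counts_rejected(self, two_clouds, tiny_model_cfg):
        from dataclasses import replace

        shrunk = replace(two_clouds[1], points=two_clouds[1].points[:100],
                         normals=two_clouds[1].normals[:100],
                         curvatures=two_clouds[1].curvatures[:100],
                         chem_raw=two_clouds[1].chem_raw[:100],
                         chem_neighbor_idx=two_clouds[1].chem_neighbor_idx[:100])
        with pytest.raises(ValueError):
            Pretrainer([two_clouds[0], shrunk], tiny_model_cfg,
                       PatchConfig(g=8, k_prime=4, m=0.5))


class TestPPIMechanics:
    def test_self_pair_loss_drops_below_ln2_within_100_steps(self, tiny_model_cfg,
                                                             small_cloud):
        # identical descriptor fields with self-pairs as positives: the scaled
        # dot product separates (i, i) from random (i, j) quickly
        pos = np.stack([np.arange(40), np.arange(40)], axis=1)
        data = [(small_cloud, small_cloud, pos)]
        tuner = PPIFinetuner(data, tiny_model_cfg,
                             PatchConfig(g=16, k_prime=8, m=0.0),
                             TrainConfig(finetune_lr=1e-3), seed=0)
        res = tuner.fit(epochs=100)
        assert min(res.train_losses) < np.log(2)

    def test_negative_positive_ratio_is_one_to_one(self, tiny_model_cfg,
                                                   small_cloud, monkeypatch):
        import surfmae.training as T

        captured = []
        orig = T.binary_cross_entropy_with_logits

        def spy(logits, targets):
            captured.append(np.asarray(targets))
            return orig(logits, targets)

        monkeypatch.setattr(T, "binary_cross_entropy_with_logits", spy)
        pos = np.stack([np.arange(10), np.arange(10)], axis=1)
        tuner = T.PPIFinetuner([(small_cloud, small_cloud, pos)], tiny_model_cfg,
                               PatchConfig(g=16, k_prime=8, m=0.0), seed=0)
        tuner.fit(epochs=2)
        for t in captured:
            assert t.sum() == len(t) / 2

    def test_requires_positive_pairs(self, tiny_model_cfg, small_cloud):
        with pytest.raises(ValueError):
            PPIFinetuner([(small_cloud, small_cloud, np.zeros((0, 2), dtype=int))],
                         tiny_model_cfg, PatchConfig(g=16, k_prime=8, m=0.0))
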