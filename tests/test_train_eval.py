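"""Splitting, schedule, metrics identities, ROC oracle and training sanity."""

import numpy as np
import pytest

from sffnet.model import SFFNet, SFFNetConfig
from sffnet.synthetic import PhantomSpec, iter_cohort
from sffnet.semi_sp import apply_strategy
from sffnet.train_eval import (
    CLASS_ORDER,
    MetricsReport,
    TrainConfig,
    embed_2d,
    evaluate,
    lr_at_epoch,
    majority_vote_report,
    report_from_confusion,
    roc_auc,
    split_lesions,
    train,
)


def concordance_auc(scores, labels):
    """Brute-force Mann-Whitney statistic with half-credit ties."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def test_cohort_shape_conserved(self):
        table = {f"m{i}": "MF-ICC" for i in range(47)}
        table.update({f"h{i}": "HCC" for i in range(69)})
        a = split_lesions(table, (0.6, 0.2, 0.2), seed=4)
        for label, total in (("MF-ICC", 47), ("HCC", 69)):
            per = [
                sum(1 for l, s in a.assignment.items() if s == sp and table[l] == label)
                for sp in ("train", "validation", "test")
            ]
            assert sum(per) == total
            # 6:2:2 allocation within one lesion of the exact quota
            for got, want in zip(per, (0.6 * total, 0.2 * total, 0.2 * total)):
                assert abs(got - want) <= 1.0

    def test_degenerate_ratio_all_train(self):
        table = {f"x{i}": "HCC" for i in range(5)}
        table.update({f"y{i}": "MF-ICC" for i in range(4)})
        a = split_lesions(table, (1.0, 0.0, 0.0), seed=0)
        assert all(v == "train" for v in a.assignment.values())

    def test_same_seed_reproduces(self):
        table = {f"x{i}": ("HCC" if i % 2 else "MF-ICC") for i in range(20)}
        assert split_lesions(table, seed=9).assignment == split_lesions(table, seed=9).assignment

    def test_too_few_lesions_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            split_lesions({"a": "HCC", "b": "HCC", "c": "MF-ICC", "d": "MF-ICC", "e": "MF-ICC"})

    def test_partition_is_disjoint_and_complete(self):
        table = {f"x{i}": ("HCC" if i % 3 else "MF-ICC") for i in range(30)}
        a = split_lesions(table, seed=2)
        assert set(a.assignment) == set(table)
        sets = [set(a.lesions_for(s)) for s in ("train", "validation", "test")]
        assert sets[0] | sets[1] | sets[2] == set(table)
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [(0, 1e-3), (29, 1e-3), (30, 1e-4), (60, 1e-5), (95, 1e-6)])
    def test_step_decay(self, epoch, expected):
        assert lr_at_epoch(epoch, TrainConfig()) == pytest.approx(expected, rel=1e-9)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(-1, TrainConfig())


class TestMetrics:
    def test_f1_identity_on_random_matrices(self, rng):
        for _ in range(50):
            cm = rng.integers(0, 200, (2, 2))
            r = report_from_confusion(cm)
            for label in CLASS_ORDER:
                p, rec = r.precision[label], r.recall[label]
                expect = 2 * p * rec / (p + rec) if p + rec > 0 else 0.0
                assert abs(r.f1[label] - expect) < 1e-12
            assert r.accuracy == np.trace(cm) / cm.sum()

    def test_degenerate_all_one_class_predictor(self):
        # balanced truth, everything predicted HCC
        with pytest.warns(UserWarning, match="precision"):
            r = report_from_confusion(np.array([[50, 0], [50, 0]]))
        assert r.accuracy == 0.5
        assert r.precision["MF-ICC"] == 0.0
        assert r.warnings

    def test_perfect_predictions(self):
        r = report_from_confusion(np.array([[30, 0], [0, 20]]))
        assert r.accuracy == 1.0
        assert all(v == 1.0 for v in r.precision.values())
        assert all(v == 1.0 for v in r.f1.values())


class TestROC:
    def test_perfect_and_inverted_ranking(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels)[2] == 1.0
        assert roc_auc(scores, 1 - labels)[2] == 0.0

    def test_known_small_example(self):
        _, _, auc = roc_auc(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_equals_concordance_oracle(self, rng, n):
        for trial in range(5):
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestEvaluate:
    @pytest.fixture(scope="class")
    def tiny_model_and_data(self):
        model = SFFNet(SFFNetConfig.preset("reduced", input_size=64, init_seed=0))
        rng = np.random.default_rng(0)
        x = rng.random((12, 1, 64, 64), dtype=np.float32)
        y = rng.integers(0, 2, 12)
        y[:2] = [0, 1]
        return model, x, y

    def test_report_is_consistent(self, tiny_model_and_data):
        model, x, y = tiny_model_and_data
        r = evaluate(model, x, y)
        assert r.confusion.sum() == len(y)
        assert 0.0 <= r.accuracy <= 1.0
        for label in CLASS_ORDER:
            assert 0.0 <= r.f1[label] <= 1.0

    def test_permutation_invariance(self, tiny_model_and_data):
        model, x, y = tiny_model_and_data
        perm = np.random.default_rng(5).permutation(len(y))
        a = evaluate(model, x, y)
        b = evaluate(model, x[perm], y[perm])
        assert np.array_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy
        assert a.auc == pytest.approx(b.auc)

    def test_single_class_auc_is_nan_with_warning(self, tiny_model_and_data):
        model, x, _ = tiny_model_and_data
        with pytest.warns(UserWarning, match="AUC undefined"):
            r = evaluate(model, x, np.zeros(len(x), dtype=int))
        assert np.isnan(r.auc["HCC"]) and np.isnan(r.auc["MF-ICC"])

    def test_majority_vote_hand_case(self):
        labels = np.array([0, 0, 0, 1, 1, 1, 1])
        preds = np.array([0, 0, 1, 1, 0, 1, 1])
        lesions = ["a", "a", "a", "b", "b", "c", "c"]
        r = majority_vote_report(labels, preds, lesions)
        # a -> majority 0 (truth 0), b -> tie 0/1 -> HCC (truth 1), c -> 1
        assert np.array_equal(r.confusion, np.array([[1, 0], [1, 1]]))


class TestTraining:
    def _patches(self, n_per_class, size=64, seed=0):
        spec = PhantomSpec(seed=seed)
        xs, ys = [], []
        for sl, mask in iter_cohort(n_per_class, spec, seed, slices_per_lesion=1):
            p = apply_strategy(sl, mask, "semi_sp", out_size=size)
            xs.append(p.pixels)
            ys.append(0 if sl.class_label == "HCC" else 1)
        return np.stack(xs)[:, None], np.array(ys)

    def test_memorizes_small_set(self):
        """Overfit sanity: 32 phantom patches, 30 epochs, accuracy >= 0.95."""
        x, y = self._patches(16)
        model = SFFNet(SFFNetConfig.preset("reduced", input_size=64, init_seed=0))
        cfg = TrainConfig(initial_lr=0.01, lr_step_epochs=15, epochs=30, batch_size=16, seed=0)
        result = train(model, {"train": (x, y), "validation": (x, y)}, cfg)
        assert np.isfinite(result.history.train_loss).all()
        assert result.history.train_accuracy.iloc[-1] >= 0.95

    def test_same_seed_identical_loss_curves(self):
        x, y = self._patches(4)
        curves = []
        for _ in range(2):
            model = SFFNet(SFFNetConfig.preset("reduced", input_size=64, init_seed=3))
            cfg = TrainConfig(initial_lr=0.01, epochs=3, batch_size=8, seed=11)
            r = train(model, {"train": (x, y), "validation": (x, y)}, cfg)
            curves.append(r.history.train_loss.to_numpy())
        assert np.array_equal(curves[0], curves[1])

    def test_empty_split_rejected(self):
        model = SFFNet(SFFNetConfig.preset("reduced", input_size=64))
        with pytest.raises(ValueError, match="empty or missing"):
            train(model, {"train": (np.zeros((0, 1, 64, 64)), np.zeros(0))}, TrainConfig())

    def test_best_checkpoint_restored(self):
        x, y = self._patches(4)
        model = SFFNet(SFFNetConfig.preset("reduced", input_size=64, init_seed=0))
        cfg = TrainConfig(initial_lr=0.01, epochs=4, batch_size=8, seed=0)
        result = train(model, {"train": (x, y), "validation": (x, y)}, cfg)
        best = result.history.val_accuracy.max()
        assert result.best_val_accuracy == best
        # earliest epoch wins ties
        assert result.best_epoch == int(result.history.val_accuracy.idxmax())


class TestEmbedding:
    def test_shape_and_determinism(self, rng):
        feats = rng.random((20, 8))
        a = embed_2d(feats, seed=3)
        b = embed_2d(feats, seed=3)
        assert a.shape == (20, 2)
        assert np.array_equal(a, b)

    def test_separated_blobs_keep_separation(self, rng):
        from sklearn.metrics import silhouette_score

        x = np.r_[rng.normal(0, 1, (30, 10)), rng.normal(6, 1, (30, 10))]
        y = np.r_[np.zeros(30), np.ones(30)]
        coords = embed_2d(x, seed=0)
        # frozen after first computation (observed 0.93)
        assert silhouette_score(coords, y) > 0.5

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            embed_2d(np.zeros((4, 3)), seed=0)
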