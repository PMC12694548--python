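"""Metrics oracle, fold aggregation, and training-loop contracts."""

import numpy as np
import pandas as pd
import pytest

from icsms import factory
from icsms.synth import generate_arrays
from icsms.traineval import (ArrayDataset, FoldResult, MetricsReport,
                             TrainConfig, aggregate_folds, evaluate,
                             lambda_sweep, train_model)


def _brute_force_metrics(cm):
    """Independent per-class TP/FP/FN/TN counting by explicit enumeration."""
    cm = np.asarray(cm)
    c = cm.shape[0]
    total = cm.sum()
    precs, recs, f1s = [], [], []
    for k in range(c):
        tp = fp = fn = 0
        for i in range(c):
            for j in range(c):
                if i == k and j == k:
                    tp += cm[i, j]
                elif j == k:
                    fp += cm[i, j]
                elif i == k:
                    fn += cm[i, j]
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    acc = sum(cm[k, k] for k in range(c)) / total
    return (acc * 100, np.mean(precs) * 100, np.mean(recs) * 100,
            np.mean(f1s) * 100)


class TestMetrics:
    def test_hand_worked_three_class_example(self):
        rep = MetricsReport.from_confusion([[8, 1, 1], [0, 9, 1], [2, 0, 8]])
        assert rep.accuracy == pytest.approx(83.3333, abs=1e-3)
        assert rep.macro_precision == pytest.approx(83.3333, abs=1e-3)
        assert rep.macro_recall == pytest.approx(83.3333, abs=1e-3)
        assert rep.macro_f1 == pytest.approx(83.3333, abs=1e-3)

    def test_perfect_two_class_prediction(self):
        rep = MetricsReport.from_confusion([[50, 0], [0, 50]])
        assert rep.accuracy == 100.0 and rep.macro_f1 == 100.0

    def test_all_one_class_predictor_on_balanced_set(self):
        rep = MetricsReport.from_confusion([[50, 0], [50, 0]])
        assert rep.accuracy == 50.0
        assert rep.per_class.loc[0, "recall"] == 100.0

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_counting_on_random_matrices(self, trial):
        rng = np.random.default_rng(trial)
        cm = rng.integers(0, 30, size=(6, 6))
        cm[0, 0] += 1  # never fully empty
        rep = MetricsReport.from_confusion(cm)
        acc, prec, rec, f1 = _brute_force_metrics(cm)
        assert rep.accuracy == pytest.approx(acc, rel=1e-9)
        assert rep.macro_precision == pytest.approx(prec, rel=1e-9)
        assert rep.macro_recall == pytest.approx(rec, rel=1e-9)
        assert rep.macro_f1 == pytest.approx(f1, rel=1e-9)

    def test_matches_sklearn_macro_scores(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        cm = sklearn.confusion_matrix(y_true, y_pred)
        rep = MetricsReport.from_confusion(cm)
        assert rep.macro_f1 / 100 == pytest.approx(
            sklearn.f1_score(y_true, y_pred, average="macro"), rel=1e-9)
        assert rep.accuracy / 100 == pytest.approx(
            sklearn.accuracy_score(y_true, y_pred), rel=1e-9)

    def test_trace_over_total_equals_accuracy(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 20, size=(4, 4)) + 1
        rep = MetricsReport.from_confusion(cm)
        assert rep.accuracy == pytest.approx(
            np.trace(cm) / cm.sum() * 100, rel=1e-12)

    def test_macro_f1_bounded_by_per_class_extremes(self):
        rng = np.random.default_rng(2)
        cm = rng.integers(0, 20, size=(5, 5)) + 1
        rep = MetricsReport.from_confusion(cm)
        assert rep.per_class["f1"].min() <= rep.macro_f1 \
            <= rep.per_class["f1"].max()


class TestAggregateFolds:
    def _reports(self, accs):
        reports = []
        for a in accs:
            n_ok = int(a)
            cm = [[n_ok, 100 - n_ok], [0, 100]]
            reports.append(MetricsReport.from_confusion(cm))
        return reports

    def test_mean_and_sample_sd(self):
        table = pd.DataFrame([{"accuracy": a}
                              for a in (90, 92, 94, 91, 93)])
        assert table["accuracy"].mean() == 92.0
        assert table["accuracy"].std(ddof=1) == pytest.approx(1.5811, abs=1e-3)
        result = aggregate_folds(self._reports([90, 92, 94, 91, 93]))
        assert isinstance(result, FoldResult)
        assert len(result.reports) == 5

    def test_identical_folds_have_zero_sd(self):
        result = aggregate_folds(self._reports([90, 90, 90]))
        assert result.sd["accuracy"] == 0.0

    def test_permutation_invariant(self):
        a = aggregate_folds(self._reports([80, 90, 100]))
        b = aggregate_folds(self._reports([100, 80, 90]))
        assert a.mean == b.mean and a.sd == b.sd

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_folds(self._reports([90]))


@pytest.fixture(scope="module")
def micro_data():
    """Two-class, 10-images-per-class in-memory dataset for loop contracts."""
    images, labels, _ = generate_arrays(per_class=10, num_classes=2, seed=21)
    return ArrayDataset(images={"train": images, "val": images,
                                "test": images},
                        labels={"train": labels, "val": labels,
                                "test": labels})


def _micro_config(**kw):
    base = dict(batch_size=8, epochs=2, lr=1e-3, seed=5, image_size=48,
                augment=None)
    base.update(kw)
    return TrainConfig(**base)


class TestTrainingLoop:
    def test_fixed_seed_reproduces_history_exactly(self, micro_data):
        runs = []
        for _ in range(2):
            model = factory.build("ICS-MS", num_classes=2, seed=5)
            _, hist = train_model(model, micro_data, _micro_config(lam=0.01))
            runs.append(hist)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_lambda_zero_joint_path_identical_to_ce_only(self, micro_data):
        """The joint model trained at lambda 0 and the CE-only model follow
        bit-identical loss trajectories under the same seed."""
        m_joint = factory.build("ICS-MS", num_classes=2, seed=5)
        _, h_joint = train_model(m_joint, micro_data, _micro_config(lam=0.0))
        m_ce = factory.build("ICS-MS-CE", num_classes=2, seed=5)
        _, h_ce = train_model(m_ce, micro_data, _micro_config(lam=0.0))
        np.testing.assert_array_equal(h_joint["loss"], h_ce["loss"])
        np.testing.assert_array_equal(h_joint["val_accuracy"],
                                      h_ce["val_accuracy"])

    def test_joint_training_moves_centers(self, micro_data):
        model = factory.build("ICS-MS", num_classes=2, seed=5)
        before = model.centers.data.copy()
        train_model(model, micro_data, _micro_config(lam=0.01, epochs=1))
        assert not np.array_equal(model.centers.data, before)

    def test_history_schema_and_loss_composition(self, micro_data):
        model = factory.build("ICS-MS", num_classes=2, seed=5)
        _, hist = train_model(model, micro_data, _micro_config(lam=0.01))
        assert list(hist.columns) == ["epoch", "loss", "ce", "center",
                                      "val_accuracy"]
        np.testing.assert_allclose(hist["loss"],
                                   hist["ce"] + 0.01 * hist["center"],
                                   rtol=1e-5)

    def test_empty_split_rejected(self, micro_data):
        model = factory.build("ICS-MS", num_classes=2, seed=5).eval()
        empty = ArrayDataset(
            images={"test": np.zeros((0, 48, 48, 3), dtype=np.float32)},
            labels={"test": np.zeros(0, dtype=np.int64)})
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, empty, "test", _micro_config())


class TestLambdaSweep:
    def test_emits_requested_lambda_column(self, micro_data):
        table = lambda_sweep(
            lambda: factory.build("ICS-MS", num_classes=2, seed=5),
            micro_data, _micro_config(epochs=1), lambdas=(0.0, 0.01))
        assert table["lambda"].tolist() == [0.0, 0.01]
        assert {"accuracy", "precision", "recall", "f1",
                "loss"} <= set(table.columns)

    def test_empty_lambda_set_rejected(self, micro_data):
        with pytest.raises(ValueError, match="non-empty"):
            lambda_sweep(lambda: None, micro_data, _micro_config(),
                         lambdas=())
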