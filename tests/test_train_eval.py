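"""Splitting, training control flow, and metric correctness."""

import numpy as np
import pytest

from ppgid.nn.model import build_model, tiny_config
from ppgid.train_eval import (
    SETTINGS,
    ablation,
    dataset_to_arrays,
    evaluate,
    report_from_predictions,
    split_dataset,
    train,
)
from ppgid.types import LabelledDataset, Record


def _raster_dataset(rng, n_subjects=4, per_subject=6, side=16):
    recs = []
    for i in range(n_subjects):
        base = rng.random((side, side))
        for j in range(per_subject):
            recs.append(
                Record(
                    payload=base + 0.01 * rng.random((side, side)),
                    subject_id=f"S{i}",
                    record_id=f"S{i}_r{j}",
                )
            )
    return LabelledDataset(recs)


class TestSplit:
    def test_counts_80_20(self, rng):
        ds = _raster_dataset(rng, n_subjects=4, per_subject=10)
        tr, te = split_dataset(ds, 0.8, rng)
        assert len(tr) == 32 and len(te) == 8
        for sid in ds.subject_ids:
            assert sum(1 for r in tr if r.subject_id == sid) == 8

    def test_minimal_two_records(self, rng):
        ds = _raster_dataset(rng, n_subjects=3, per_subject=2)
        tr, te = split_dataset(ds, 0.5, rng)
        for sid in ds.subject_ids:
            assert sum(1 for r in tr if r.subject_id == sid) == 1
            assert sum(1 for r in te if r.subject_id == sid) == 1

    def test_partition_disjoint_and_complete(self, rng):
        ds = _raster_dataset(rng)
        tr, te = split_dataset(ds, 0.8, rng)
        tr_ids = {r.record_id for r in tr}
        te_ids = {r.record_id for r in te}
        assert tr_ids.isdisjoint(te_ids)
        assert tr_ids | te_ids == {r.record_id for r in ds}
        assert all(r.split == "train" for r in tr)
        assert all(r.split == "test" for r in te)

    def test_single_record_subject_rejected(self, rng):
        ds = LabelledDataset([Record(payload=rng.random((4, 4)), subject_id="S0", record_id="r0")])
        with pytest.raises(ValueError, match="need >= 2"):
            split_dataset(ds, 0.8, rng)

    def test_deterministic_under_seed(self, rng):
        ds = _raster_dataset(rng)
        a = split_dataset(ds, 0.8, np.random.default_rng(3))[0]
        b = split_dataset(ds, 0.8, np.random.default_rng(3))[0]
        assert [r.record_id for r in a] == [r.record_id for r in b]


class TestEarlyStopping:
    def test_monotonically_worsening_val_stops_at_eleven(self, rng):
        ds = _raster_dataset(rng, n_subjects=2, per_subject=4, side=16)
        model = build_model(config=tiny_config(n_classes=2, input_side=16), seed=0)
        worsening = list(np.linspace(1.0, 2.0, 50))
        hist = train(
            model,
            ds,
            setting=SETTINGS[2],
            epochs=50,
            patience=10,
            rng=rng,
            val_loss_override=worsening,
        )
        assert hist.stopped_epoch == 11
        assert hist.best_epoch == 1

    def test_runs_to_epoch_budget_without_worsening(self, rng):
        ds = _raster_dataset(rng, n_subjects=2, per_subject=4, side=16)
        model = build_model(config=tiny_config(n_classes=2, input_side=16), seed=0)
        improving = list(np.linspace(2.0, 1.0, 5))
        hist = train(model, ds, epochs=5, patience=10, rng=rng, val_loss_override=improving)
        assert hist.stopped_epoch == 5
        assert hist.best_epoch == 5

    def test_empty_training_data_rejected(self):
        model = build_model(config=tiny_config(n_classes=2, input_side=16), seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, (np.zeros((0, 16, 16)), np.zeros(0, dtype=int)))


class TestMetrics:
    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = report_from_predictions(y, y.copy(), ["a", "b", "c"])
        assert np.allclose(rep.precision, 1.0)
        assert np.allclose(rep.recall, 1.0)
        assert np.allclose(rep.f1, 1.0)
        assert rep.accuracy == 1.0

    def test_two_class_hand_computed(self):
        # confusion [[8, 2], [1, 9]]
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 1 + [1] * 9)
        rep = report_from_predictions(y_true, y_pred, ["n", "p"])
        assert np.array_equal(rep.confusion, [[8, 2], [1, 9]])
        assert np.allclose(rep.precision, [8 / 9, 9 / 11])
        assert np.allclose(rep.recall, [0.8, 0.9])

    def test_matches_sklearn_on_random_predictions(self):
        from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 5, 200)
        y_pred = rng.integers(0, 5, 200)
        rep = report_from_predictions(y_true, y_pred, [str(i) for i in range(5)])
        assert np.array_equal(rep.confusion, confusion_matrix(y_true, y_pred, labels=range(5)))
        p, r, f, s = precision_recall_fscore_support(y_true, y_pred, labels=range(5), zero_division=0)
        assert np.allclose(rep.precision, p)
        assert np.allclose(rep.recall, r)
        assert np.allclose(rep.f1, f)
        assert np.array_equal(rep.support, s)
        pm, rm, fm, _ = precision_recall_fscore_support(
            y_true, y_pred, average="weighted", zero_division=0
        )
        assert np.isclose(rep.weighted_precision, pm)
        assert np.isclose(rep.weighted_f1, fm)

    def test_mass_conservation_and_accuracy_identity(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, 120)
        y_pred = rng.integers(0, 4, 120)
        rep = report_from_predictions(y_true, y_pred, list("abcd"))
        assert rep.confusion.sum() == 120
        assert np.isclose(rep.accuracy, np.trace(rep.confusion) / 120)

    def test_macro_equals_weighted_on_balanced_support(self):
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 1, 1, 1, 2, 0])
        rep = report_from_predictions(y_true, y_pred, list("abc"))
        assert np.isclose(rep.macro_f1, rep.weighted_f1)
        assert np.isclose(rep.macro_precision, rep.weighted_precision)

    def test_single_class_test_set_weighted_equals_class_metric(self):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.array([0] * 8 + [1] * 2)
        rep = report_from_predictions(y_true, y_pred, ["a", "b"])
        assert np.isclose(rep.weighted_recall, rep.recall[0])

    def test_empty_test_set_rejected(self):
        model = build_model(config=tiny_config(n_classes=2, input_side=16), seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, (np.zeros((0, 16, 16)), np.zeros(0, dtype=int)))


class TestAblation:
    def test_table_shape_and_determinism(self, rng):
        ds = _raster_dataset(rng, n_subjects=3, per_subject=4, side=16)
        tr, te = split_dataset(ds, 0.5, np.random.default_rng(0))

        def factory(setting, n_classes, seed):
            return build_model(
                config=tiny_config(
                    n_classes=n_classes, input_side=16, activation=setting.hidden_activation
                ),
                seed=seed,
            )

        variants = {"raw": (tr, te)}
        settings = [SETTINGS[1], SETTINGS[2]]
        t1 = ablation(settings, variants, factory, epochs=2, seed=0)
        assert len(t1) == 2
        assert set(t1.columns) >= {"setting_id", "variant", "accuracy"}
        t2 = ablation(settings, variants, factory, epochs=2, seed=0)
        assert t1.equals(t2)

    def test_single_cell(self, rng):
        ds = _raster_dataset(rng, n_subjects=2, per_subject=4, side=16)
        tr, te = split_dataset(ds, 0.5, np.random.default_rng(0))

        def factory(setting, n_classes, seed):
            return build_model(config=tiny_config(n_classes=n_classes, input_side=16), seed=seed)

        table = ablation([SETTINGS[2]], {"filtered": (tr, te)}, factory, epochs=1, seed=0)
        assert len(table) == 1


def test_settings_mirror_ablation_grid():
    assert [SETTINGS[i].batch_size for i in (1, 2, 3)] == [16, 32, 64]
    assert [SETTINGS[i].optimizer for i in (1, 2, 3)] == ["sgd", "adam", "rmsprop"]
    assert [SETTINGS[i].learning_rate for i in (1, 2, 3)] == [0.01, 0.001, 0.0001]
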