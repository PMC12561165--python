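import numpy as np
import pytest

from rtcn.io import Beat, CLASSES
from rtcn.model import RTCN, RtcnConfig
from rtcn.train import (ConfusionMatrix, SplitSpec, TrainConfig,
                        compute_metrics, evaluate, split_dataset, train_model)


def _beats(n_patients=10, beats_per_patient=4, label="HC", source="real"):
    rng = np.random.default_rng(0)
    return [Beat(rng.normal(size=16), label, f"p{i}", 8, source)
            for i in range(n_patients) for _ in range(beats_per_patient)]


class TestSplit:
    def test_inter_patient_partition_is_disjoint_8_to_2(self):
        train, test = split_dataset(_beats(10), SplitSpec("inter_patient", 0.8, 1))
        tp = {b.patient_id for b in train}
        sp = {b.patient_id for b in test}
        assert len(tp) == 8 and len(sp) == 2
        assert not tp & sp
        assert len(train) + len(test) == 40

    def test_single_patient_cannot_be_partitioned(self):
        with pytest.raises(ValueError):
            split_dataset(_beats(1), SplitSpec("inter_patient", 0.8, 0))

    def test_intra_patient_full_train_fraction_gives_empty_test(self):
        train, test = split_dataset(_beats(5), SplitSpec("intra_patient", 1.0, 0))
        assert test == [] and len(train) == 20

    def test_synthetic_beats_always_in_train(self):
        beats = _beats(10) + _beats(3, 2, source="synthetic")
        for paradigm in ("inter_patient", "intra_patient"):
            train, test = split_dataset(beats, SplitSpec(paradigm, 0.8, 2))
            assert all(b.source == "real" for b in test)
            assert sum(b.source == "synthetic" for b in train) == 6

    def test_missing_patient_id_rejected_inter_patient(self):
        beats = _beats(4)
        beats[0].patient_id = ""
        with pytest.raises(ValueError, match="patient ID"):
            split_dataset(beats, SplitSpec("inter_patient", 0.8, 0))


class TestMetrics:
    def test_diagonal_matrix_gives_perfect_scores(self):
        cm = ConfusionMatrix(12)
        for k in range(12):
            cm.add(k, k, 5)
        rep = compute_metrics(cm)
        assert rep.acc_total == pytest.approx(100.0)
        for row in rep.per_class.values():
            for v in row.values():
                assert v == pytest.approx(100.0)

    def test_binary_hand_oracle(self):
        # class 0: TP=8 FN=2 FP=1 TN=9
        cm = ConfusionMatrix(2, labels=("pos", "neg"))
        cm.add(0, 0, 8); cm.add(0, 1, 2); cm.add(1, 0, 1); cm.add(1, 1, 9)
        row = compute_metrics(cm).per_class["pos"]
        assert row["Sen"] == pytest.approx(80.0)
        assert row["Pre"] == pytest.approx(100 * 8 / 9)
        assert row["Spe"] == pytest.approx(90.0)
        assert row["Acc"] == pytest.approx(85.0)
        assert row["F1"] == pytest.approx(2 * 80 * (800 / 9) / (80 + 800 / 9))

    def test_f1_consistent_with_sen_and_pre(self):
        rng = np.random.default_rng(1)
        cm = ConfusionMatrix(12)
        for t in range(12):
            for p in range(12):
                cm.add(t, p, int(rng.integers(0, 30)))
        rep = compute_metrics(cm)
        for row in rep.per_class.values():
            if row["Sen"] == row["Sen"] and row["Pre"] == row["Pre"] \
                    and row["Sen"] + row["Pre"] > 0:
                expected = 2 * row["Sen"] * row["Pre"] / (row["Sen"] + row["Pre"])
                assert row["F1"] == pytest.approx(expected, abs=1e-9)

    def test_acct_equals_direct_fraction_correct(self):
        rng = np.random.default_rng(2)
        true = rng.integers(0, 12, 300)
        pred = rng.integers(0, 12, 300)
        cm = ConfusionMatrix(12)
        for t, p in zip(true, pred):
            cm.add(int(t), int(p))
        assert compute_metrics(cm).acc_total == \
            pytest.approx(100.0 * np.mean(true == pred))

    def test_permutation_invariance_of_macro_metrics(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 20, (12, 12))
        perm = rng.permutation(12)
        cm1, cm2 = ConfusionMatrix(12), ConfusionMatrix(12)
        cm1.matrix[...] = m
        cm2.matrix[...] = m[np.ix_(perm, perm)]
        r1, r2 = compute_metrics(cm1), compute_metrics(cm2)
        for key in ("Acc", "Sen", "Pre", "Spe", "F1"):
            assert r1.macro[key] == pytest.approx(r2.macro[key], abs=1e-9)
        assert r1.acc_total == pytest.approx(r2.acc_total)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(12))

    def test_summary_renders_all_classes(self):
        cm = ConfusionMatrix(12)
        for k in range(12):
            cm.add(k, k, 2)
        text = compute_metrics(cm).summary()
        for label in CLASSES:
            assert label in text
        assert "AccT" in text


class _ConstantModel:
    def __init__(self, k):
        self.k = k

    def predict(self, images):
        return np.full(len(images), self.k, dtype=int)


class TestEvaluate:
    def test_constant_predictor_fills_single_column(self):
        images = np.zeros((30, 1))
        labels = np.repeat(np.arange(6), 5)
        cm = evaluate(_ConstantModel(3), images, labels)
        assert cm.matrix[:, 3].sum() == 30
        assert cm.matrix.sum() == 30
        col = np.delete(cm.matrix, 3, axis=1)
        assert col.sum() == 0

    def test_grand_total_equals_test_size(self):
        cm = evaluate(_ConstantModel(0), np.zeros((17, 1)),
                      np.zeros(17, dtype=int))
        assert cm.total == 17


def _toy_images(n, side=32, seed=0):
    rng = np.random.default_rng(seed)
    X = 0.05 * rng.random((n, 3, side, side))
    y = np.arange(n) % 2
    for i in range(n):
        r0 = 4 if y[i] == 0 else 20
        X[i, :, r0 : r0 + 8, 12:20] += 1.0
    return X, y


class TestTrainModel:
    CFG = RtcnConfig(n_classes=2, input_side=32, width_divisor=16,
                     compressed_dim=16, n_heads=2, n_encoder_layers=1,
                     dropout=0.0, seed=0)

    def test_learning_improves_train_accuracy(self):
        X, y = _toy_images(16)
        m = RTCN(self.CFG)
        _, curves = train_model(m, X, y, TrainConfig(
            lr=0.02, momentum=0.9, batch_size=8, epochs=4, val_fraction=0.0,
            seed=0))
        assert curves.train_acc[-1] > 0.5
        assert curves.train_loss[-1] < curves.train_loss[0]

    def test_zero_learning_rate_flat_loss(self):
        X, y = _toy_images(8)
        m = RTCN(self.CFG)
        _, curves = train_model(m, X, y, TrainConfig(
            lr=0.0, momentum=0.9, batch_size=8, epochs=3, val_fraction=0.0,
            seed=0))
        assert np.ptp(curves.train_loss) < 1e-9

    def test_seeded_training_reproducible(self):
        X, y = _toy_images(8)
        cfg = TrainConfig(lr=0.02, momentum=0.9, batch_size=4, epochs=2,
                          val_fraction=0.0, seed=5)
        _, c1 = train_model(RTCN(self.CFG), X, y, cfg)
        _, c2 = train_model(RTCN(self.CFG), X, y, cfg)
        np.testing.assert_array_equal(c1.train_loss, c2.train_loss)

    def test_single_class_rejected(self):
        X, _ = _toy_images(6)
        with pytest.raises(ValueError, match="two classes"):
            train_model(RTCN(self.CFG), X, np.zeros(6, dtype=int))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            train_model(RTCN(self.CFG), np.zeros((0, 3, 32, 32)), np.zeros(0))
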