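import numpy as np
import pandas as pd
import pytest

from fracopd.nn import DenseNet
from fracopd.staging import (
    MinMaxScalerSafe,
    NetSpec,
    StagedDataset,
    build_baseline,
    build_fddlm,
    count_params,
    holdout_eval,
    kfold_eval,
    linear_probe,
    metrics_from_confusion,
    normalize_features,
    stage_from_spirometry,
)


def enumerate_dense_params(sizes):
    """Layer-by-layer enumeration oracle for dense-stack counts."""
    total = 0
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        total += fan_in * fan_out  # weights
        total += fan_out  # biases
    return total


class TestParamCounts:
    def test_staging_net_count(self):
        assert count_params(NetSpec(input_dim=144)) == 74_105

    def test_vanilla_dnn_count(self):
        assert count_params(build_baseline("vanilla_dnn")) == 21_630_905

    def test_cnn_count(self):
        assert count_params(build_baseline("cnn")) == 147_456_453

    def test_tiny_example(self):
        assert count_params(NetSpec(input_dim=2, hidden=(2, 2), n_classes=2)) == 18

    def test_lstm_reports_discrepancy(self):
        spec = build_baseline("lstm")
        computed = count_params(spec)
        # 4*((12+300+1)*300) + 301*100 + 101*5
        assert computed == 406_205
        assert spec["count_discrepancy"]
        assert spec["reported_params"] == 535_805

    @pytest.mark.parametrize(
        "sizes", [(144, 300, 100, 5), (36, 300, 100, 5), (7, 4, 3), (2, 2, 2, 2)]
    )
    def test_closed_form_matches_enumeration(self, sizes):
        spec = NetSpec(input_dim=sizes[0], hidden=tuple(sizes[1:-1]), n_classes=sizes[-1])
        assert count_params(spec) == enumerate_dense_params(sizes)
        # and the instantiated network holds exactly that many parameters
        assert DenseNet(sizes, seed=0).n_params == enumerate_dense_params(sizes)

    def test_transfer_variant_dimensions(self):
        assert count_params(NetSpec(input_dim=36)) == enumerate_dense_params((36, 300, 100, 5))

    def test_baseline_input_shapes(self):
        assert build_baseline("vanilla_dnn")["input_shape"] == (72000,)
        assert build_baseline("lstm")["input_shape"] == (6000, 12)
        assert build_baseline("cnn")["input_shape"] == (72000, 1)


class TestBuildNet:
    def test_same_seed_identical_weights(self):
        n1 = build_fddlm(NetSpec(input_dim=36, seed=7))
        n2 = build_fddlm(NetSpec(input_dim=36, seed=7))
        for w1, w2 in zip(n1.W, n2.W):
            assert np.array_equal(w1, w2)

    def test_different_seed_differs(self):
        n1 = build_fddlm(NetSpec(input_dim=36, seed=7))
        n2 = build_fddlm(NetSpec(input_dim=36, seed=8))
        assert not np.array_equal(n1.W[0], n2.W[0])

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            NetSpec(dropout_rate=1.0)

    def test_training_loss_decreases(self):
        """Loss drops over the first 10 epochs on separable blobs."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(c, 0.3, size=(40, 10)) for c in range(5)])
        y = np.repeat(np.arange(5), 40)
        net = build_fddlm(NetSpec(input_dim=10, seed=1))
        losses = net.fit(X, y, epochs=10, batch_size=64)
        assert losses[-1] < losses[0]


class TestNormalization:
    def test_minmax_example(self):
        train = np.array([[2.0], [4.0], [6.0]])
        ts, _, _ = normalize_features(train)
        assert np.allclose(ts.ravel(), [0.0, 0.5, 1.0])

    def test_idempotent_on_train(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((20, 3))
        scaler = MinMaxScalerSafe().fit(train)
        once = scaler.transform(train)
        twice_scaler = MinMaxScalerSafe().fit(once)
        assert np.allclose(twice_scaler.transform(once), once)

    def test_heldout_clipping_counted(self):
        train = np.array([[0.0], [1.0]])
        test = np.array([[2.0], [-1.0], [0.5]])
        ts, (hs,), scaler = normalize_features(train, test)
        assert np.allclose(hs.ravel(), [1.0, 0.0, 0.5])
        assert scaler.clipped_count == 2

    def test_constant_feature_warns_and_maps_to_zero(self):
        train = np.array([[3.0, 1.0], [3.0, 2.0]])
        with pytest.warns(UserWarning, match="constant"):
            ts, _, _ = normalize_features(train)
        assert np.allclose(ts[:, 0], 0.0)


class TestMetrics:
    def test_identity_confusion_perfect(self):
        m = metrics_from_confusion(np.eye(5, dtype=int) * 10)
        assert np.allclose(m[["sensitivity", "specificity", "precision"]].to_numpy(), 1.0)

    def test_single_error(self):
        C = np.eye(5, dtype=int) * 10
        C[0, 0], C[0, 1] = 9, 1
        m = metrics_from_confusion(C)
        assert np.isclose(m.loc[0, "sensitivity"], 0.9)

    def test_three_class_hand_enumeration(self):
        """Cross-checked against explicit one-vs-rest TP/FP/TN/FN counting."""
        C = np.array([[5, 2, 0], [1, 7, 1], [0, 3, 6]])
        m = metrics_from_confusion(C)
        # class 1: TP=7, FN=2, FP=5, TN=25-7-2-5=11
        assert np.isclose(m.loc[1, "sensitivity"], 7 / 9)
        assert np.isclose(m.loc[1, "specificity"], 11 / 16)
        assert np.isclose(m.loc[1, "precision"], 7 / 12)

    def test_undefined_ratio_is_nan_not_zero(self):
        C = np.zeros((3, 3), dtype=int)
        C[0, 0] = 5  # classes 1, 2 have no support and no predictions
        m = metrics_from_confusion(C)
        assert np.isnan(m.loc[1, "sensitivity"])
        assert np.isnan(m.loc[1, "precision"])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((5, 5), dtype=int))

    def test_rates_bounded(self):
        rng = np.random.default_rng(2)
        C = rng.integers(0, 20, size=(5, 5))
        m = metrics_from_confusion(C).to_numpy()
        finite = m[np.isfinite(m)]
        assert np.all((finite >= 0) & (finite <= 1))


def _toy_dataset(n_per_class=20, n_feat=8, sep=4.0, seed=0, n_inst=4):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(5):
        center = rng.standard_normal(n_feat) * sep * c / 4
        X.append(center + 0.5 * rng.standard_normal((n_per_class, n_feat)))
        y.append(np.full(n_per_class, c))
    X, y = np.vstack(X), np.concatenate(y)
    n = len(y)
    pids = np.array([f"P{i // 2}" for i in range(n)])  # 2 records per patient
    insts = np.array([("VB", "MD1", "MD2", "CP")[i % n_inst] for i in range(n)])
    return StagedDataset(X, y, pids, insts)


class TestProtocols:
    def test_folds_partition_records(self):
        from fracopd.staging import _kfold_indices

        ds = _toy_dataset()
        folds = _kfold_indices(ds, 5, "per_record", np.random.default_rng(0))
        concat = np.sort(np.concatenate(folds))
        assert np.array_equal(concat, np.arange(len(ds.labels)))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1  # 20% each at k=5

    def test_per_patient_never_splits_a_patient(self):
        from fracopd.staging import _kfold_indices

        ds = _toy_dataset()
        folds = _kfold_indices(ds, 5, "per_patient", np.random.default_rng(1))
        for i, f1 in enumerate(folds):
            pats1 = set(ds.patient_ids[f1])
            for f2 in folds[i + 1 :]:
                assert pats1.isdisjoint(set(ds.patient_ids[f2]))

    def test_kfold_on_separable_toy(self):
        ds = _toy_dataset()
        spec = NetSpec(input_dim=8, epochs=60, seed=0)
        rep = kfold_eval(ds, k=5, spec=spec, seed=0)
        assert rep.accuracy_mean > 0.8
        assert rep.confusion.sum() == len(ds.labels)
        assert np.array_equal(rep.confusion.sum(axis=1), np.bincount(ds.labels, minlength=5))

    def test_kfold_determinism(self):
        ds = _toy_dataset()
        spec = NetSpec(input_dim=8, epochs=15, seed=3)
        r1 = kfold_eval(ds, k=3, spec=spec, seed=5)
        r2 = kfold_eval(ds, k=3, spec=spec, seed=5)
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.fold_accuracies == r2.fold_accuracies

    def test_holdout_tests_only_named_institution(self):
        ds = _toy_dataset()
        spec = NetSpec(input_dim=8, epochs=30, seed=0)
        rep = holdout_eval(ds, "VB", spec=spec)
        n_vb = int((ds.institutions == "VB").sum())
        assert rep.confusion.sum() == n_vb

    def test_holdout_resampling_balances_training(self):
        ds = _toy_dataset()
        spec = NetSpec(input_dim=8, epochs=30, seed=0)
        rep = holdout_eval(ds, "MD1", spec=spec, balance="resample", seed=1)
        assert rep.confusion.sum() == int((ds.institutions == "MD1").sum())

    def test_missing_institution_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(ValueError):
            holdout_eval(ds, "NOPE")

    def test_linear_probe_separable(self):
        acc = linear_probe(_toy_dataset(), k=5, seed=0)
        assert 0.8 <= acc <= 1.0


class TestGoldStaging:
    @pytest.mark.parametrize(
        "fev1, ratio, stage",
        [
            (90, 0.75, 0),  # preserved ratio: no COPD regardless of FEV1
            (85, 0.65, 1),
            (80, 0.65, 1),  # boundary: FEV1 >= 80 is mild
            (79.9, 0.65, 2),
            (50, 0.6, 2),
            (49.9, 0.6, 3),
            (30, 0.6, 3),
            (29.9, 0.6, 4),
            (25, 0.60, 4),
        ],
    )
    def test_thresholds(self, fev1, ratio, stage):
        assert stage_from_spirometry(fev1, ratio) == stage

    @pytest.mark.parametrize("fev1, ratio", [(-5, 0.6), (0, 0.6), (50, 0.0), (50, 1.5)])
    def test_out_of_range_rejected(self, fev1, ratio):
        with pytest.raises(ValueError):
            stage_from_spirometry(fev1, ratio)
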