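"""Metrics, cross-validation and the accuracy-vs-window-length curve."""

import numpy as np
import pytest

import posegym as pg
from posegym.evaluation import _stratified_folds, confusion_from_decisions


class TestComputeMetrics:
    def test_perfect_diagonal(self):
        rep = pg.compute_metrics(np.diag([3, 4, 5]))
        assert rep.accuracy == 1.0
        assert np.allclose(rep.precision, 1.0)
        assert np.allclose(rep.recall, 1.0)
        assert np.allclose(rep.f1, 1.0)
        assert rep.n_decisions == 12

    def test_hand_computed_two_class_matrix(self):
        rep = pg.compute_metrics(np.array([[8, 2], [3, 7]]))
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision[0] == pytest.approx(8 / 11)
        assert rep.recall[0] == pytest.approx(0.8)
        assert rep.precision[1] == pytest.approx(7 / 9)
        assert rep.recall[1] == pytest.approx(0.7)
        f1_0 = 2 * (8 / 11) * 0.8 / ((8 / 11) + 0.8)
        assert rep.f1[0] == pytest.approx(f1_0)
        assert rep.macro_precision == pytest.approx((8 / 11 + 7 / 9) / 2)

    def test_never_predicted_class_flagged_as_zero_precision(self):
        cm = np.array([[5, 0, 0], [1, 0, 4], [0, 0, 3]])  # column 1 empty
        rep = pg.compute_metrics(cm)
        assert rep.undefined_precision == [1]
        assert rep.precision[1] == 0.0
        # macro precision averages only defined classes
        assert rep.macro_precision == pytest.approx(
            (5 / 6 + 3 / 7) / 2
        )

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pg.compute_metrics(np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError):
            pg.compute_metrics(np.ones((2, 3)))

    def test_agrees_with_sklearn_on_random_matrices(self):
        """Independent reference: sklearn's precision/recall/F1 computed
        from a prediction stream reconstructed from the matrix counts."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            cm = rng.integers(0, 12, size=(n, n))
            if cm.sum() == 0 or (cm.sum(axis=0) == 0).any() or (cm.sum(axis=1) == 0).any():
                continue
            y_true, y_pred = [], []
            for i in range(n):
                for j in range(n):
                    y_true += [i] * cm[i, j]
                    y_pred += [j] * cm[i, j]
            rep = pg.compute_metrics(cm)
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, labels=range(n), average="macro"
            )
            assert rep.macro_precision == pytest.approx(p)
            assert rep.macro_recall == pytest.approx(r)
            assert rep.macro_f1 == pytest.approx(f)
            assert rep.accuracy == pytest.approx(np.mean(np.array(y_true) == y_pred))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(1, 10, size=(5, 5))
        perm = rng.permutation(5)
        rep = pg.compute_metrics(cm)
        rep_p = pg.compute_metrics(cm[np.ix_(perm, perm)])
        assert rep_p.accuracy == pytest.approx(rep.accuracy)
        assert np.allclose(rep_p.precision, rep.precision[perm])
        assert np.allclose(rep_p.recall, rep.recall[perm])
        assert rep_p.macro_f1 == pytest.approx(rep.macro_f1)


class TestStratifiedFolds:
    def test_each_fold_has_one_sequence_per_class(self):
        labels = [c for c in range(10) for _ in range(5)]
        folds = _stratified_folds(labels, k=5, seed=0)
        labels = np.asarray(labels)
        for fold in folds:
            assert len(fold) == 10
            assert sorted(labels[fold]) == list(range(10))

    def test_same_seed_identical_assignment(self):
        labels = [c for c in range(4) for _ in range(6)]
        a = _stratified_folds(labels, 3, seed=9)
        b = _stratified_folds(labels, 3, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_sequences_for_class_named_in_error(self):
        labels = [0] * 5 + [1] * 2
        with pytest.raises(ValueError, match="1"):
            _stratified_folds(labels, k=3, seed=0)

    def test_k_below_two_rejected(self, tmp_path):
        manifest = pg.simulate_dataset(
            tmp_path / "ds", sequences_per_class=2, n_frames=5, seed=0
        )
        with pytest.raises(ValueError, match="k"):
            pg.stratified_kfold_evaluate(manifest, k=1)


class TestKFoldEvaluate:
    def test_pooled_accuracy_equals_trace_over_total(self, tmp_path):
        manifest = pg.simulate_dataset(
            tmp_path / "ds", sequences_per_class=4, n_frames=45, seed=2
        )
        folds, pooled = pg.stratified_kfold_evaluate(
            manifest,
            pg.ModelConfig(epochs=2, seed=2),
            pg.EnsembleConfig(window_frames=15),
            k=2,
            seed=2,
        )
        assert len(folds) == 2
        summed = sum(f.confusion for f in folds)
        assert np.array_equal(pooled.confusion, summed)
        assert pooled.accuracy == pytest.approx(
            np.trace(summed) / summed.sum()
        )
        # 3 decisions per 45-frame sequence at K=15, all sequences tested once
        assert pooled.n_decisions == 40 * 3


class TestAccuracyVsFrames:
    def test_k1_equals_single_frame_accuracy_and_dedup(self, small_model, noisy_sequences):
        curve = pg.accuracy_vs_frames(
            small_model, noisy_sequences, frame_counts=[1, 10, 10, 30, 1]
        )
        assert list(curve["K"]) == [1, 10, 30]
        correct = n = 0
        for seq in noisy_sequences:
            X = pg.feature_matrix(pg.extract_sequence_features(seq))
            probs = pg.predict_batch(small_model, X)
            correct += int((probs.argmax(axis=1) == seq.label.index).sum())
            n += probs.shape[0]
        assert curve.loc[curve["K"] == 1, "accuracy"].item() == pytest.approx(correct / n)

    def test_overlong_window_skipped_with_warning(self, small_model, noisy_sequences, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="posegym.evaluation"):
            curve = pg.accuracy_vs_frames(
                small_model, noisy_sequences, frame_counts=[30, 500]
            )
        assert list(curve["K"]) == [30]
        assert any("skipped" in r.message for r in caplog.records)

    def test_windowed_beats_or_matches_single_frame_on_clean_data(self, small_model):
        seqs = [
            pg.simulate_sequence(
                c, n_frames=60,
                noise=pg.NoiseModel(coordinate_sigma=0.0, outlier_rate=0.0),
                seed=40 + i, sequence_id=f"c{i}",
            )
            for i, c in enumerate(pg.EXERCISE_CLASS_NAMES)
        ]
        curve = pg.accuracy_vs_frames(small_model, seqs, frame_counts=[1, 30])
        acc = dict(zip(curve["K"], curve["accuracy"]))
        assert acc[30] >= acc[1]


class TestReportExport:
    def test_json_markdown_and_confusion_files(self, tmp_path):
        rep = pg.compute_metrics(np.diag([2] * 10))
        paths = pg.export_report(rep, tmp_path)
        import json

        doc = json.loads(paths["json"].read_text())
        assert doc["accuracy"] == 1.0
        assert len(doc["confusion"]) == 10
        md = paths["markdown"].read_text()
        assert "macro" in md and "arm_raise" in md
        import pandas as pd

        cm = pd.read_csv(paths["confusion"], index_col=0)
        assert cm.shape == (10, 10)
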