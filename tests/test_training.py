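"""Stratified folds, focal-loss training loop, and the cross-validation harness."""

import dataclasses

import numpy as np
import pytest

import seizformer as sz
from seizformer.errors import (BalancingError, ConfigurationError,
                               StratificationError)
from seizformer.model import build_sequences, graphs_for_sequences
from seizformer.training import (TrainConfig, apply_channel_stats,
                                 fit_channel_stats, load_checkpoint,
                                 oversample_indices, run_crossval,
                                 save_checkpoint, select_threshold,
                                 stratified_kfold, train_model)

TINY = TrainConfig(epochs=2, batch_size=16, n_folds=3, seq_len=4, seq_stride=4,
                   gat_hidden=8, gat_heads=2, d_model=16, tx_heads=2,
                   tx_depth=2, seed=0)


class TestStratifiedKFold:
    def test_balanced_classes_split_evenly(self):
        y = np.repeat([0, 1], 100)
        folds = stratified_kfold(y, k=10, seed=0, scheme="random")
        for f in folds:
            assert (y[f] == 1).sum() == 10 and (y[f] == 0).sum() == 10

    def test_folds_partition_the_index_set(self):
        y = np.random.default_rng(0).integers(0, 2, 83)
        folds = stratified_kfold(y, k=5, seed=1)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 83
        assert len(np.unique(all_idx)) == 83

    def test_uneven_classes_differ_by_at_most_one(self):
        y = np.array([1] * 95 + [0] * 100)
        folds = stratified_kfold(y, k=10, seed=2, scheme="random")
        pos_counts = [(y[f] == 1).sum() for f in folds]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert sum(pos_counts) == 95

    def test_blocked_scheme_keeps_time_contiguity_per_class(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        folds = stratified_kfold(y, k=2, seed=0, scheme="blocked")
        assert folds[0].tolist() == [0, 1, 4, 5]
        assert folds[1].tolist() == [2, 3, 6, 7]

    def test_too_few_samples_rejected(self):
        with pytest.raises(StratificationError):
            stratified_kfold([0, 1, 1, 1], k=2)

    def test_deterministic_given_seed(self):
        y = np.random.default_rng(1).integers(0, 2, 60)
        a = stratified_kfold(y, k=4, seed=9, scheme="random")
        b = stratified_kfold(y, k=4, seed=9, scheme="random")
        assert all(np.array_equal(x, z) for x, z in zip(a, b))


class TestOversampling:
    def test_indices_reach_parity(self):
        y = np.array([0] * 30 + [1] * 10)
        idx = oversample_indices(y, np.random.default_rng(0))
        assert (y[idx] == 1).sum() == (y[idx] == 0).sum() == 30
        # the original samples are all retained
        assert set(range(40)) <= set(idx.tolist())

    def test_single_class_rejected(self):
        with pytest.raises(BalancingError):
            oversample_indices(np.zeros(10), np.random.default_rng(0))


class TestSelectThreshold:
    def test_separable_scores_split_cleanly(self):
        scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = select_threshold(scores, y)
        assert 0.3 < t < 0.6
        assert (((scores >= t).astype(int)) == y).all()

    def test_deflated_probabilities_recovered(self):
        """Well-ranked but downward-biased scores (the focal alpha < 0.5
        signature) still yield a perfect-accuracy operating point."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        scores = np.where(y == 1, rng.uniform(0.2, 0.45, 200),
                          rng.uniform(0.0, 0.15, 200))
        t = select_threshold(scores, y)
        assert (((scores >= t).astype(int)) == y).mean() == 1.0
        assert t < 0.5

    def test_all_one_class_predictions_possible(self):
        scores = np.array([0.4, 0.5, 0.6])
        t0 = select_threshold(scores, np.array([1, 1, 1]))
        assert (scores >= t0).all()
        t1 = select_threshold(scores, np.array([0, 0, 0]))
        assert not (scores >= t1).any()

    def test_tie_prefers_lower_threshold(self):
        # both cuts below 0.35 and below 0.65 give accuracy 2/3; the
        # sensitivity-favoring (lower) one is returned
        scores = np.array([0.2, 0.5, 0.8])
        y = np.array([0, 1, 0])
        t = select_threshold(scores, y)
        assert t < 0.5


class TestSequences:
    def test_shapes_and_stride(self, labeled_windows):
        X, y, starts = build_sequences(labeled_windows, seq_len=4, seq_stride=2)
        assert X.shape[1:] == (4, 16, 256)
        assert len(X) == len(y) == len(starts)
        assert starts[1] - starts[0] == pytest.approx(1.0)  # 2 * 0.5 s steps

    def test_majority_label_with_tie_toward_seizure(self):
        wins = [sz.Window(data=np.random.default_rng(i).standard_normal((2, 8)),
                          label=l, start_s=float(i))
                for i, l in enumerate([1, 1, 0, 0])]
        ws = sz.WindowSet(windows=wins, fs=8.0, channel_labels=["A-B", "C-D"])
        _, y, _ = build_sequences(ws, seq_len=4, seq_stride=4)
        assert y.tolist() == [1]    # 2/4 windows positive -> tie -> seizure


class TestTrainModel:
    def _toy(self, n=24, seed=0):
        """Linearly separable toy: positives have 4x the signal scale."""
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2
        X = rng.standard_normal((n, 2, 3, 8))
        X[y == 1] *= 4.0
        adj = graphs_for_sequences(X, tau=0.3)
        return X, adj, y

    def _cfg(self, **kw):
        base = dict(epochs=3, batch_size=8, seq_len=2, gat_hidden=4,
                    gat_heads=2, d_model=8, tx_heads=2, tx_depth=1, seed=1)
        base.update(kw)
        return TrainConfig(**base)

    def test_history_length_equals_epochs(self):
        X, adj, y = self._toy()
        _, hist = train_model(X, adj, y, self._cfg(epochs=3))
        assert len(hist) == 3

    def test_loss_decreases_on_separable_task(self):
        X, adj, y = self._toy(n=40)
        _, hist = train_model(X, adj, y, self._cfg(epochs=12))
        assert hist[-1] < hist[0]

    def test_training_is_deterministic(self):
        X, adj, y = self._toy()
        cfg = self._cfg(epochs=2)
        m1, h1 = train_model(X, adj, y, cfg)
        m2, h2 = train_model(X, adj, y, cfg)
        assert h1 == h2
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            assert np.array_equal(a, b)

    def test_zero_epochs_returns_untrained_model(self):
        X, adj, y = self._toy()
        model, hist = train_model(X, adj, y, self._cfg(epochs=0))
        assert hist == []
        fresh = sz.SeizureModel(3, 8, self._cfg().model_config(), seed=1)
        for a, b in zip(model.state_arrays(), fresh.state_arrays()):
            assert np.array_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(focal_gamma=-1).validate()
        with pytest.raises(ConfigurationError):
            TrainConfig(focal_alpha=1.5).validate()
        with pytest.raises(ConfigurationError):
            TrainConfig(mode="nope").validate()

    def test_checkpoint_roundtrip(self, tmp_path):
        X, adj, y = self._toy()
        cfg = self._cfg(epochs=1)
        model, hist = train_model(X, adj, y, cfg)
        p = tmp_path / "ckpt.npz"
        save_checkpoint(model, cfg, p, hist)
        back, cfg2, hist2 = load_checkpoint(p)
        assert cfg2 == cfg and hist2 == hist
        for a, b in zip(model.state_arrays(), back.state_arrays()):
            assert np.array_equal(a, b)
        pa = model.predict_proba(X, adj)
        pb = back.predict_proba(X, adj)
        assert np.array_equal(pa, pb)


class TestCrossval:
    @pytest.fixture(scope="class")
    def report(self, labeled_windows):
        return run_crossval(labeled_windows, TINY)

    def test_report_has_k_folds_with_aggregates(self, report):
        assert len(report.folds) == TINY.n_folds
        for m in ("accuracy", "sensitivity", "specificity", "f1", "auc"):
            assert 0.0 <= report.mean[m] <= 1.0
            assert report.std[m] >= 0.0

    def test_test_folds_keep_natural_class_ratio(self, report, labeled_windows):
        """Evaluation folds are never oversampled: their sizes and class
        counts add up exactly to the raw sequence set."""
        X, y, _ = build_sequences(labeled_windows, TINY.seq_len, TINY.seq_stride)
        total = sum(len(fr.true) for fr in report.folds)
        assert total == len(y)
        pos = sum(int(fr.true.sum()) for fr in report.folds)
        assert pos == int(y.sum())

    def test_ablation_modes_run(self, labeled_windows):
        for mode in ("gat_only", "transformer_only"):
            cfg = dataclasses.replace(TINY, mode=mode, epochs=1)
            rep = run_crossval(labeled_windows, cfg)
            assert len(rep.folds) == TINY.n_folds

    def test_channel_stats_fit_apply(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 2, 3, 16)) * 5 + 2
        stats = fit_channel_stats(X)
        Xn = apply_channel_stats(X, stats)
        assert np.allclose(Xn.mean(axis=(0, 1, 3)), 0.0, atol=1e-9)
        assert np.allclose(Xn.std(axis=(0, 1, 3)), 1.0, atol=1e-9)
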