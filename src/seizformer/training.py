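"""Focal-loss training, stratified k-fold cross-validation, ablation harness.

The cross-validation protocol for one subject:

1. windows -> sequences of N consecutive windows (majority-vote labels);
2. stratified split of the sequences into k folds (default: time-contiguous
   blocks per class, so overlapping neighbors do not straddle train/test);
3. per fold: z-score stats fitted on the training sequences only, minority
   oversampling on the training fold only, Adam + focal loss for the
   configured number of epochs, then evaluation on the untouched test fold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam
from .errors import (BalancingError, ConfigurationError, StratificationError,
                     TrainingDivergenceError)
from .losses import focal_loss_batch
from .metrics import EvalReport, FoldResult, aggregate_report, evaluate_scores
from .model import ModelConfig, SeizureModel, build_sequences, graphs_for_sequences
from .preprocess import STD_FLOOR
from .records import WindowSet


@dataclass
class TrainConfig:
    """Everything one cross-validation run needs, flat for YAML round-trips."""

    # optimization
    lr: float = 0.001
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.5
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    # protocol
    n_folds: int = 10
    fold_scheme: str = "blocked"      # or "random"
    seq_len: int = 8
    seq_stride: int = 1
    tau: float = 0.3
    mode: str = "combined"
    #: decision threshold on p(seizure): a float, or "train" to pick the
    #: accuracy-maximizing cut on each fold's (unbalanced) training scores.
    #: Focal loss with alpha != 0.5 deliberately re-weights the classes,
    #: which biases the fitted probabilities away from the 0.5 posterior
    #: cut; selecting the operating point on training data corrects this
    #: without touching the test fold.
    decision_threshold: float | str = "train"
    seed: int = 0
    # architecture
    gat_hidden: int = 64
    gat_heads: int = 8
    gat_activation: str = "elu"
    d_model: int = 128
    tx_heads: int = 4
    tx_depth: int = 4
    mlp_hidden: int | None = None

    def validate(self) -> None:
        if self.focal_gamma < 0:
            raise ConfigurationError("focal_gamma must be >= 0")
        if not 0 < self.focal_alpha < 1:
            raise ConfigurationError("focal_alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.fold_scheme not in ("blocked", "random"):
            raise ConfigurationError("fold_scheme must be 'blocked' or 'random'")
        if not (self.decision_threshold == "train"
                or isinstance(self.decision_threshold, (int, float))):
            raise ConfigurationError(
                "decision_threshold must be 'train' or a number")
        self.model_config().validate()

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            mode=self.mode, gat_hidden=self.gat_hidden, gat_heads=self.gat_heads,
            gat_activation=self.gat_activation, d_model=self.d_model,
            tx_heads=self.tx_heads, tx_depth=self.tx_depth,
            mlp_hidden=self.mlp_hidden, dropout=self.dropout, tau=self.tau,
            seq_len=self.seq_len)


def stratified_kfold(labels, k: int = 10, seed: int = 0,
                     scheme: str = "blocked") -> list[np.ndarray]:
    """Disjoint test-index sets with each class spread as evenly as possible.

    ``blocked`` keeps each class's samples in input (time) order and cuts
    contiguous chunks, so temporally adjacent (overlapping) samples share a
    fold; ``random`` shuffles within class first.
    """
    y = np.asarray(labels, dtype=np.int64).ravel()
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise StratificationError(
                f"class {cls} has {len(idx)} samples for {k} folds")
        if scheme == "random":
            idx = rng.permutation(idx)
        elif scheme != "blocked":
            raise ConfigurationError(f"unknown fold scheme {scheme!r}")
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices after 1:1 minority oversampling with replacement."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise BalancingError("both classes needed to balance the training fold")
    if len(pos) == len(neg):
        return np.arange(len(y))
    minority = pos if len(pos) < len(neg) else neg
    extra = rng.choice(minority, size=abs(len(pos) - len(neg)), replace=True)
    return np.concatenate([np.arange(len(y)), extra])


def select_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Accuracy-maximizing cut on (training) scores; ties -> lowest cut.

    Candidates are midpoints between consecutive distinct scores plus the
    open ends, so the returned threshold never sits exactly on a sample.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y)
    order = np.argsort(scores)
    s_sorted, y_sorted = scores[order], y[order]
    # predicting 1 for scores >= cut placed after position k (k samples below)
    pos_right = np.concatenate([[y_sorted.sum()],
                                y_sorted.sum() - np.cumsum(y_sorted)])
    neg_left = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    acc = (pos_right + neg_left) / len(y)
    k = int(np.argmax(acc))     # first (lowest-threshold) maximum
    if k == 0:
        return float(s_sorted[0] - 1e-9)
    if k == len(y):
        return float(s_sorted[-1] + 1e-9)
    return float(0.5 * (s_sorted[k - 1] + s_sorted[k]))


def fit_channel_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over sequences ``(n, N, M, F)`` (training only)."""
    mean = X.mean(axis=(0, 1, 3))
    std = np.maximum(X.std(axis=(0, 1, 3)), STD_FLOOR)
    return mean, std


def apply_channel_stats(X: np.ndarray, stats) -> np.ndarray:
    mean, std = stats
    return (X - mean[None, None, :, None]) / std[None, None, :, None]


def train_model(X: np.ndarray, adjacency: np.ndarray | None, y: np.ndarray,
                cfg: TrainConfig) -> tuple[SeizureModel, list[float]]:
    """Adam + focal loss on already balanced, normalized training sequences.

    ``epochs = 0`` returns the freshly initialized (untrained) model, which
    serves as the chance-level baseline in ablation comparisons. Raises
    :class:`TrainingDivergenceError` on a non-finite epoch loss.
    """
    cfg.validate()
    n, N, M, F = X.shape
    model = SeizureModel(n_channels=M, samples_per_window=F,
                         cfg=cfg.model_config(), seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    shuffle_rng = np.random.default_rng((cfg.seed + 0x5EED) & 0x7FFFFFFF)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            bi = order[i:i + cfg.batch_size]
            adj = None if adjacency is None else adjacency[bi]
            probs = model.forward(X[bi], adj, training=True)
            loss = focal_loss_batch(probs, y[bi], alpha=cfg.focal_alpha,
                                    gamma=cfg.focal_gamma)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise TrainingDivergenceError(epoch)
        history.append(mean_loss)
    return model, history


def run_crossval(ws: WindowSet, cfg: TrainConfig) -> EvalReport:
    """Stratified k-fold cross-validation of the configured mode.

    Test folds are never oversampled or used for normalization statistics.
    """
    cfg.validate()
    X, y, _ = build_sequences(ws, seq_len=cfg.seq_len, seq_stride=cfg.seq_stride)
    needs_graphs = cfg.mode in ("combined", "gat_only")
    # correlation is scale/offset invariant, so adjacency can be built once
    adj_all = graphs_for_sequences(X, cfg.tau) if needs_graphs else None
    folds = stratified_kfold(y, k=cfg.n_folds, seed=cfg.seed,
                             scheme=cfg.fold_scheme)
    all_idx = np.arange(len(y))
    results: list[FoldResult] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        stats = fit_channel_stats(X[train_idx])
        bal_rng = np.random.default_rng((cfg.seed * 1000 + f) & 0x7FFFFFFF)
        rel = oversample_indices(y[train_idx], bal_rng)
        tr = train_idx[rel]
        X_tr = apply_channel_stats(X[tr], stats)
        X_te = apply_channel_stats(X[test_idx], stats)
        adj_tr = adj_all[tr] if needs_graphs else None
        adj_te = adj_all[test_idx] if needs_graphs else None
        model, _ = train_model(X_tr, adj_tr, y[tr], cfg)
        if cfg.decision_threshold == "train":
            # operating point from the *unbalanced* training fold only
            X_tr_raw = apply_channel_stats(X[train_idx], stats)
            adj_raw = adj_all[train_idx] if needs_graphs else None
            thr = select_threshold(model.predict_proba(X_tr_raw, adj_raw),
                                   y[train_idx])
        else:
            thr = float(cfg.decision_threshold)
        scores = model.predict_proba(X_te, adj_te)
        results.append(evaluate_scores(scores, y[test_idx], fold=f,
                                       threshold=thr))
    return aggregate_report(results)


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: SeizureModel, cfg: TrainConfig, path: str | Path,
                    history: list[float] | None = None) -> None:
    """Single-file NPZ archive: every tensor + config + training history."""
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    meta = {"config": asdict(cfg), "n_channels": model.n_channels,
            "samples_per_window": model.samples_per_window}
    np.savez(path, __meta__=np.array(json.dumps(meta)),
             __history__=np.array(history or [], dtype=np.float64), **arrays)


def load_checkpoint(path: str | Path) -> tuple[SeizureModel, TrainConfig, list[float]]:
    with np.load(path, allow_pickle=True) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = TrainConfig(**meta["config"])
        model = SeizureModel(n_channels=meta["n_channels"],
                             samples_per_window=meta["samples_per_window"],
                             cfg=cfg.model_config(), seed=cfg.seed)
        keys = sorted(k for k in z.files if k.startswith("param_"))
        model.load_state_arrays([z[k] for k in keys])
        history = [float(v) for v in z["__history__"]]
    return model, cfg, history
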