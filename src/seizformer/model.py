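"""The spatiotemporal classifier and its ablation variants.

A classification sample is a sequence of N consecutive 1-s windows. The
three modes mirror the ablation design:

``combined``
    every window passes the shared-weight GAT encoder over its own channel
    graph; the N spatial maps become Transformer tokens; class-token softmax.
``gat_only``
    GAT encoder per window, mean-pooled over nodes and windows, linear head.
``transformer_only``
    raw flattened windows tokenized directly (no graph stage).

Sample label = majority vote of the window labels, ties counting as seizure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, xavier_uniform
from .errors import ConfigurationError, ShapeError
from .gat import GATEncoderParams, gat_encoder, init_gat_encoder
from .graphs import adjacency_stack
from .records import WindowSet
from .transformer import TransformerParams, classify, init_transformer

MODES = ("combined", "gat_only", "transformer_only")


def build_sequences(ws: WindowSet, seq_len: int = 8,
                    seq_stride: int = 1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group consecutive windows into classification samples.

    Returns ``(X, y, starts)`` with ``X`` of shape ``(n, N, M, F)``, ``y`` the
    majority-vote labels (tie -> 1) and ``starts`` the start time of each
    sequence's first window.
    """
    if seq_len < 1 or seq_stride < 1:
        raise ConfigurationError("seq_len and seq_stride must be >= 1")
    n_win = len(ws)
    if n_win < seq_len:
        raise ShapeError(f"{n_win} windows cannot form a sequence of {seq_len}")
    data = ws.stacked()
    labels = ws.labels
    starts = ws.starts
    idx0 = np.arange(0, n_win - seq_len + 1, seq_stride)
    X = np.stack([data[i:i + seq_len] for i in idx0], axis=0)
    win_labels = np.stack([labels[i:i + seq_len] for i in idx0], axis=0)
    y = (win_labels.sum(axis=1) * 2 >= seq_len).astype(np.int64)
    return X, y, starts[idx0]


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the classifier."""

    mode: str = "combined"
    gat_hidden: int = 64        # F', width of both attention layers
    gat_heads: int = 8
    gat_activation: str = "elu"
    negative_slope: float = 0.2
    d_model: int = 128
    tx_heads: int = 4
    tx_depth: int = 4
    mlp_hidden: int | None = None     # defaults to 4 * d_model
    dropout: float = 0.5
    tau: float = 0.3                  # correlation threshold for the graphs
    seq_len: int = 8

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.d_model % self.tx_heads != 0:
            raise ConfigurationError("d_model must be divisible by tx_heads")


class SeizureModel:
    """GAT + Transformer seizure classifier (or one of its ablations).

    Parameters are created once from ``seed``; :meth:`forward` is pure given
    ``training=False`` and uses the internal rng only for dropout masks.
    """

    def __init__(self, n_channels: int, samples_per_window: int,
                 cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        self.n_channels = n_channels
        self.samples_per_window = samples_per_window
        self.rng = np.random.default_rng(seed)
        self.gat: GATEncoderParams | None = None
        self.tx: TransformerParams | None = None
        self.pool_W: Tensor | None = None
        self.pool_b: Tensor | None = None

        if cfg.mode in ("combined", "gat_only"):
            self.gat = init_gat_encoder(
                f_in=samples_per_window, hidden=cfg.gat_hidden,
                n_heads=cfg.gat_heads, rng=self.rng,
                dropout_rate=cfg.dropout, negative_slope=cfg.negative_slope,
                activation=cfg.gat_activation)
        if cfg.mode == "combined":
            slice_dim = n_channels * cfg.gat_hidden
        elif cfg.mode == "transformer_only":
            slice_dim = n_channels * samples_per_window
        else:
            slice_dim = None
        if slice_dim is not None:
            self.tx = init_transformer(
                slice_dim=slice_dim, n_tokens=cfg.seq_len, d_model=cfg.d_model,
                n_heads=cfg.tx_heads, depth=cfg.tx_depth,
                mlp_hidden=cfg.mlp_hidden, dropout_rate=cfg.dropout,
                rng=self.rng)
        if cfg.mode == "gat_only":
            self.pool_W = xavier_uniform(self.rng, cfg.gat_hidden, 2,
                                         (2, cfg.gat_hidden))
            self.pool_b = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.gat is not None:
            ps.extend(self.gat.parameters())
        if self.tx is not None:
            ps.extend(self.tx.parameters())
        if self.pool_W is not None:
            ps.extend([self.pool_W, self.pool_b])
        return ps

    def forward(self, X: np.ndarray, adjacency: np.ndarray | None,
                training: bool = False) -> Tensor:
        """Sequences ``(B, N, M, F)`` -> probabilities ``(B, 2)``.

        ``adjacency`` is ``(B, N, M, M)`` (required unless transformer_only).
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ShapeError(f"expected (B, N, M, F), got {X.shape}")
        B, N, M, F = X.shape
        rng = self.rng if training else None
        mode = self.cfg.mode

        if mode == "transformer_only":
            return classify(X.reshape(B, N, M * F), self.tx,
                            training=training, rng=rng)

        if adjacency is None:
            raise ShapeError("combined / gat_only modes need adjacency matrices")
        flat_x = as_tensor(X.reshape(B * N, M, F))
        flat_adj = np.asarray(adjacency, dtype=bool).reshape(B * N, M, M)
        maps = gat_encoder(flat_x, flat_adj, self.gat,
                           training=training, rng=rng)     # (B*N, M, F')

        if mode == "combined":
            slices = maps.reshape(B, N, M * self.cfg.gat_hidden)
            return classify(slices, self.tx, training=training, rng=rng)

        pooled = maps.reshape(B, N, M, self.cfg.gat_hidden).mean(axis=(1, 2))
        logits = pooled @ self.pool_W.swapaxes(-1, -2) + self.pool_b
        return logits.softmax(axis=-1)

    def predict_proba(self, X: np.ndarray, adjacency: np.ndarray | None,
                      batch_size: int = 256) -> np.ndarray:
        """Seizure probability per sequence, in inference mode."""
        out = []
        for i in range(0, len(X), batch_size):
            adj = None if adjacency is None else adjacency[i:i + batch_size]
            out.append(self.forward(X[i:i + batch_size], adj,
                                    training=False).data[:, 1])
        return np.concatenate(out)

    # -- checkpointing -------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ShapeError(f"checkpoint has {len(arrays)} tensors, "
                             f"model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ShapeError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def graphs_for_sequences(X: np.ndarray, tau: float) -> np.ndarray:
    """Adjacency stack ``(B, N, M, M)`` for sequence data ``(B, N, M, F)``.

    Correlation is invariant to per-channel affine normalization, so graphs
    may be built before or after z-scoring with identical results.
    """
    return adjacency_stack(X, tau)
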