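"""Multi-head graph-attention encoder over channel graphs.

One attention head on a graph with features ``h_i`` (i = 1..M) computes

    e_ij   = LeakyReLU( a^T [ W h_i || W h_j ] )        for j in V_i
    alpha  = softmax over the first-order neighborhood V_i of e_i.
    h'_i   = sigma( (1/Q) * sum_q sum_{j in V_i} alpha_ij^q  W_q h_j )

i.e. the Q heads are *averaged* (not concatenated) before the nonlinearity —
in both layers of the two-layer encoder. Neighborhoods come from the
thresholded-correlation adjacency and always contain the node itself
(self-loops), so the softmax is never over an empty set.

All forward functions are batched: features ``(..., M, F)`` with adjacency
``(..., M, M)`` broadcast over any leading dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, dropout, xavier_uniform
from .errors import ParameterError

_NEG_INF = -1e30

ACTIVATIONS = {
    "elu": lambda t: t.elu(),
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
}


@dataclass
class GATLayerParams:
    """Trainable tensors of one multi-head graph-attention layer.

    ``W`` stacks the per-head shared linear maps, shape ``(Q, F_out, F_in)``;
    ``a`` stacks the per-head attention vectors, shape ``(Q, 2 * F_out)``.
    """

    W: Tensor
    a: Tensor
    negative_slope: float = 0.2
    activation: str = "elu"

    @property
    def n_heads(self) -> int:
        return self.W.shape[0]

    @property
    def f_out(self) -> int:
        return self.W.shape[1]


def init_gat_layer(f_in: int, f_out: int, n_heads: int,
                   rng: np.random.Generator, negative_slope: float = 0.2,
                   activation: str = "elu") -> GATLayerParams:
    if n_heads < 1:
        raise ParameterError("need at least one attention head")
    if activation not in ACTIVATIONS:
        raise ParameterError(f"unknown activation {activation!r}; "
                             f"options: {sorted(ACTIVATIONS)}")
    W = xavier_uniform(rng, f_in, f_out, (n_heads, f_out, f_in))
    a = xavier_uniform(rng, 2 * f_out, 1, (n_heads, 2 * f_out))
    return GATLayerParams(W=W, a=a, negative_slope=negative_slope,
                          activation=activation)


@dataclass
class GATEncoderParams:
    """Two stacked attention layers with dropout between them."""

    layer1: GATLayerParams
    layer2: GATLayerParams
    dropout_rate: float = 0.5

    def parameters(self) -> list[Tensor]:
        return [self.layer1.W, self.layer1.a, self.layer2.W, self.layer2.a]


def init_gat_encoder(f_in: int, hidden: int, n_heads: int,
                     rng: np.random.Generator, dropout_rate: float = 0.5,
                     negative_slope: float = 0.2,
                     activation: str = "elu") -> GATEncoderParams:
    return GATEncoderParams(
        layer1=init_gat_layer(f_in, hidden, n_heads, rng, negative_slope, activation),
        layer2=init_gat_layer(hidden, hidden, n_heads, rng, negative_slope, activation),
        dropout_rate=dropout_rate,
    )


def _attention_mask(adjacency: np.ndarray) -> np.ndarray:
    """Additive logits mask: 0 on edges, -inf-like elsewhere."""
    return np.where(np.asarray(adjacency, dtype=bool), 0.0, _NEG_INF)


def _head_scores(h: Tensor, W: Tensor, a: Tensor, slope: float) -> tuple[Tensor, Tensor]:
    """Per-head projected features and raw attention logits.

    h: (..., M, F) -> Wh: (..., Q, M, F'), e: (..., Q, M, M) where
    e[..., q, i, j] = LeakyReLU(a_q . [W_q h_i || W_q h_j]).

    The projection is computed as one flat (batch*M, F) x (F, Q*F') GEMM:
    broadcasting the head axis through a batched matmul would materialize a
    (batch, Q, F, F') gradient intermediate, which dominates training time.
    """
    Q, f_out, f_in = W.shape
    lead = h.shape[:-2]
    M = h.shape[-2]
    W_flat = W.transpose(2, 0, 1).reshape(f_in, Q * f_out)
    Wh = (h.reshape(-1, f_in) @ W_flat)                 # (batch*M, Q*F')
    Wh = Wh.reshape(lead + (M, Q, f_out)).swapaxes(-2, -3)   # (..., Q, M, F')
    a1 = a[:, :f_out].reshape(Q, f_out, 1)              # source part
    a2 = a[:, f_out:].reshape(Q, f_out, 1)              # destination part
    s1 = Wh @ a1                                        # (..., Q, M, 1)
    s2 = Wh @ a2
    e = (s1 + s2.swapaxes(-1, -2)).leaky_relu(slope)    # (..., Q, M, M)
    return Wh, e


def attention_weights(h, adjacency: np.ndarray, W, a,
                      negative_slope: float = 0.2) -> np.ndarray:
    """Attention matrix of a single head, for inspection and testing.

    ``W`` is ``(F_out, F_in)`` and ``a`` has length ``2 F_out``; the result is
    a dense ``(M, M)`` row-stochastic-on-neighborhoods array with exact zeros
    off the graph's edges.
    """
    h = as_tensor(np.asarray(h, dtype=np.float64))
    Wt = as_tensor(np.asarray(W, dtype=np.float64))
    at = as_tensor(np.asarray(a, dtype=np.float64))
    Wh, e = _head_scores(h, Wt.reshape(1, *Wt.shape), at.reshape(1, -1),
                         negative_slope)
    mask = _attention_mask(adjacency)
    alpha = e.softmax(axis=-1, mask=mask[None])
    return alpha.data[0]


def gat_layer(h, adjacency: np.ndarray, params: GATLayerParams) -> Tensor:
    """One batched multi-head attention layer; heads averaged, then sigma."""
    h = as_tensor(h)
    Wh, e = _head_scores(h, params.W, params.a, params.negative_slope)
    mask = _attention_mask(adjacency)
    # broadcast mask over the head axis: (..., M, M) -> (..., 1, M, M)
    mask = np.expand_dims(mask, -3)
    alpha = e.softmax(axis=-1, mask=mask)
    per_head = alpha @ Wh                       # (..., Q, M, F')
    averaged = per_head.mean(axis=-3)           # (..., M, F')
    return ACTIVATIONS[params.activation](averaged)


def gat_encoder(window_features, adjacency: np.ndarray,
                params: GATEncoderParams, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
    """Two attention layers with dropout on the hidden features.

    ``window_features``: ``(..., M, F)`` raw (normalized) window samples;
    ``adjacency``: matching ``(..., M, M)`` binary matrices. Returns the
    spatially aggregated map ``(..., M, F')``.
    """
    h = gat_layer(window_features, adjacency, params.layer1)
    if training:
        if rng is None:
            raise ParameterError("training-mode dropout needs an rng")
        h = dropout(h, params.dropout_rate, rng, training)
    return gat_layer(h, adjacency, params.layer2)
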