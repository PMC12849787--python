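"""Temporal Transformer encoder and softmax classification head.

A classification sample is a sequence of N spatial feature maps (one per
1-s window). Each map is flattened, linearly projected to the model width D,
a learned class token is prepended, and a fixed sinusoidal positional table
is added (position 0 = class token)::

    H_0 = [ k_class, E k_1, ..., E k_N ] + E_pos

The encoder stacks L pre-norm residual blocks

    H'_l = MSA(LN(H_{l-1})) + H_{l-1}
    H_l  = MLP(LN(H'_l))    + H'_l

with standard scaled dot-product multi-head self-attention and a two-layer
GELU MLP. The final class-token state passes through LayerNorm, a linear map
to two logits, and softmax to give (p_non_seizure, p_seizure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, dropout, xavier_uniform
from .errors import ParameterError, ShapeError

LN_EPS = 1e-5


def positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal table, ``PE[p, 2i] = sin(p / 10000^(2i/D))`` and
    ``PE[p, 2i+1] = cos`` of the same argument. ``d_model`` must be even."""
    if d_model % 2 != 0:
        raise ParameterError(f"d_model must be even, got {d_model}")
    pos = np.arange(n_positions, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / d_model)
    pe = np.empty((n_positions, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _linear_init(rng, f_in, f_out):
    W = xavier_uniform(rng, f_in, f_out, (f_out, f_in))
    b = Tensor(np.zeros(f_out), requires_grad=True)
    return W, b


@dataclass
class EncoderBlockParams:
    ln1_g: Tensor; ln1_b: Tensor
    Wq: Tensor; bq: Tensor
    Wk: Tensor; bk: Tensor
    Wv: Tensor; bv: Tensor
    Wo: Tensor; bo: Tensor
    ln2_g: Tensor; ln2_b: Tensor
    W1: Tensor; b1: Tensor
    W2: Tensor; b2: Tensor
    n_heads: int = 4

    def parameters(self) -> list[Tensor]:
        return [self.ln1_g, self.ln1_b, self.Wq, self.bq, self.Wk, self.bk,
                self.Wv, self.bv, self.Wo, self.bo, self.ln2_g, self.ln2_b,
                self.W1, self.b1, self.W2, self.b2]


@dataclass
class TransformerParams:
    """All trainable tensors of the temporal classifier."""

    E: Tensor                 # (D, slice_dim) token projection
    E_b: Tensor               # (D,)
    class_token: Tensor       # (D,)
    E_pos: np.ndarray         # fixed (N+1, D) sinusoidal table
    blocks: list[EncoderBlockParams]
    head_ln_g: Tensor
    head_ln_b: Tensor
    W_head: Tensor            # (2, D)
    b_head: Tensor            # (2,)
    dropout_rate: float = 0.5

    @property
    def d_model(self) -> int:
        return self.E.shape[0]

    @property
    def depth(self) -> int:
        return len(self.blocks)

    def parameters(self) -> list[Tensor]:
        ps = [self.E, self.E_b, self.class_token]
        for blk in self.blocks:
            ps.extend(blk.parameters())
        ps.extend([self.head_ln_g, self.head_ln_b, self.W_head, self.b_head])
        return ps


def init_encoder_block(d_model: int, n_heads: int, mlp_hidden: int,
                       rng: np.random.Generator) -> EncoderBlockParams:
    if d_model % n_heads != 0:
        raise ParameterError(f"d_model {d_model} not divisible by {n_heads} heads")
    Wq, bq = _linear_init(rng, d_model, d_model)
    Wk, bk = _linear_init(rng, d_model, d_model)
    Wv, bv = _linear_init(rng, d_model, d_model)
    Wo, bo = _linear_init(rng, d_model, d_model)
    W1, b1 = _linear_init(rng, d_model, mlp_hidden)
    W2, b2 = _linear_init(rng, mlp_hidden, d_model)
    ones = lambda: Tensor(np.ones(d_model), requires_grad=True)
    zeros = lambda: Tensor(np.zeros(d_model), requires_grad=True)
    return EncoderBlockParams(ln1_g=ones(), ln1_b=zeros(),
                              Wq=Wq, bq=bq, Wk=Wk, bk=bk, Wv=Wv, bv=bv,
                              Wo=Wo, bo=bo, ln2_g=ones(), ln2_b=zeros(),
                              W1=W1, b1=b1, W2=W2, b2=b2, n_heads=n_heads)


def init_transformer(slice_dim: int, n_tokens: int, d_model: int = 128,
                     n_heads: int = 4, depth: int = 4,
                     mlp_hidden: int | None = None, dropout_rate: float = 0.5,
                     rng: np.random.Generator | None = None) -> TransformerParams:
    """Build parameters for sequences of ``n_tokens`` slices of ``slice_dim``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    mlp_hidden = mlp_hidden if mlp_hidden is not None else 4 * d_model
    E, E_b = _linear_init(rng, slice_dim, d_model)
    class_token = Tensor(0.02 * rng.standard_normal(d_model), requires_grad=True)
    blocks = [init_encoder_block(d_model, n_heads, mlp_hidden, rng)
              for _ in range(depth)]
    Wh, bh = _linear_init(rng, d_model, 2)
    return TransformerParams(
        E=E, E_b=E_b, class_token=class_token,
        E_pos=positional_encoding(n_tokens + 1, d_model),
        blocks=blocks,
        head_ln_g=Tensor(np.ones(d_model), requires_grad=True),
        head_ln_b=Tensor(np.zeros(d_model), requires_grad=True),
        W_head=Wh, b_head=bh, dropout_rate=dropout_rate,
    )


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = LN_EPS) -> Tensor:
    """LayerNorm over the last axis, composed from differentiable primitives."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps).pow(-0.5) * gamma + beta


def tokenize(slices, params: TransformerParams) -> Tensor:
    """Flattened slices ``(B, N, slice_dim)`` -> token sequence ``(B, N+1, D)``.

    Projects each slice with E, prepends the class token at position 0 and
    adds the fixed positional table row-wise.
    """
    x = as_tensor(slices)
    if x.ndim == 2:
        x = x.reshape(1, *x.shape)
    B, N, sdim = x.shape
    if sdim != params.E.shape[1]:
        raise ShapeError(f"slice dim {sdim} does not match projection "
                         f"input {params.E.shape[1]}")
    if N + 1 != params.E_pos.shape[0]:
        raise ShapeError(f"{N} slices but positional table has "
                         f"{params.E_pos.shape[0]} rows (expects N+1)")
    tok = x @ params.E.swapaxes(-1, -2) + params.E_b          # (B, N, D)
    cls = params.class_token.reshape(1, 1, -1) + Tensor(np.zeros((B, 1, 1)))
    H = concat([cls, tok], axis=1)
    return H + Tensor(params.E_pos[None])


def multi_head_self_attention(H: Tensor, blk: EncoderBlockParams) -> Tensor:
    """Scaled dot-product self-attention over the token axis, batched."""
    B, T, D = H.shape
    nh = blk.n_heads
    dh = D // nh
    def split(x):   # (B, T, D) -> (B, nh, T, dh)
        return x.reshape(B, T, nh, dh).transpose(0, 2, 1, 3)
    q = split(H @ blk.Wq.swapaxes(-1, -2) + blk.bq)
    k = split(H @ blk.Wk.swapaxes(-1, -2) + blk.bk)
    v = split(H @ blk.Wv.swapaxes(-1, -2) + blk.bv)
    att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    att = att.softmax(axis=-1)
    ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
    return ctx @ blk.Wo.swapaxes(-1, -2) + blk.bo


def encoder_block(H: Tensor, blk: EncoderBlockParams, training: bool = False,
                  rng: np.random.Generator | None = None,
                  dropout_rate: float = 0.0) -> Tensor:
    """One pre-norm residual block: attention sub-layer then MLP sub-layer."""
    H1 = multi_head_self_attention(layer_norm(H, blk.ln1_g, blk.ln1_b), blk) + H
    z = layer_norm(H1, blk.ln2_g, blk.ln2_b)
    z = (z @ blk.W1.swapaxes(-1, -2) + blk.b1).gelu()
    if training and rng is not None:
        z = dropout(z, dropout_rate, rng, training)
    z = z @ blk.W2.swapaxes(-1, -2) + blk.b2
    return z + H1


def encode(slices, params: TransformerParams, training: bool = False,
           rng: np.random.Generator | None = None) -> Tensor:
    H = tokenize(slices, params)
    if training and rng is not None and params.dropout_rate > 0:
        # embedding dropout on the slice tokens only: zeroing the class
        # token row would sever the classification pathway at random
        mask = ((rng.random(H.shape) >= params.dropout_rate)
                / (1.0 - params.dropout_rate))
        mask[:, 0, :] = 1.0
        H = H * Tensor(mask)
    for blk in params.blocks:
        H = encoder_block(H, blk, training=training, rng=rng,
                          dropout_rate=params.dropout_rate)
    return H


def classify(slices, params: TransformerParams, training: bool = False,
             rng: np.random.Generator | None = None) -> Tensor:
    """Probabilities ``(B, 2)`` = (p_non_seizure, p_seizure); rows sum to 1."""
    H = encode(slices, params, training=training, rng=rng)
    cls = H[:, 0, :]
    cls = layer_norm(cls, params.head_ln_g, params.head_ln_b)
    logits = cls @ params.W_head.swapaxes(-1, -2) + params.b_head
    return logits.softmax(axis=-1)
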