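"""Independent loop-based reference implementations used only by tests.

These deliberately avoid the package's vectorized/autodiff code paths:
everything is plain numpy with explicit loops, so agreement between the two
routes is meaningful evidence of correctness.
"""

import numpy as np
from scipy.special import erf


def pearson_oracle(x, y):
    """Textbook covariance / (std * std), via explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


def _act(name):
    if name == "elu":
        return lambda v: np.where(v > 0, v, np.expm1(v))
    if name == "relu":
        return lambda v: np.maximum(v, 0.0)
    return lambda v: v


def gat_attention_oracle(h, adj, W, a, slope):
    """Dense single-head attention: mask non-edges with -inf before softmax."""
    M = h.shape[0]
    Wh = np.array([W @ h[j] for j in range(M)])
    alpha = np.zeros((M, M))
    for i in range(M):
        e = np.full(M, -np.inf)
        for j in range(M):
            if adj[i, j]:
                z = float(a @ np.concatenate([Wh[i], Wh[j]]))
                e[j] = z if z > 0 else slope * z
        finite = np.isfinite(e)
        w = np.zeros(M)
        w[finite] = np.exp(e[finite] - e[finite].max())
        alpha[i] = w / w.sum()
    return alpha


def gat_layer_oracle(h, adj, W, a, slope, activation="elu"):
    """Triple loop over (head, node, neighbor); heads averaged then sigma."""
    Q = W.shape[0]
    M = h.shape[0]
    f_out = W.shape[1]
    acc = np.zeros((M, f_out))
    for q in range(Q):
        Whq = np.array([W[q] @ h[j] for j in range(M)])
        alpha = gat_attention_oracle(h, adj, W[q], a[q], slope)
        for i in range(M):
            for j in range(M):
                acc[i] += alpha[i, j] * Whq[j] / Q
    return _act(activation)(acc)


def layer_norm_oracle(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


def gelu_oracle(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def msa_oracle(H, blk):
    """Loop-based scaled dot-product multi-head self-attention on (T, D)."""
    T, D = H.shape
    nh = blk.n_heads
    dh = D // nh
    q = H @ blk.Wq.data.T + blk.bq.data
    k = H @ blk.Wk.data.T + blk.bk.data
    v = H @ blk.Wv.data.T + blk.bv.data
    out = np.zeros((T, D))
    for head in range(nh):
        sl = slice(head * dh, (head + 1) * dh)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        for t in range(T):
            scores = np.array([qh[t] @ kh[s] for s in range(T)]) / np.sqrt(dh)
            w = np.exp(scores - scores.max())
            w /= w.sum()
            out[t, sl] = sum(w[s] * vh[s] for s in range(T))
    return out @ blk.Wo.data.T + blk.bo.data


def encoder_block_oracle(H, blk):
    """Pre-norm residual block on one (T, D) sequence."""
    H1 = msa_oracle(layer_norm_oracle(H, blk.ln1_g.data, blk.ln1_b.data), blk) + H
    z = layer_norm_oracle(H1, blk.ln2_g.data, blk.ln2_b.data)
    z = gelu_oracle(z @ blk.W1.data.T + blk.b1.data)
    return z @ blk.W2.data.T + blk.b2.data + H1


def tokenize_oracle(slices, params):
    """Flatten -> project -> prepend class token -> add positions, by loops."""
    N = slices.shape[0]
    D = params.E.shape[0]
    H = np.zeros((N + 1, D))
    H[0] = params.class_token.data
    for t in range(N):
        H[t + 1] = params.E.data @ slices[t] + params.E_b.data
    return H + params.E_pos


def auc_concordance_oracle(scores, labels):
    """Pairwise concordance count (ties = 1/2) over all pos/neg pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def confusion_oracle(pred, true):
    tp = fp = tn = fn = 0
    for p, t in zip(pred, true):
        if p == 1 and t == 1:
            tp += 1
        elif p == 1 and t == 0:
            fp += 1
        elif p == 0 and t == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def random_connected_adjacency(rng, M):
    """Symmetric binary adjacency with self-loops (edge prob 0.5)."""
    upper = rng.random((M, M)) < 0.5
    adj = np.triu(upper, 1)
    adj = adj | adj.T
    np.fill_diagonal(adj, True)
    return adj
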