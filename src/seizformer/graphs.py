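"""Functional-connectivity channel graphs from windowed EEG.

For each window the pairwise Pearson correlation matrix of the channels is
computed, thresholded on |r| into a binary adjacency (with self-loops), and
the raw per-channel samples become the node features. The conventional
verbal strength bands (very weak < 0.2 <= weak < 0.4 <= moderate < 0.6 <=
strong < 0.8 <= very strong) are exposed for inspection.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GraphInvariantError, ParameterError, ShapeError
from .records import Window

DEFAULT_TAU = 0.3


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation r = C(X,Y) / (S(X) S(Y)), in [-1, 1].

    A zero-variance input yields r = 0 by convention (degenerate channels
    stay unconnected rather than producing NaNs).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ShapeError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ShapeError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip(np.dot(xc, yc) / (sx * sy), -1.0, 1.0))


def correlation_matrix(w: Window | np.ndarray) -> np.ndarray:
    """M x M symmetric Pearson matrix of a window's channels.

    Degenerate (constant) channels get 0 off-diagonal and 1 on the diagonal.
    """
    data = w.data if isinstance(w, Window) else np.asarray(w, dtype=np.float64)
    if data.shape[0] < 2:
        raise ShapeError("need at least 2 channels")
    std = data.std(axis=1)
    ok = std > 0
    c = np.eye(data.shape[0])
    if ok.sum() >= 2:
        sub = np.corrcoef(data[ok])
        c[np.ix_(ok, ok)] = np.clip(sub, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


class CorrelationStrength(enum.Enum):
    VERY_WEAK = "very weak or no correlation"
    WEAK = "weak correlation"
    MODERATE = "moderate correlation"
    STRONG = "strong correlation"
    VERY_STRONG = "very strong correlation"


def strength_category(r: float) -> CorrelationStrength:
    """Verbal strength band of |r|; bands are left-closed, right-open except
    the top band which includes 1.0 exactly."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise DomainError(f"|r| must be <= 1, got {r}")
    a = min(a, 1.0)
    if a < 0.2:
        return CorrelationStrength.VERY_WEAK
    if a < 0.4:
        return CorrelationStrength.WEAK
    if a < 0.6:
        return CorrelationStrength.MODERATE
    if a < 0.8:
        return CorrelationStrength.STRONG
    return CorrelationStrength.VERY_STRONG


@dataclass
class ChannelGraph:
    """Binary channel graph for one window.

    ``adjacency`` is symmetric with unit diagonal (self-loops, so every
    neighborhood is non-empty); ``node_features`` are the raw window samples,
    one row per channel.
    """

    adjacency: np.ndarray      # (M, M) uint8
    node_features: np.ndarray  # (M, F)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ShapeError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise GraphInvariantError("adjacency must be symmetric")
        if not np.all((a == 0) | (a == 1)):
            raise GraphInvariantError("adjacency must be binary")
        if not np.all(np.diag(a) == 1):
            raise GraphInvariantError("adjacency must carry self-loops")
        if a.shape[0] != self.node_features.shape[0]:
            raise ShapeError("adjacency and node_features disagree on M")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def neighborhood(self, i: int) -> np.ndarray:
        """First-order neighborhood V_i (includes i via its self-loop)."""
        return np.flatnonzero(self.adjacency[i])


def threshold_adjacency(corr: np.ndarray, tau: float) -> np.ndarray:
    """|r| >= tau keeps an edge (strong anticorrelation also connects);
    self-loops are always present."""
    if not 0 < tau < 1:
        raise ParameterError(f"tau must be in (0, 1), got {tau}")
    adj = (np.abs(corr) >= tau).astype(np.uint8)
    np.fill_diagonal(adj, 1)
    return adj


def build_graph(w: Window, tau: float = DEFAULT_TAU) -> ChannelGraph:
    """Window -> thresholded-correlation graph with raw-signal node features."""
    corr = correlation_matrix(w)
    return ChannelGraph(adjacency=threshold_adjacency(corr, tau),
                        node_features=np.asarray(w.data, dtype=np.float64))


def adjacency_stack(windows_data: np.ndarray, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Vectorized batch form: (..., M, F) signals -> (..., M, M) adjacencies."""
    lead = windows_data.shape[:-2]
    flat = windows_data.reshape((-1,) + windows_data.shape[-2:])
    out = np.empty((flat.shape[0], flat.shape[1], flat.shape[1]), dtype=np.uint8)
    for i, d in enumerate(flat):
        out[i] = threshold_adjacency(correlation_matrix(d), tau)
    return out.reshape(lead + out.shape[-2:])


def dump_graph_csv(graph: ChannelGraph, corr: np.ndarray,
                   edges_path, corr_path) -> None:
    """Inspection dump: edge list (i, j) and the raw correlation matrix."""
    with open(edges_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i", "j"])
        ii, jj = np.nonzero(np.triu(graph.adjacency, k=1))
        for i, j in zip(ii, jj):
            w.writerow([int(i), int(j)])
    np.savetxt(corr_path, corr, delimiter=",", fmt="%.6f")
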