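"""Pearson correlation, strength bands, and thresholded adjacency graphs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seizformer as sz
from oracles import pearson_oracle
from seizformer.errors import DomainError, GraphInvariantError, ShapeError
from seizformer.graphs import (CorrelationStrength, build_graph,
                               threshold_adjacency)


def window_with_correlations(target: np.ndarray, n: int = 512,
                             seed: int = 0) -> sz.Window:
    """Channels whose *sample* correlation matrix equals ``target`` exactly.

    Random data is empirically whitened and then colored with the Cholesky
    factor of the target, so np.corrcoef reproduces it to rounding error.
    """
    rng = np.random.default_rng(seed)
    M = target.shape[0]
    x = rng.standard_normal((M, n))
    x -= x.mean(axis=1, keepdims=True)
    cov = x @ x.T / n
    white = np.linalg.inv(np.linalg.cholesky(cov)) @ x
    colored = np.linalg.cholesky(target) @ white
    return sz.Window(data=colored, label=0, start_s=0.0)


class TestPearson:
    def test_self_and_negated_self(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert sz.pearson(x, x) == pytest.approx(1.0)
        assert sz.pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example_matches_textbook_formula(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        assert sz.pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40)
            assert sz.pearson(x, y) == pytest.approx(pearson_oracle(x, y),
                                                     abs=1e-12)

    def test_zero_variance_convention(self):
        assert sz.pearson(np.ones(10), np.arange(10.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            sz.pearson(np.ones(5), np.ones(6))


class TestCorrelationMatrix:
    def test_identical_channels_give_all_ones(self):
        row = np.sin(np.arange(64.0))
        w = sz.Window(data=np.tile(row, (4, 1)), label=0, start_s=0.0)
        assert np.allclose(sz.correlation_matrix(w), 1.0)

    def test_matches_elementwise_pearson(self):
        rng = np.random.default_rng(3)
        w = sz.Window(data=rng.standard_normal((5, 100)), label=0, start_s=0.0)
        c = sz.correlation_matrix(w)
        for i in range(5):
            for j in range(5):
                assert c[i, j] == pytest.approx(
                    sz.pearson(w.data[i], w.data[j]), abs=1e-12)

    def test_long_independent_noise_nearly_diagonal(self):
        rng = np.random.default_rng(4)
        w = sz.Window(data=rng.standard_normal((6, 2560)), label=0, start_s=0.0)
        c = sz.correlation_matrix(w)
        off = c[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.2

    def test_degenerate_channel_isolated(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 50))
        data[1] = 7.0
        c = sz.correlation_matrix(sz.Window(data=data, label=0, start_s=0.0))
        assert c[1, 1] == 1.0
        assert c[1, 0] == c[1, 2] == 0.0


class TestStrengthCategory:
    @pytest.mark.parametrize("r, expected", [
        (0.0, CorrelationStrength.VERY_WEAK),
        (0.19, CorrelationStrength.VERY_WEAK),
        (0.2, CorrelationStrength.WEAK),
        (0.4, CorrelationStrength.MODERATE),
        (0.6, CorrelationStrength.STRONG),
        (0.69, CorrelationStrength.STRONG),
        (0.8, CorrelationStrength.VERY_STRONG),
        (0.86, CorrelationStrength.VERY_STRONG),
        (1.0, CorrelationStrength.VERY_STRONG),
        (-0.75, CorrelationStrength.STRONG),
    ])
    def test_band_assignment(self, r, expected):
        assert sz.strength_category(r) is expected

    def test_out_of_domain_rejected(self):
        with pytest.raises(DomainError):
            sz.strength_category(1.2)


class TestBuildGraph:
    def test_tau_extremes(self):
        rng = np.random.default_rng(6)
        w = sz.Window(data=rng.standard_normal((4, 256)), label=0, start_s=0.0)
        corr = sz.correlation_matrix(w)
        off = np.abs(corr[~np.eye(4, dtype=bool)])
        above_all = build_graph(w, tau=min(0.999, off.max() + 1e-6))
        assert np.array_equal(above_all.adjacency, np.eye(4, dtype=np.uint8))
        near_zero = build_graph(w, tau=1e-6)
        assert np.all(near_zero.adjacency == 1)

    def test_handset_correlations_produce_expected_edges(self):
        target = np.array([[1.0, 0.9, 0.1],
                           [0.9, 1.0, 0.5],
                           [0.1, 0.5, 1.0]])
        w = window_with_correlations(target, seed=7)
        g = build_graph(w, tau=0.3)
        expected = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=np.uint8)
        assert np.array_equal(g.adjacency, expected)
        assert g.neighborhood(0).tolist() == [0, 1]

    def test_boundary_correlation_counts_as_edge(self):
        target = np.array([[1.0, 0.5], [0.5, 1.0]])
        w = window_with_correlations(target, seed=8)
        g = build_graph(w, tau=0.5 - 1e-9)
        assert g.adjacency[0, 1] == 1

    def test_anticorrelation_also_connects(self):
        target = np.array([[1.0, -0.8], [-0.8, 1.0]])
        w = window_with_correlations(target, seed=9)
        assert build_graph(w, tau=0.5).adjacency[0, 1] == 1

    @given(seed=st.integers(0, 50))
    def test_adjacency_symmetric_binary_monotone_in_tau(self, seed):
        rng = np.random.default_rng(seed)
        w = sz.Window(data=rng.standard_normal((5, 64)), label=0, start_s=0.0)
        prev_edges = None
        for tau in (0.1, 0.3, 0.5, 0.7, 0.9):
            adj = build_graph(w, tau=tau).adjacency
            assert np.array_equal(adj, adj.T)
            assert set(np.unique(adj)) <= {0, 1}
            assert np.all(np.diag(adj) == 1)
            edges = {(i, j) for i, j in zip(*np.nonzero(adj))}
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_graph_dump_writes_edge_list_and_matrix(self, tmp_path):
        target = np.array([[1.0, 0.9, 0.1],
                           [0.9, 1.0, 0.5],
                           [0.1, 0.5, 1.0]])
        w = window_with_correlations(target, seed=7)
        corr = sz.correlation_matrix(w)
        g = build_graph(w, tau=0.3)
        from seizformer.graphs import dump_graph_csv
        dump_graph_csv(g, corr, tmp_path / "edges.csv", tmp_path / "corr.csv")
        edges = (tmp_path / "edges.csv").read_text().strip().splitlines()
        assert edges[0] == "i,j"
        assert set(edges[1:]) == {"0,1", "1,2"}
        back = np.loadtxt(tmp_path / "corr.csv", delimiter=",")
        assert np.allclose(back, corr, atol=1e-6)

    def test_invariants_enforced_on_construction(self):
        with pytest.raises(GraphInvariantError):
            sz.ChannelGraph(adjacency=np.array([[1, 1], [0, 1]]),
                            node_features=np.zeros((2, 4)))
        with pytest.raises(GraphInvariantError):
            sz.ChannelGraph(adjacency=np.zeros((2, 2), dtype=int),
                            node_features=np.zeros((2, 4)))
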