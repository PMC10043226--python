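"""Synthetic network and excitability-profile generators."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from epileptornet.dynamics import ModelParams
from epileptornet.errors import ParameterError
from epileptornet.synthetic import (
    ConnectivityMatrix,
    FocalTopologySpec,
    build_base_network,
    build_focal_adjacency,
    build_sparse_random_network,
    build_study_network,
    embed_focal,
    sample_x0,
)


class TestBaseNetwork:
    def test_inverse_ring_distance_weights(self):
        net = build_base_network(4)
        assert net.weights[0, 1] == 1.0
        assert net.weights[0, 2] == 0.5
        assert net.weights[0, 3] == 1.0  # wraps around the ring

    def test_fully_connected_contract(self):
        net = build_base_network(17)
        off = ~np.eye(17, dtype=bool)
        assert np.all(net.weights[off] > 0)
        assert np.all(np.diag(net.weights) == 0)
        assert np.array_equal(net.weights, net.weights.T)

    def test_minimum_weight_is_inverse_half_ring(self):
        net = build_base_network(100)
        assert net.weights[net.weights > 0].min() == pytest.approx(1 / 50)

    def test_too_small(self):
        with pytest.raises(ParameterError):
            build_base_network(1)


class TestSparseRandomNetwork:
    def test_seeded_determinism(self):
        a = build_sparse_random_network(50, 0.1, seed=7)
        b = build_sparse_random_network(50, 0.1, seed=7)
        assert np.array_equal(a.weights, b.weights)

    def test_edge_count_matches_binomial_expectation(self):
        n, density, m = 100, 0.1, 100 * 99 // 2
        counts = [
            np.count_nonzero(np.triu(
                build_sparse_random_network(n, density, seed=s).weights))
            for s in range(50)
        ]
        se = np.sqrt(m * density * (1 - density) / 50)
        assert abs(np.mean(counts) - density * m) < 3 * se

    def test_uniform_weight(self):
        net = build_sparse_random_network(30, 0.2, weight=2.5, seed=0)
        vals = np.unique(net.weights)
        assert set(vals.tolist()) <= {0.0, 2.5}

    @pytest.mark.parametrize("density", [0.0, 1.0, -0.2])
    def test_rejects_degenerate_density(self, density):
        with pytest.raises(ParameterError):
            build_sparse_random_network(10, density)


class TestFocalAdjacency:
    def test_regular_ring_degrees(self):
        spec = FocalTopologySpec(n_focal=10, family="regular", k=2)
        adj = build_focal_adjacency(spec, seed=0)
        assert np.all(adj.sum(axis=1) == 2)

    def test_smallworld_p0_reduces_to_regular(self):
        reg = build_focal_adjacency(
            FocalTopologySpec(n_focal=12, family="regular", k=4), seed=3)
        sw0 = build_focal_adjacency(
            FocalTopologySpec(n_focal=12, family="smallworld", p=0.0, k=4),
            seed=3)
        assert np.array_equal(reg, sw0)

    def test_clustering_drops_with_rewiring(self):
        # small-world sanity: ring lattice clusters, full rewiring does not
        def mean_clustering(family, p):
            cs = []
            for s in range(5):
                adj = build_focal_adjacency(
                    FocalTopologySpec(n_focal=24, family=family, p=p, k=4),
                    seed=s)
                cs.append(nx.average_clustering(nx.from_numpy_array(adj)))
            return np.mean(cs)

        assert mean_clustering("regular", 0.0) > mean_clustering("random", 1.0)

    def test_scalefree_heavy_tail(self):
        spec = FocalTopologySpec(n_focal=30, family="scalefree", gamma_sf=2.5)
        degs = []
        for s in range(100):
            adj = build_focal_adjacency(spec, seed=s)
            assert nx.is_connected(nx.from_numpy_array(adj))
            degs.extend(adj.sum(axis=1).tolist())
        degs = np.asarray(degs)
        assert degs.min() >= 1
        # heavier tail than an ER graph of the same mean degree
        er_var = degs.mean()  # Poisson variance
        assert degs.var() > er_var
        # empirical log-log degree distribution has negative slope
        ks, counts = np.unique(degs, return_counts=True)
        slope = np.polyfit(np.log(ks), np.log(counts), 1)[0]
        assert slope < 0

    @pytest.mark.parametrize("bad", [
        dict(n_focal=1), dict(p=1.5), dict(k=5), dict(k=10),
        dict(family="scalefree", gamma_sf=0.5), dict(strength_factor=1.0),
    ])
    def test_spec_validation(self, bad):
        kwargs = dict(n_focal=10, family="smallworld", k=4)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            FocalTopologySpec(**kwargs)


class TestEmbedFocal:
    def test_embedded_edges_get_prominent_weight(self):
        base = build_base_network(20)
        spec = FocalTopologySpec(n_focal=4, family="regular", k=2)
        adj = build_focal_adjacency(spec, seed=0)
        net = embed_focal(base, adj, range(4), strength_factor=10)
        for a in range(4):
            for b in range(4):
                if adj[a, b]:
                    assert net.weights[a, b] == 10.0  # 10 * max(base) = 10

    def test_empty_adjacency_is_identity(self):
        base = build_base_network(10)
        net = embed_focal(base, np.zeros((3, 3), int), [0, 1, 2], 5.0)
        assert np.array_equal(net.weights, base.weights)

    def test_prominence_contract(self):
        net = build_study_network(
            30, FocalTopologySpec(n_focal=6, family="smallworld", p=0.3, k=2),
            seed=4)
        strong = 10.0  # strength_factor * max(base weight) = 10 * 1
        rows, cols = np.nonzero(net.weights == strong)
        assert len(rows) > 0
        # prominent edges connect focal nodes only ...
        assert set(rows.tolist()) <= set(net.focal_indices)
        # ... and strictly dominate every other weight
        others = net.weights[net.weights != strong]
        assert others.max() < strong

    def test_index_out_of_range(self):
        base = build_base_network(5)
        with pytest.raises(ParameterError):
            embed_focal(base, np.ones((2, 2), int) - np.eye(2, dtype=int),
                        [0, 7], 10.0)


class TestSampleX0:
    def test_sigma_zero_is_exactly_mu(self, params):
        prof = sample_x0(10, range(4), mu=-1.6, sigma=0.0, seed=0)
        assert np.all(prof.x0_values[:4] == -1.6)
        assert np.all(prof.x0_values[4:] == -2.2)

    def test_truncation_respects_threshold(self, params):
        prof = sample_x0(400, range(400), mu=-2.0, sigma=0.3,
                         x0_nonfocal=-2.2, seed=1)
        assert np.all(prof.x0_values > params.x_threshold)

    def test_matches_truncated_normal_moment(self, params):
        # independent oracle: scipy's truncated normal mean
        mu, sigma = -1.6, 0.1
        prof = sample_x0(10_000, range(10_000), mu=mu, sigma=sigma, seed=2)
        a = (params.x_threshold - mu) / sigma
        expected = stats.truncnorm.mean(a, np.inf, loc=mu, scale=sigma)
        se = stats.truncnorm.std(a, np.inf, loc=mu, scale=sigma) / 100
        assert abs(prof.x0_values.mean() - expected) < 3 * se

    def test_seeded_determinism(self):
        a = sample_x0(50, range(10), sigma=0.1, seed=9)
        b = sample_x0(50, range(10), sigma=0.1, seed=9)
        assert np.array_equal(a.x0_values, b.x0_values)

    @pytest.mark.parametrize("bad", [
        dict(mu=-2.1),            # at/below threshold
        dict(sigma=-0.1),
        dict(x0_nonfocal=-1.9),   # not healthy
    ])
    def test_precondition_validation(self, bad):
        kwargs = dict(n_total=10, focal_indices=range(3), mu=-1.6,
                      sigma=0.1, x0_nonfocal=-2.2)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            sample_x0(**kwargs)


class TestConnectivityMatrixInvariants:
    @pytest.mark.parametrize("bad_weights", [
        np.array([[0.0, 1.0], [2.0, 0.0]]),   # asymmetric
        np.array([[1.0, 1.0], [1.0, 0.0]]),   # nonzero diagonal
        np.array([[0.0, -1.0], [-1.0, 0.0]]),  # negative
    ])
    def test_rejects_invalid(self, bad_weights):
        with pytest.raises(ParameterError):
            ConnectivityMatrix(weights=bad_weights)

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        family=st.sampled_from(["regular", "smallworld", "random", "scalefree"]),
        n_focal=st.integers(4, 10),
    )
    def test_study_networks_satisfy_invariants(self, seed, family, n_focal):
        spec = FocalTopologySpec(n_focal=n_focal, family=family, p=0.3,
                                 gamma_sf=2.5, k=2)
        net = build_study_network(25, spec, seed=seed)
        w = net.weights
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.all(w >= 0)
        off = ~np.eye(25, dtype=bool)
        assert np.all(w[off] > 0)  # still fully connected
        strong = w == w.max()
        rows, cols = np.nonzero(strong)
        assert set(rows) <= set(net.focal_indices)
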