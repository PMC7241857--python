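import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from hubnet import ensembles as ens


class TestScaleFreeDegrees:
    def test_sample_mean_matches_discretized_pareto(self):
        """Sampled degree mean agrees with the exact rounded-Pareto mean."""
        gamma, k_min, n = 3.0, 2.0, 100_000
        k = ens.sample_scale_free_degrees(gamma, k_min, n, rng=1)
        exact = ens.discretized_pareto_mean(gamma, k_min)
        # continuous Pareto mean k_min(gamma-1)/(gamma-2) = 4; discretization
        # shifts it only slightly
        assert abs(exact - 4.0) < 0.25
        sem = k.std() / np.sqrt(n)
        assert abs(k.mean() - exact) < 4 * sem

    def test_support_boundary_and_clamping(self):
        k = ens.sample_scale_free_degrees(2.2, 1.0, 1500, rng=2)
        assert k.min() >= 1
        assert k.max() <= 1499

    def test_heavy_tail_mean_near_five(self):
        """gamma=2.2, k_min=1 realizations have mean degree of order 5-6."""
        means = [
            ens.sample_scale_free_degrees(2.2, 1.0, 1500, rng=seed).mean()
            for seed in range(30)
        ]
        assert 3.0 < np.median(means) < 9.0

    @pytest.mark.parametrize("gamma,k_min", [(2.0, 1.0), (1.5, 1.0), (2.5, 0.0), (2.5, -1.0)])
    def test_invalid_parameters_rejected(self, gamma, k_min):
        with pytest.raises(ValueError):
            ens.sample_scale_free_degrees(gamma, k_min, 10, rng=0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        gamma=st.floats(2.05, 5.0),
        k_min=st.floats(0.3, 4.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_degrees_always_valid_integers(self, gamma, k_min, seed):
        """Any admissible (gamma, k_min) yields integer degrees in [1, n-1]."""
        k = ens.sample_scale_free_degrees(gamma, k_min, 50, rng=seed)
        assert k.dtype.kind == "i"
        assert k.min() >= 1 and k.max() <= 49

    def test_survival_tail_slope(self):
        """Log-log survival slope of sampled degrees is -(gamma - 1)."""
        gamma, k_min = 2.5, 1.0
        k = ens.sample_scale_free_degrees(gamma, k_min, 1_000_000, rng=3)
        ks = np.unique(np.geomspace(10, 2000, 12).astype(int))
        surv = np.array([(k >= x).mean() for x in ks])
        slope, _ = np.polyfit(np.log(ks), np.log(surv), 1)
        assert abs(slope + (gamma - 1.0)) < 0.15


class TestTopologyBuilders:
    def test_sfo_out_degrees_exact(self):
        topo = ens.build_sfo_topology(np.array([2, 0, 1]), 3, rng=0)
        assert topo.out_degrees.tolist() == [2, 0, 1]
        assert topo.adjacency.diagonal().sum() == 0
        assert topo.n_edges == 3

    def test_sfo_full_hub(self):
        n = 6
        topo = ens.build_sfo_topology(np.full(n, n - 1), n, rng=0)
        dense = topo.adjacency.toarray()
        assert (dense + np.eye(n, dtype=np.int8) == 1).all()

    def test_sfo_degree_conservation_random(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            n = int(rng.integers(5, 40))
            degrees = rng.integers(0, n - 1, size=n)
            topo = ens.build_sfo_topology(degrees, n, rng)
            assert topo.n_edges == degrees.sum()
            np.testing.assert_array_equal(topo.out_degrees, degrees)
            assert topo.adjacency.diagonal().sum() == 0
            assert topo.adjacency.max() <= 1  # simple graph, no multi-edges

    def test_sfo_rejects_excess_degree(self):
        with pytest.raises(ValueError):
            ens.build_sfo_topology(np.array([3, 0, 0]), 3, rng=0)

    def test_sfo_hubs_reach_macroscopic_fraction(self):
        """At N=1500, gamma=2.2 the largest hub targets >> mean-degree many nodes."""
        params = ens.EnsembleParams(N=1500, family="sfo", gamma=2.2, k_min=1.0)
        best = max(
            ens.build_topology(params, np.random.default_rng(seed)).out_degrees.max()
            for seed in range(5)
        )
        assert best >= 150

    def test_transpose_involution_and_duality(self):
        params = ens.EnsembleParams(N=200, family="sfo", gamma=2.5, k_min=1.0)
        topo = ens.build_topology(params, np.random.default_rng(7))
        tt = ens.transpose_topology(ens.transpose_topology(topo))
        assert (tt.adjacency != topo.adjacency).nnz == 0
        flipped = ens.transpose_topology(topo)
        np.testing.assert_array_equal(flipped.out_degrees, topo.in_degrees)
        np.testing.assert_array_equal(flipped.in_degrees, topo.out_degrees)
        assert flipped.n_edges == topo.n_edges

    def test_binomial_edge_cases(self):
        assert ens.build_binomial_topology(10, 0.0, rng=0).n_edges == 0
        full = ens.build_binomial_topology(10, 1.0, rng=0)
        assert full.n_edges == 90
        assert full.adjacency.diagonal().sum() == 0

    def test_binomial_mean_degree(self):
        n, k = 1500, 5.0
        edges = [
            ens.build_binomial_topology(n, k / n, rng=seed).n_edges for seed in range(3)
        ]
        mean_deg = np.mean(edges) / n
        # nnz ~ Binomial(n(n-1), p); 4-sigma band on the mean degree
        sd = np.sqrt(n * (n - 1) * (k / n)) / n / np.sqrt(3)
        assert abs(mean_deg - k * (n - 1) / n) < 4 * sd

    def test_binomial_invalid_p(self):
        with pytest.raises(ValueError):
            ens.build_binomial_topology(10, 1.5, rng=0)


class TestComposeNetwork:
    def test_empty_topology_gives_zero_weights(self):
        topo = ens.build_binomial_topology(8, 0.0, rng=0)
        net = ens.compose_network(topo, rng=0)
        assert net.weights.nnz == 0

    def test_sparsity_pattern_preserved(self):
        topo = ens.build_binomial_topology(100, 0.1, rng=5)
        net = ens.compose_network(topo, rng=6)
        assert ((net.weights != 0).astype(np.int8) != topo.adjacency).nnz == 0

    def test_gaussian_strength_moments(self):
        topo = ens.build_binomial_topology(400, 0.5, rng=8)
        net = ens.compose_network(topo, rng=9)
        w = net.weights.data
        assert w.size > 50_000
        assert abs(w.mean()) < 4 / np.sqrt(w.size)
        assert abs(w.var() - 1.0) < 0.03

    def test_seed_reproducibility(self):
        params = ens.EnsembleParams(N=100, family="sfo", gamma=2.5, k_min=1.0)
        a = ens.build_network(params, np.random.default_rng(42))
        b = ens.build_network(params, np.random.default_rng(42))
        assert (a.weights != b.weights).nnz == 0


class TestEnsembleParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ens.EnsembleParams(N=10, family="sfo", gamma=1.9, k_min=1.0)
        with pytest.raises(ValueError):
            ens.EnsembleParams(N=10, family="nope")
        with pytest.raises(ValueError):
            ens.EnsembleParams(N=0, family="binomial", p=0.1)
        params = ens.EnsembleParams(N=10, family="binomial", p=0.5)
        assert params.p == 0.5
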