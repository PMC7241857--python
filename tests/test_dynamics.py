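import numpy as np
import pytest
import scipy.sparse as sp

from hubnet import dynamics as dyn
from hubnet import fixtures
from hubnet.ensembles import EnsembleParams, build_network


class TestStep:
    def test_zero_weights_default_variant_gives_zeros(self):
        W = np.zeros((4, 4))
        s = np.array([1, -1, 1, -1])
        np.testing.assert_array_equal(dyn.step(W, s), np.zeros(4))

    def test_zero_weights_nonneg_variant_gives_ones(self):
        W = np.zeros((4, 4))
        s = np.array([1, -1, 1, -1])
        np.testing.assert_array_equal(dyn.step(W, s, sign_variant="nonneg"), np.ones(4))

    def test_positive_diagonal_is_invariant(self):
        W = np.diag([0.5, 2.0, 3.0])
        s = np.array([1, -1, 1])
        np.testing.assert_array_equal(dyn.step(W, s), s)

    def test_cross_coupling_hand_evaluation(self):
        W = np.array([[0.0, 1.0], [-1.0, 0.0]])
        out = dyn.step(W, np.array([1, 1]))
        np.testing.assert_array_equal(out, [1, -1])

    def test_partial_update_leaves_others(self):
        W = np.zeros((3, 3))
        s = np.array([1, 1, 1])
        out = dyn.step(W, s, update_set=[1])
        np.testing.assert_array_equal(out, [1, 0, 1])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dyn.step(np.zeros((3, 3)), np.array([1, -1]))


class TestRunDynamics:
    def test_strong_diagonal_constant_from_start(self):
        W = sp.diags([5.0] * 6).tocsr()
        s0 = np.array([1, -1, 1, 1, -1, -1], dtype=np.int8)
        traj = dyn.run_dynamics(W, s0, total_steps=50, update_fraction=0.5, seed=3)
        assert (traj.states == s0).all()
        assert dyn.frozen_core_fraction(traj) == 1.0

    def test_flipflop_period_four_orbit(self):
        """Synchronous cross-coupling cycles through all four ±1 states."""
        net = fixtures.flipflop_network()
        s0 = np.array([1, 1], dtype=np.int8)
        traj = dyn.run_dynamics(net.weights, s0, total_steps=8, update_fraction=1.0, seed=0)
        expected = [(1, 1), (1, -1), (-1, -1), (-1, 1)]
        for t, state in enumerate(traj.states):
            assert tuple(state) == expected[t % 4]
        assert dyn.frozen_core_fraction(traj) == 0.0

    def test_same_seed_reproducible(self):
        net = build_network(
            EnsembleParams(N=80, family="binomial", p=0.1), np.random.default_rng(1)
        )
        s0 = np.random.default_rng(2).choice(np.array([-1, 1], dtype=np.int8), size=80)
        a = dyn.run_dynamics(net.weights, s0, 200, seed=7)
        b = dyn.run_dynamics(net.weights, s0, 200, seed=7)
        np.testing.assert_array_equal(a.states, b.states)

    def test_spin_flip_symmetry(self):
        """sign is odd: starting from -s0 with the same update stream negates everything."""
        net = build_network(
            EnsembleParams(N=60, family="binomial", p=0.15), np.random.default_rng(5)
        )
        s0 = np.random.default_rng(6).choice(np.array([-1, 1], dtype=np.int8), size=60)
        a = dyn.run_dynamics(net.weights, s0, 150, seed=11)
        b = dyn.run_dynamics(net.weights, -s0, 150, seed=11)
        np.testing.assert_array_equal(a.states, -b.states)

    def test_zero_input_nodes_prune_or_lock(self):
        """Nodes with no inputs go to 0 by default, to +1 under the nonneg variant."""
        W = sp.csr_matrix((5, 5))
        s0 = np.ones(5, dtype=np.int8)
        pruned = dyn.run_dynamics(W, s0, 30, update_fraction=0.4, seed=1)
        assert (pruned.states[-1] == 0).all()
        locked = dyn.run_dynamics(W, -s0, 30, update_fraction=0.4, seed=1,
                                  sign_variant="nonneg")
        assert (locked.states[-1] == 1).all()

    def test_invalid_arguments(self):
        W = sp.csr_matrix((3, 3))
        s0 = np.ones(3, dtype=np.int8)
        with pytest.raises(ValueError):
            dyn.run_dynamics(W, s0, 0)
        with pytest.raises(ValueError):
            dyn.run_dynamics(W, s0, 10, update_fraction=0.0)
        with pytest.raises(ValueError):
            dyn.run_dynamics(W, np.ones(2, dtype=np.int8), 10)


class TestFrozenCore:
    def _traj(self, states):
        return dyn.StateTrajectory(states=np.asarray(states, dtype=np.int8),
                                   update_fraction=1.0, steps=len(states) - 1)

    def test_constant_trajectory(self):
        traj = self._traj(np.ones((5, 10)))
        assert dyn.frozen_core_fraction(traj) == 1.0

    def test_all_toggling(self):
        states = np.array([[1] * 4, [-1] * 4] * 3)
        assert dyn.frozen_core_fraction(self._traj(states)) == 0.0

    def test_partial_freeze_direct_count(self):
        states = np.ones((6, 10), dtype=np.int8)
        states[1::2, 0] = -1  # one node toggles
        assert dyn.frozen_core_fraction(self._traj(states)) == 0.9

    def test_monotone_in_window_length(self):
        rng = np.random.default_rng(3)
        states = rng.choice(np.array([-1, 1], dtype=np.int8), size=(30, 20))
        traj = self._traj(states)
        fracs = [dyn.frozen_core_fraction(traj, window=(0, k)) for k in range(2, 31)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_window_invalid(self):
        with pytest.raises(ValueError):
            dyn.frozen_core_fraction(self._traj(np.ones((4, 3))), window=(2, 2))


class TestClassification:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(1.0, "fixed_point"), (0.95, "qfp"), (0.9, "qfp"), (0.5, "none"), (0.0, "none")],
    )
    def test_thresholds(self, fraction, expected):
        assert dyn.classify_convergence(fraction) == expected

    def test_custom_threshold(self):
        assert dyn.classify_convergence(0.85, qfp_threshold=0.8) == "qfp"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dyn.classify_convergence(1.2)


class TestConvergenceProbability:
    def test_zero_network_always_fixed_point(self):
        """All-zero weights freeze every node at 0 under the default variant."""
        factory = lambda rng: (sp.csr_matrix((40, 40)), None)
        p, se = dyn.convergence_probability(
            factory, 10, seed=0, criterion="fixed_point", burn_in=50, window=20
        )
        assert p == 1.0 and se == 0.0

    def test_longer_protocol_stable_estimate(self):
        """Doubling the simulation length leaves the estimate unchanged within error."""
        params = EnsembleParams(N=150, family="binomial", p=6.0 / 150)

        def factory(rng):
            return build_network(params, rng).weights, None

        p1, se1 = dyn.convergence_probability(
            factory, 60, seed=1, burn_in=800, window=200
        )
        p2, se2 = dyn.convergence_probability(
            factory, 60, seed=1, burn_in=1600, window=400
        )
        assert abs(p1 - p2) <= 3 * np.sqrt(se1**2 + se2**2) + 1e-12

    def test_requires_ensemble_params(self):
        with pytest.raises(TypeError):
            dyn.estimate_convergence_probability(object(), 5)
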