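"""Propensity estimators, the logarithmic-mean gamma estimate, omega, and iterations."""

import math

import numpy as np
import pytest

import modprune as mp
from modprune.estimation import EstimationError
from modprune.heuristics import MaximizerSpec, maximize

from conftest import random_graph


class TestPropensities:
    def test_two_triangles(self, two_triangles):
        prop = mp.estimate_propensities(two_triangles, mp.Partition([0, 0, 0, 1, 1, 1]))
        assert prop == pytest.approx((2.0, 0.0))

    def test_g4_split(self, g4, g4_split):
        prop = mp.estimate_propensities(g4, g4_split)
        assert prop.theta_in == pytest.approx(0.96)
        assert prop.theta_out == pytest.approx(8 / 7)
        assert not prop.assortative

    def test_singletons_have_zero_theta_in(self, two_triangles):
        prop = mp.estimate_propensities(two_triangles, mp.Partition(range(6)))
        assert prop.theta_in == 0.0

    def test_single_community_rejected(self, g4):
        with pytest.raises(EstimationError):
            mp.estimate_propensities(g4, mp.Partition([0] * 4))

    def test_empty_graph_rejected(self):
        with pytest.raises(EstimationError):
            mp.estimate_propensities(mp.Graph(4, []), mp.Partition([0, 0, 1, 1]))

    def test_weighted_input_warns(self):
        g = mp.Graph(4, [(0, 1, 2.0), (2, 3, 1.0)])
        with pytest.warns(UserWarning, match="unweighted"):
            mp.estimate_propensities(g, mp.Partition([0, 0, 1, 1]))

    def test_theta_in_upper_bound(self, rng):
        """On unweighted graphs theta_in <= 2m / (sum kappa^2 / 2m)."""
        for _ in range(10):
            g = random_graph(rng, 12)
            part = mp.Partition(rng.integers(0, 4, size=12))
            if part.K == 1:
                continue
            try:
                prop = mp.estimate_propensities(g, part)
            except EstimationError:
                continue
            c = mp.partition_coefficients(g, part)
            assert 0.0 <= prop.theta_in <= g.two_m / c.P_hat + 1e-12
            assert prop.theta_out >= 0.0


class TestLogarithmicMean:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ((1.3, 1.3), 1.3),
            ((4.0, 1.0), 3.0 / math.log(4.0)),
            ((0.96, 8 / 7), (0.96 - 8 / 7) / math.log(0.96 * 7 / 8)),
        ],
    )
    def test_values(self, pair, expected):
        assert mp.gamma_from_propensities(mp.PropensityPair(*pair)) == pytest.approx(expected)

    def test_zero_propensity_gives_none(self):
        assert mp.gamma_from_propensities(mp.PropensityPair(2.0, 0.0)) is None
        assert mp.gamma_from_propensities(mp.PropensityPair(0.0, 0.0)) is None

    def test_symmetry_monotonicity_bounds(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0.05, 5.0, size=2)
            g = mp.gamma_from_propensities(mp.PropensityPair(a, b))
            assert g == pytest.approx(mp.gamma_from_propensities(mp.PropensityPair(b, a)))
            assert min(a, b) - 1e-12 <= g <= max(a, b) + 1e-12
            g_up = mp.gamma_from_propensities(mp.PropensityPair(a * 1.1, b))
            assert g_up > g

    def test_gamma_estimate_none_for_trivial_partition(self, g4):
        assert mp.gamma_estimate(g4, mp.Partition([0] * 4)) is None

    def test_gamma_estimate_g4(self, g4, g4_split):
        assert mp.gamma_estimate(g4, g4_split) == pytest.approx(1.0488, abs=1e-3)


class TestMultilayerPropensities:
    def test_identical_layers_match_single_layer(self, two_triangles):
        labels = np.array([0, 0, 0, 1, 1, 1])
        ml = mp.MultilayerNetwork([two_triangles] * 3, mp.TEMPORAL_CHAIN)
        prop_ml = mp.estimate_multilayer_propensities(
            ml, mp.MultilayerPartition(np.tile(labels, (3, 1)))
        )
        prop_sl = mp.estimate_propensities(two_triangles, mp.Partition(labels))
        assert prop_ml == pytest.approx(prop_sl)

    def test_planted_ratio_tends_to_inverse_epsilon(self):
        eps = 0.4
        ml, planted = mp.generate_temporal(
            mp.TemporalSpec(n=300, T=6, K=2, eta=0.8, epsilon=eps, seed=9)
        )
        prop = mp.estimate_multilayer_propensities(ml, planted)
        assert prop.theta_in / prop.theta_out == pytest.approx(1 / eps, rel=0.1)

    def test_all_layers_single_community_rejected(self, g4_chain):
        with pytest.raises(EstimationError):
            mp.estimate_multilayer_propensities(
                g4_chain, mp.MultilayerPartition([[0] * 4, [1] * 4])
            )


class TestCopyingProbability:
    def test_identical_layers(self):
        p = mp.MultilayerPartition([[0, 1, 1]] * 4)
        assert mp.estimate_copying_probability(p) == 1.0

    def test_direct_count(self):
        p = mp.MultilayerPartition([[0, 0, 1], [0, 1, 1]])
        assert mp.estimate_copying_probability(p) == pytest.approx(2 / 3)

    def test_iid_labels_agree_at_chance(self, rng):
        labels = rng.integers(0, 2, size=(2, 10_000))
        f = mp.estimate_copying_probability(mp.MultilayerPartition(labels))
        assert f == pytest.approx(0.5, abs=0.02)

    def test_label_permutation_invariance(self, rng):
        labels = rng.integers(0, 3, size=(4, 50))
        f1 = mp.estimate_copying_probability(mp.MultilayerPartition(labels))
        f2 = mp.estimate_copying_probability(mp.MultilayerPartition((labels + 1) % 3))
        assert f1 == f2

    def test_single_layer_rejected(self):
        with pytest.raises(EstimationError):
            mp.estimate_copying_probability(mp.MultilayerPartition([[0, 1]]))

    def test_chance_correction(self):
        assert mp.copying_from_persistence(0.85, 2) == pytest.approx(0.7)
        assert mp.copying_from_persistence(0.5, 2) == 0.0
        assert mp.copying_from_persistence(0.2, 2) == 0.0  # clipped


class TestOmegaEstimate:
    def test_limits(self):
        prop = mp.PropensityPair(4 / 3, 2 / 3)
        assert mp.omega_from_estimates(0.0, 2, prop) == 0.0
        assert mp.omega_from_estimates(1.0, 2, prop) == math.inf

    def test_hand_value(self):
        omega = mp.omega_from_estimates(0.5, 2, mp.PropensityPair(4 / 3, 2 / 3))
        assert omega == pytest.approx(math.log(3) / (2 * math.log(2)))

    def test_degenerate_propensities_rejected(self):
        with pytest.raises(EstimationError):
            mp.omega_from_estimates(0.5, 2, mp.PropensityPair(1.0, 0.0))
        with pytest.raises(EstimationError):
            mp.omega_from_estimates(0.5, 2, mp.PropensityPair(0.5, 0.9))


class TestJointEstimate:
    def test_identical_labels_give_infinite_omega(self, g4_chain):
        part = mp.MultilayerPartition([[0, 0, 0, 1], [0, 0, 0, 1]])
        est = mp.multilayer_parameter_estimate(g4_chain, part)
        assert est.omega == math.inf

    def test_trivial_partition_has_no_estimate(self, g4_chain):
        est = mp.multilayer_parameter_estimate(
            g4_chain, mp.MultilayerPartition([[0] * 4, [0] * 4])
        )
        assert est.gamma is None and est.omega is None


class TestIterativeProcedures:
    def test_constant_maximizer_converges_immediately(self, two_triangles):
        part = mp.Partition([0, 0, 0, 1, 1, 1])
        trace = mp.newman_iterative_gamma(
            two_triangles, 2, 1.0, lambda g, gamma, K: part, tol=1e-3
        )
        # theta_out = 0 for disconnected components: the estimate is undefined
        assert not trace.converged and trace.reason == "no-estimate"

    def test_constant_maximizer_fixed_point(self, g4, g4_split):
        trace = mp.newman_iterative_gamma(g4, 2, 0.5, lambda g, gamma, K: g4_split)
        assert trace.converged and trace.n_steps == 2
        assert trace.final_gamma == pytest.approx(1.0488, abs=1e-3)

    def test_exhaustive_fixed_k_matches_brute_force(self, g4):
        def exhaustive(graph, gamma, K):
            return maximize(graph, MaximizerSpec(backend="exhaustive", gamma=gamma, K=K))

        trace = mp.newman_iterative_gamma(g4, 2, 1.0, exhaustive, tol=1e-6)
        # oracle: evaluate the estimate of every bipartition's argmax directly
        from modprune.heuristics import enumerate_set_partitions

        best = max(
            (
                labels
                for labels in enumerate_set_partitions(4)
                if labels.max() + 1 == 2
            ),
            key=lambda lab: mp.modularity(g4, mp.Partition(lab), trace.final_gamma),
        )
        assert mp.gamma_estimate(g4, mp.Partition(best)) == pytest.approx(trace.final_gamma)

    def test_pamfil_one_step_with_oracle_maximizer(self):
        ml, planted = mp.generate_temporal(
            mp.TemporalSpec(n=60, T=4, K=2, eta=0.8, epsilon=0.3, seed=4)
        )
        truth_est = mp.multilayer_parameter_estimate(ml, planted)
        trace = mp.pamfil_iterative_parameters(
            ml, truth_est.gamma, truth_est.omega, lambda m, g, w: planted
        )
        assert trace.converged and trace.n_steps == 1

    def test_pamfil_flags_infinite_omega(self, g4_chain):
        frozen = mp.MultilayerPartition([[0, 0, 0, 1], [0, 0, 0, 1]])
        trace = mp.pamfil_iterative_parameters(g4_chain, 1.0, 1.0, lambda m, g, w: frozen)
        assert not trace.converged and trace.reason == "omega-infinite"
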