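"""Finite-state map construction, stability classification, and map invariants."""

import math

import numpy as np
import pytest

import modprune as mp
from modprune.champ import DomainInterval
from modprune.estimation import ParameterEstimate
from modprune.pruning import build_map, stable_partitions

from conftest import random_graph


def interval_map(specs, gamma_range=(0.0, 2.0), **kwargs):
    """Assemble a map from (A_hat, P_hat, gamma_hat) triples via real domains."""
    coeffs = [mp.QualityCoefficients(a, p) for a, p, _ in specs]
    domains = mp.champ_intervals(coeffs, *gamma_range)
    keep = [d.partition_id for d in domains]
    estimates = [ParameterEstimate(specs[i][2], None, K=2) for i in keep]
    states = [f"partition-{i}" for i in keep]
    return build_map(
        states, [coeffs[i] for i in keep], domains, estimates, gamma_range, **kwargs
    )


class TestBuildMap:
    def test_single_state_self_successor(self):
        fsmap = interval_map([(3.0, 2.0, 1.0)])
        assert fsmap.successor == {0: 0}
        assert stable_partitions(fsmap).fixed_points == [0]

    def test_two_cycle_detected(self):
        # line 0 optimal on [0,1], line 1 on [1,2]; estimates swapped across the break
        fsmap = interval_map([(10.0, 2.0, 1.5), (9.0, 1.0, 0.5)])
        assert fsmap.successor == {0: 1, 1: 0}
        result = stable_partitions(fsmap)
        assert result.fixed_points == []
        assert result.orbits == [(0, 1)]

    def test_escaped_states(self):
        fsmap = interval_map([(10.0, 2.0, None), (9.0, 1.0, 5.0)])
        assert fsmap.successor == {0: None, 1: None}
        result = stable_partitions(fsmap)
        assert result.escaped == [0, 1] and result.fixed_points == []

    def test_boundary_tie_resolved_by_quality_then_lower_id(self):
        # both lines meet at gamma = 1 where both estimates sit
        fsmap = interval_map([(10.0, 2.0, 1.0), (9.0, 1.0, 1.0)])
        assert fsmap.successor[0] == 0  # equal quality at the break: lower id wins
        assert fsmap.successor[1] == 0

    def test_transient_classification(self):
        # three contiguous domains [0, 2/3], [2/3, 1], [1, 2]; all estimates in the last
        fsmap = interval_map([(10.0, 6.0, 1.8), (8.0, 3.0, 1.9), (6.0, 1.0, 1.9)])
        result = stable_partitions(fsmap)
        assert result.classification[2] == "fixed"
        assert all(
            result.classification[s] in {"fixed", "transient"} for s in fsmap.state_ids
        )


class TestInfiniteOmegaClamping:
    def make_2d_map(self, clamp):
        coeffs = [mp.QualityCoefficients(5, 1, 0), mp.QualityCoefficients(4, 1, 2)]
        domains = mp.champ_domains_2d(coeffs, (0, 2), (0, 2))
        order = [d.partition_id for d in domains]
        est = {
            0: ParameterEstimate(1.0, 0.2, K=2),
            1: ParameterEstimate(1.0, math.inf, K=2),
        }
        return build_map(
            [f"s{i}" for i in order],
            [coeffs[i] for i in order],
            domains,
            [est[i] for i in order],
            (0, 2),
            (0, 2),
            clamp_infinite_omega=clamp,
        )

    def test_clamped_infinite_omega_maps_to_top_of_range(self):
        fsmap = self.make_2d_map(clamp=True)
        inf_state = next(
            s for s, e in fsmap.estimates.items() if e.omega is not None and math.isinf(e.omega)
        )
        assert fsmap.successor[inf_state] is not None

    def test_unclamped_infinite_omega_escapes(self):
        fsmap = self.make_2d_map(clamp=False)
        inf_state = next(
            s for s, e in fsmap.estimates.items() if e.omega is not None and math.isinf(e.omega)
        )
        assert fsmap.successor[inf_state] is None


class TestPipelineInvariants:
    def make_pool(self, rng, g):
        pool = [mp.Partition(rng.integers(0, k + 1, size=g.n)) for k in range(1, 5) for _ in range(15)]
        pool.append(mp.Partition([0] * g.n))
        return pool

    def test_determinism_and_order_invariance(self, rng):
        g = random_graph(rng, 16, p=0.35)
        pool = self.make_pool(rng, g)
        out1 = mp.prune(g, pool, (0, 2))
        shuffled = list(pool)
        rng.shuffle(shuffled)
        out2 = mp.prune(g, shuffled, (0, 2))
        fixed1 = {out1[3][s] for s in out1[6].fixed_points}
        fixed2 = {out2[3][s] for s in out2[6].fixed_points}
        assert set(out1[3]) == set(out2[3])  # same admissible partitions
        assert fixed1 == fixed2

    def test_unrestricted_fixed_point_implies_restricted(self, rng):
        """A K-community fixed point of the free map is a fixed point at fixed K."""
        checked = 0
        for trial in range(6):
            g = random_graph(rng, 14, p=0.4)
            pool = self.make_pool(rng, g)
            pool_d, _, _, adm, _, fsmap, stab = mp.prune(g, pool, (0, 2))
            for s in stab.fixed_points:
                K = adm[s].K
                if K == 1:
                    continue
                rmap, rstab = mp.restricted_map(pool_d, K, g, (0, 2))
                assert adm[s] in {rmap.states[t] for t in rstab.fixed_points}
                checked += 1
        assert checked >= 1

    def test_every_state_classified(self, rng):
        g = random_graph(rng, 12, p=0.4)
        pool = self.make_pool(rng, g)
        _, _, _, adm, _, fsmap, stab = mp.prune(g, pool, (0, 2))
        assert set(stab.classification) == set(fsmap.state_ids)
        for s, cls in stab.classification.items():
            if cls == "fixed":
                assert fsmap.successor[s] == s
            elif cls == "escaped":
                assert fsmap.successor[s] is None
            else:
                assert fsmap.successor[s] is not None and fsmap.successor[s] != s

    def test_restricted_map_requires_matching_partitions(self, g4, g4_split):
        with pytest.raises(ValueError):
            mp.restricted_map([g4_split], 3, g4, (0, 2))
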