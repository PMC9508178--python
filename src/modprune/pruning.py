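"""The finite-state parameter map on the admissible subset and its fixed points.

Each admissible partition occupies a convex domain of optimality and carries an
estimated "correct" parameter point from the SBM equivalence.  Sending every
partition to the admissible partition that is optimal at its estimated point
defines a deterministic map on a finite set of states; its fixed points — the
partitions whose estimates land inside their own domains — are the stable
partitions.  Because the state space is finite, iterating the map from any
state reaches a fixed point, a periodic orbit, or an escaped state (undefined
or out-of-range estimate) in at most |states| steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .champ import admissible_subset
from .estimation import (
    EstimationError,
    ParameterEstimate,
    estimate_propensities,
    gamma_from_propensities,
    multilayer_parameter_estimate,
)
from .network import MultilayerNetwork, QualityCoefficients

__all__ = [
    "FiniteStateMap",
    "StabilityResult",
    "build_map",
    "stable_partitions",
    "restricted_map",
    "prune",
    "single_layer_parameter_estimate",
]


@dataclass
class FiniteStateMap:
    """Successor relation on the admissible partitions.

    ``successor[s]`` is the state (index into ``states``) whose domain contains
    state s's estimated parameter point, or None when the estimate is undefined
    or out of range (an "escaped" state).
    """

    states: list  # partition objects, position = state id
    domains: dict  # state id -> DomainInterval | DomainPolygon
    estimates: dict  # state id -> ParameterEstimate
    successor: dict  # state id -> state id | None
    gamma_range: tuple[float, float]
    omega_range: Optional[tuple[float, float]] = None

    @property
    def state_ids(self) -> list[int]:
        return list(range(len(self.states)))


@dataclass
class StabilityResult:
    """Classification of every state of a finite-state map."""

    fixed_points: list[int]
    orbits: list[tuple[int, ...]]
    escaped: list[int]
    classification: dict = field(default_factory=dict)  # state -> "fixed"|"orbit"|"transient"|"escaped"

    def fixed_point_partitions(self, fsmap: FiniteStateMap) -> list:
        return [fsmap.states[s] for s in self.fixed_points]


def _estimate_point(
    est: ParameterEstimate,
    gamma_range: tuple[float, float],
    omega_range: Optional[tuple[float, float]],
    clamp_infinite_omega: bool,
) -> Optional[tuple]:
    """The (possibly clamped) parameter point of an estimate, or None if escaped."""
    if est.gamma is None:
        return None
    g0, g1 = gamma_range
    if not g0 <= est.gamma <= g1:
        return None
    if omega_range is None:
        return (est.gamma,)
    if est.omega is None:
        return None
    omega = est.omega
    if math.isinf(omega):
        if not clamp_infinite_omega:
            return None
        omega = omega_range[1]
    if not omega_range[0] <= omega <= omega_range[1]:
        return None
    return (est.gamma, omega)


def build_map(
    admissible: Sequence,
    coeffs: Sequence[QualityCoefficients],
    domains: Sequence,
    estimates: Sequence[ParameterEstimate],
    gamma_range: tuple[float, float],
    omega_range: Optional[tuple[float, float]] = None,
    clamp_infinite_omega: bool = True,
) -> FiniteStateMap:
    """Locate each admissible partition's estimate within the set of domains.

    The containing domain is found by evaluating every admissible partition's
    quality at the estimate point and taking the argmax, which coincides with
    point-in-domain location and resolves boundary points by maximum quality;
    remaining exact ties go to the lower state id.  An infinite omega estimate
    is clamped to the top of the omega range when ``clamp_infinite_omega`` is
    set; estimates outside the ranges mark the state as escaped.
    """
    A = np.array([c.A_hat for c in coeffs])
    P = np.array([c.P_hat for c in coeffs])
    C = np.array([c.C_hat for c in coeffs])
    successor: dict[int, Optional[int]] = {}
    for s, est in enumerate(estimates):
        pt = _estimate_point(est, gamma_range, omega_range, clamp_infinite_omega)
        if pt is None:
            successor[s] = None
            continue
        vals = A - pt[0] * P + (pt[1] * C if omega_range is not None else 0.0)
        best = vals.max()
        tol = 1e-10 * max(1.0, abs(best))
        successor[s] = int(np.nonzero(vals >= best - tol)[0][0])
    return FiniteStateMap(
        states=list(admissible),
        domains={i: d for i, d in enumerate(domains)},
        estimates={i: e for i, e in enumerate(estimates)},
        successor=successor,
        gamma_range=gamma_range,
        omega_range=omega_range,
    )


def stable_partitions(fsmap: FiniteStateMap) -> StabilityResult:
    """Fixed points, periodic orbits and escaped states of the map."""
    succ = fsmap.successor
    fixed = [s for s in fsmap.state_ids if succ[s] == s]
    escaped = [s for s in fsmap.state_ids if succ[s] is None]
    on_orbit: dict[int, tuple[int, ...]] = {}
    orbits: list[tuple[int, ...]] = []
    classification: dict[int, str] = {}
    for s in fsmap.state_ids:
        if succ[s] is None:
            classification[s] = "escaped"
        elif succ[s] == s:
            classification[s] = "fixed"
    for s in fsmap.state_ids:
        if s in classification:
            continue
        path, seen = [], {}
        cur = s
        while cur is not None and cur not in classification and cur not in seen:
            seen[cur] = len(path)
            path.append(cur)
            cur = succ[cur]
        if cur is not None and cur in seen:  # found a new cycle of length >= 2
            cycle = tuple(path[seen[cur]:])
            orbits.append(cycle)
            for c in cycle:
                classification[c] = "orbit"
                on_orbit[c] = cycle
        for p in path:
            classification.setdefault(p, "transient")
    return StabilityResult(fixed, orbits, escaped, classification)


def single_layer_parameter_estimate(graph, partition) -> ParameterEstimate:
    """Gamma estimate of a single-layer partition, packaged with its propensities."""
    if partition.K == 1:
        return ParameterEstimate(None, None, K=1)
    try:
        prop = estimate_propensities(graph, partition)
    except EstimationError:
        return ParameterEstimate(None, None, K=partition.K)
    return ParameterEstimate(
        gamma_from_propensities(prop),
        None,
        theta_in=prop.theta_in,
        theta_out=prop.theta_out,
        K=partition.K,
    )


def prune(
    network,
    partitions: Sequence,
    gamma_range: tuple[float, float],
    omega_range: Optional[tuple[float, float]] = None,
    clamp_infinite_omega: bool = True,
):
    """Full pruning pipeline: dedup -> domains -> estimates -> map -> stability.

    Returns (pool, coeffs, domains, admissible, estimates, map, stability);
    the model facade wraps this tuple into a results object.
    """
    pool, coeffs, domains, admissible = admissible_subset(
        partitions, network, gamma_range, omega_range
    )
    adm_coeffs = [coeffs[d.partition_id] for d in domains]
    if isinstance(network, MultilayerNetwork):
        estimates = [multilayer_parameter_estimate(network, p) for p in admissible]
    else:
        estimates = [single_layer_parameter_estimate(network, p) for p in admissible]
    fsmap = build_map(
        admissible, adm_coeffs, domains, estimates, gamma_range, omega_range, clamp_infinite_omega
    )
    stability = stable_partitions(fsmap)
    return pool, coeffs, domains, admissible, estimates, fsmap, stability


def restricted_map(
    partitions: Sequence,
    K: int,
    network,
    gamma_range: tuple[float, float],
    omega_range: Optional[tuple[float, float]] = None,
    clamp_infinite_omega: bool = True,
) -> tuple[FiniteStateMap, StabilityResult]:
    """The pruning pipeline on the subset of partitions with exactly K communities."""
    pool = [p for p in partitions if p.K == K]
    if not pool:
        raise ValueError(f"no partitions with K={K} communities in the pool")
    *_, fsmap, stability = prune(network, pool, gamma_range, omega_range, clamp_infinite_omega)
    return fsmap, stability
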