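"""Planted-partition SBM propensity estimation and the gamma / (gamma, omega) estimates.

Modularity maximization at resolution gamma is equivalent to maximum-likelihood
inference of a degree-corrected planted-partition SBM whose within/between
connection propensities are theta_in and theta_out, provided

    gamma = (theta_in - theta_out) / (ln theta_in - ln theta_out),

the logarithmic mean of the propensities.  Given a partition, the propensities
themselves are estimated from the observed within-community edge weight and the
community degree sums:

    theta_in  = 2 m_in / (sum_c kappa_c^2 / 2m)
    theta_out = (2m - 2 m_in) / (2m - sum_c kappa_c^2 / 2m).

For temporal/multiplex multilayer networks the same estimates accumulate the
numerators and denominators per layer, and a second relation fixes the "correct"
interlayer coupling from the label copying probability p and label count K:

    omega = ln(1 + p K / (1 - p)) / (DENOM * (ln theta_in - ln theta_out)).

DENOM = 2 here because this implementation sums interlayer couplings over
*ordered* layer pairs (each physical coupling enters the quality and 2*mu
twice); see :data:`INTERLAYER_DOUBLING`.

The copying probability of the underlying temporal SBM is recovered from the
observed persistence frequency f of labels across consecutive layers by the
chance correction p = (f - 1/K) / (1 - 1/K): a label that is resampled uniformly
still agrees with its predecessor with probability 1/K, so the raw frequency
overstates copying.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional

import numpy as np

from .network import (
    Graph,
    MultilayerNetwork,
    MultilayerPartition,
    Partition,
    _layer_coefficients,
    partition_coefficients,
)

__all__ = [
    "EstimationError",
    "PropensityPair",
    "ParameterEstimate",
    "IterationTrace",
    "estimate_propensities",
    "gamma_from_propensities",
    "gamma_estimate",
    "estimate_multilayer_propensities",
    "estimate_copying_probability",
    "copying_from_persistence",
    "omega_from_estimates",
    "multilayer_parameter_estimate",
    "newman_iterative_gamma",
    "pamfil_iterative_parameters",
    "INTERLAYER_DOUBLING",
]

#: Interlayer couplings are summed over ordered layer pairs in the multilayer
#: quality, so each physical coupling is counted twice; the omega estimate
#: divides by this constant to stay on the same scale.  A package using the
#: unordered convention would set this to 1.
INTERLAYER_DOUBLING = 2.0


class EstimationError(ValueError):
    """Raised when a propensity or parameter estimate is undefined for the input."""


class PropensityPair(NamedTuple):
    theta_in: float
    theta_out: float

    @property
    def assortative(self) -> bool:
        return self.theta_in > self.theta_out


@dataclass(frozen=True)
class ParameterEstimate:
    """The (gamma[, omega]) point estimated for one partition.

    ``gamma`` is None when no estimate exists (K = 1 or a zero propensity);
    ``omega`` is None for single-layer input or a degenerate multilayer estimate
    and ``math.inf`` when the estimated copying probability is 1 (identical
    labels in every layer).
    """

    gamma: Optional[float]
    omega: Optional[float] = None
    theta_in: Optional[float] = None
    theta_out: Optional[float] = None
    persistence: Optional[float] = None
    copying: Optional[float] = None
    K: Optional[int] = None

    @property
    def defined(self) -> bool:
        return self.gamma is not None

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "theta_in": self.theta_in,
            "theta_out": self.theta_out,
            "gamma_hat": self.gamma,
            "omega_hat": self.omega,
            "p_hat": self.persistence,
        }


def _warn_weighted(graph: Graph) -> None:
    if graph.is_weighted:
        warnings.warn(
            "SBM-equivalence estimates are only known for unweighted multigraphs; "
            "weighted input is used as-is",
            stacklevel=3,
        )


def estimate_propensities(graph: Graph, partition: Partition) -> PropensityPair:
    """Estimate (theta_in, theta_out) from a partition of a single-layer graph."""
    if graph.two_m == 0:
        raise EstimationError("propensities undefined on a graph with no edge weight")
    if partition.K == 1:
        raise EstimationError("theta_out undefined for the single-community partition")
    _warn_weighted(graph)
    c = partition_coefficients(graph, partition)
    if graph.two_m - c.P_hat <= 0:
        # all degree mass in one community (the rest isolated): theta_out 0/0
        raise EstimationError("theta_out undefined: null-model mass equals total weight")
    # A_hat = 2*m_in and P_hat = sum_c kappa_c^2 / 2m
    theta_in = c.A_hat / c.P_hat
    theta_out = (graph.two_m - c.A_hat) / (graph.two_m - c.P_hat)
    return PropensityPair(theta_in, theta_out)


def gamma_from_propensities(p: PropensityPair) -> Optional[float]:
    """Logarithmic mean of the propensities; None if either propensity is 0."""
    t_in, t_out = p
    if t_in <= 0 or t_out <= 0:
        return None
    if t_in == t_out:
        return float(t_in)
    return (t_in - t_out) / (math.log(t_in) - math.log(t_out))


def gamma_estimate(graph: Graph, partition: Partition) -> Optional[float]:
    """The resolution-parameter estimate of a partition; None when undefined."""
    if partition.K == 1:
        return None
    return gamma_from_propensities(estimate_propensities(graph, partition))


def estimate_multilayer_propensities(
    ml: MultilayerNetwork, partition: MultilayerPartition
) -> PropensityPair:
    """Per-layer-accumulated (theta_in, theta_out).

    Community degree sums and within-community edge weights are formed per layer
    (group memberships are taken per layer, not in aggregate) and the four sums
    are accumulated over layers before the ratios are taken.
    """
    if ml.total_two_m == 0:
        raise EstimationError("propensities undefined: all layers are empty")
    num_in = den_in = num_out = den_out = 0.0
    for s, g in enumerate(ml.layers):
        if g.two_m == 0:
            continue
        _warn_weighted(g)
        a, p = _layer_coefficients(g, partition.layer(s))
        num_in += a
        den_in += p
        num_out += g.two_m - a
        den_out += g.two_m - p
    if den_out == 0:
        raise EstimationError("theta_out undefined: every layer is a single community")
    return PropensityPair(num_in / den_in, num_out / den_out)


def estimate_copying_probability(
    partition: MultilayerPartition, topology: str = "temporal_chain"
) -> float:
    """Raw persistence frequency of labels across coupled layer pairs.

    For a temporal chain this is the fraction of (node, layer) pairs,
    t = 2..T, whose label equals the node's label in layer t-1.  For multiplex
    all-pairs coupling it is the mean label agreement over all coupled pairs
    (an extension beyond the temporal model; a warning flags it).
    """
    if partition.T < 2:
        raise EstimationError("copying probability undefined for a single layer")
    labels = partition.labels
    if topology == "temporal_chain":
        agree = labels[:-1] == labels[1:]
        return float(agree.mean())
    if topology == "multiplex_all_pairs":
        warnings.warn(
            "multiplex copying probability is a mean label agreement over all "
            "coupled layer pairs, extending the temporal-chain definition",
            stacklevel=2,
        )
        T = partition.T
        agree = [
            (labels[s] == labels[r]).mean() for s in range(T) for r in range(s + 1, T)
        ]
        return float(np.mean(agree))
    raise ValueError(f"unknown topology {topology!r}")


def copying_from_persistence(frequency: float, K: int) -> float:
    """Chance-corrected copying probability p = (f - 1/K) / (1 - 1/K), clipped to [0, 1]."""
    if K < 2:
        raise EstimationError("copying probability needs K >= 2 labels")
    p = (frequency - 1.0 / K) / (1.0 - 1.0 / K)
    return min(1.0, max(0.0, p))


def omega_from_estimates(p: float, K: int, prop: PropensityPair) -> float:
    """Interlayer-coupling estimate from copying probability, label count and propensities."""
    if not 0.0 <= p <= 1.0:
        raise EstimationError("copying probability must lie in [0, 1]")
    if K < 2:
        raise EstimationError("omega estimate needs K >= 2")
    if p >= 1.0:
        # identical labels in every layer: the estimate diverges regardless of theta
        return math.inf
    if prop.theta_out <= 0 or prop.theta_in <= prop.theta_out:
        raise EstimationError("omega estimate requires assortative propensities theta_in > theta_out > 0")
    if p == 0.0:
        return 0.0
    num = math.log(1.0 + p * K / (1.0 - p))
    den = INTERLAYER_DOUBLING * (math.log(prop.theta_in) - math.log(prop.theta_out))
    return num / den


def multilayer_parameter_estimate(
    ml: MultilayerNetwork, partition: MultilayerPartition
) -> ParameterEstimate:
    """Joint (gamma, omega) estimate of a multilayer partition.

    Degenerate inputs (single community everywhere, zero or disassortative
    propensities) yield None fields rather than exceptions, so that pruning can
    classify such partitions as having no estimate.
    """
    K = partition.K
    if K == 1:
        return ParameterEstimate(None, None, K=1)
    try:
        prop = estimate_multilayer_propensities(ml, partition)
    except EstimationError:
        return ParameterEstimate(None, None, K=K)
    gamma = gamma_from_propensities(prop)
    persistence = copying = omega = None
    if ml.T >= 2:
        persistence = estimate_copying_probability(partition, ml.coupling)
        copying = copying_from_persistence(persistence, K)
        try:
            omega = omega_from_estimates(copying, K, prop)
        except EstimationError:
            omega = None
    return ParameterEstimate(
        gamma,
        omega,
        theta_in=prop.theta_in,
        theta_out=prop.theta_out,
        persistence=persistence,
        copying=copying,
        K=K,
    )


@dataclass
class IterationTrace:
    """Record of an alternating maximize/re-estimate run."""

    steps: list = field(default_factory=list)  # (gamma, omega, partition, K)
    converged: bool = False
    reason: Optional[str] = None

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def final_gamma(self) -> Optional[float]:
        return self.steps[-1][0] if self.steps else None

    @property
    def final_omega(self) -> Optional[float]:
        return self.steps[-1][1] if self.steps else None

    @property
    def final_partition(self):
        return self.steps[-1][2] if self.steps else None


def newman_iterative_gamma(
    graph: Graph,
    K: int,
    gamma0: float,
    maximizer: Callable[[Graph, float, int], Partition],
    tol: float = 1e-3,
    max_iter: int = 25,
) -> IterationTrace:
    """Alternate fixed-K modularity maximization and gamma re-estimation.

    ``maximizer(graph, gamma, K)`` must honor the fixed community count.  The
    iteration stops when successive gamma estimates differ by less than ``tol``.
    """
    trace = IterationTrace()
    gamma = float(gamma0)
    for _ in range(max_iter):
        part = maximizer(graph, gamma, K)
        est = gamma_estimate(graph, part)
        if est is None:
            trace.reason = "no-estimate"
            return trace
        trace.steps.append((est, None, part, part.K))
        if abs(est - gamma) < tol:
            trace.converged = True
            return trace
        gamma = est
    trace.reason = "max-iter"
    return trace


def pamfil_iterative_parameters(
    ml: MultilayerNetwork,
    gamma0: float,
    omega0: float,
    maximizer: Callable[[MultilayerNetwork, float, float], MultilayerPartition],
    tol: float = 1e-3,
    max_iter: int = 25,
) -> IterationTrace:
    """Alternate multilayer maximization at (gamma, omega) and joint re-estimation.

    The community count is free to vary.  Non-convergence (including the
    oscillation seen in hard planted regimes) is reported via the trace rather
    than forced; an infinite omega estimate terminates the trace with a flag.
    """
    trace = IterationTrace()
    gamma, omega = float(gamma0), float(omega0)
    visited: list[tuple[float, float]] = []
    for _ in range(max_iter):
        part = maximizer(ml, gamma, omega)
        est = multilayer_parameter_estimate(ml, part)
        if est.gamma is None or est.omega is None:
            trace.reason = "no-estimate"
            return trace
        trace.steps.append((est.gamma, est.omega, part, part.K))
        if math.isinf(est.omega):
            trace.reason = "omega-infinite"
            return trace
        if abs(est.gamma - gamma) < tol and abs(est.omega - omega) < tol:
            trace.converged = True
            return trace
        if any(abs(est.gamma - g) < tol and abs(est.omega - o) < tol for g, o in visited[:-1]):
            trace.reason = "oscillating"
            return trace
        visited.append((est.gamma, est.omega))
        gamma, omega = est.gamma, est.omega
    trace.reason = "max-iter"
    return trace
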