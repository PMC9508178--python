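"""Model/Results facade over the pruning pipeline.

`PartitionPruning` holds the data — a (multilayer) network, a pool of candidate
partitions (or a sweep recipe for obtaining one), and the parameter ranges —
and `fit()` runs the pipeline: deduplicate the pool, compute each partition's
domain of optimality, estimate each admissible partition's "correct"
parameters from the SBM equivalence, build the finite-state map and classify
its states.  The returned `PruningResults` carries the admissible subset,
domains, estimates, successor map and stability classification, with a
`summary()` table and JSON/CSV export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import heuristics
from .champ import DomainInterval
from .network import Graph, MultilayerNetwork
from .pruning import prune, restricted_map

__all__ = ["PartitionPruning", "PruningResults", "SweepSpec"]


@dataclass(frozen=True)
class SweepSpec:
    """Recipe for generating the input pool by heuristic maximization on a grid."""

    gamma_points: int = 100
    omega_points: Optional[int] = None
    runs_per_point: int = 1
    backend: str = "leiden"
    K: Optional[int] = None
    seed: int = 0


class PartitionPruning:
    """Prune a pool of modularity partitions to its stable members.

    Parameters
    ----------
    network : Graph or MultilayerNetwork
        The network the partitions describe.
    partitions : sequence, optional
        Candidate partitions from any source.  If omitted, `fit()` generates a
        pool with the sweep recipe.
    gamma_range : (float, float)
        Resolution-parameter range of the analysis.
    omega_range : (float, float), optional
        Interlayer-coupling range; required for multilayer networks.
    clamp_infinite_omega : bool
        Treat an infinite omega estimate as sitting at the top of the omega
        range (partitions identical across layers) instead of escaping.
    """

    def __init__(
        self,
        network,
        partitions: Optional[Sequence] = None,
        gamma_range: tuple[float, float] = (0.0, 2.0),
        omega_range: Optional[tuple[float, float]] = None,
        clamp_infinite_omega: bool = True,
    ):
        if isinstance(network, MultilayerNetwork) and omega_range is None:
            raise ValueError("multilayer pruning needs an omega_range")
        if isinstance(network, Graph) and omega_range is not None:
            raise ValueError("omega_range only applies to multilayer networks")
        self.network = network
        self.partitions = list(partitions) if partitions is not None else None
        self.gamma_range = tuple(gamma_range)
        self.omega_range = tuple(omega_range) if omega_range is not None else None
        self.clamp_infinite_omega = clamp_infinite_omega

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_edgelist(cls, path, **kwargs) -> "PartitionPruning":
        from .io import read_edgelist

        graph, _ = read_edgelist(path)
        return cls(graph, **kwargs)

    @classmethod
    def from_gml(cls, path, **kwargs) -> "PartitionPruning":
        from .io import read_gml

        graph, _ = read_gml(path)
        return cls(graph, **kwargs)

    @classmethod
    def from_multilayer_edgelist(cls, path, coupling: str, **kwargs) -> "PartitionPruning":
        from .io import read_multilayer_edgelist

        ml, _ = read_multilayer_edgelist(path, coupling)
        return cls(ml, **kwargs)

    @classmethod
    def from_networkx(cls, G, **kwargs) -> "PartitionPruning":
        return cls(Graph.from_networkx(G), **kwargs)

    # -- fitting ------------------------------------------------------------

    def sweep_pool(self, sweep: SweepSpec):
        """Generate the input partition pool from the sweep recipe."""
        g0, g1 = self.gamma_range
        gamma_grid = np.linspace(g0, g1, sweep.gamma_points)
        omega_grid = None
        if self.omega_range is not None:
            w0, w1 = self.omega_range
            omega_grid = np.linspace(w0, w1, sweep.omega_points or sweep.gamma_points)
        return heuristics.sweep(
            self.network,
            gamma_grid,
            omega_grid,
            runs_per_point=sweep.runs_per_point,
            seed=sweep.seed,
            backend=sweep.backend,
            K=sweep.K,
        )

    def fit(self, sweep: Optional[SweepSpec] = None, K: Optional[int] = None) -> "PruningResults":
        """Run the pruning pipeline; ``K`` restricts the pool to K communities first."""
        manifest = None
        partitions = self.partitions
        if partitions is None:
            partitions, manifest = self.sweep_pool(sweep or SweepSpec())
        if K is not None:
            partitions = [p for p in partitions if p.K == K]
            if not partitions:
                raise ValueError(f"no partitions with K={K} communities in the pool")
        pool, coeffs, domains, admissible, estimates, fsmap, stability = prune(
            self.network,
            partitions,
            self.gamma_range,
            self.omega_range,
            self.clamp_infinite_omega,
        )
        return PruningResults(
            model=self,
            pool=pool,
            coefficients=coeffs,
            domains=domains,
            admissible=admissible,
            estimates=estimates,
            map_=fsmap,
            stability=stability,
            sweep_manifest=manifest,
            K_restriction=K,
        )

    def fit_restricted(self, K: int, sweep: Optional[SweepSpec] = None) -> "PruningResults":
        """Convenience wrapper for a fixed-K restricted map from the same pool."""
        return self.fit(sweep=sweep, K=K)


@dataclass
class PruningResults:
    """Fitted pruning pipeline: admissible subset, domains, estimates, map, stability."""

    model: PartitionPruning
    pool: list
    coefficients: list
    domains: list
    admissible: list
    estimates: list
    map_: object
    stability: object
    sweep_manifest: Optional[dict] = None
    K_restriction: Optional[int] = None

    # -- basic accessors ----------------------------------------------------

    @property
    def n_pool(self) -> int:
        return len(self.pool)

    @property
    def n_admissible(self) -> int:
        return len(self.admissible)

    @property
    def fixed_point_ids(self) -> list[int]:
        return list(self.stability.fixed_points)

    @property
    def stable_partitions(self) -> list:
        return [self.admissible[s] for s in self.stability.fixed_points]

    @property
    def stable_K(self) -> list[int]:
        return sorted(p.K for p in self.stable_partitions)

    # -- tabular views ------------------------------------------------------

    def frame(self) -> pd.DataFrame:
        """One row per admissible partition."""
        rows = []
        is_1d = self.model.omega_range is None
        for s, (part, dom, est) in enumerate(
            zip(self.admissible, self.domains, self.estimates)
        ):
            row = {
                "state": s,
                "K": part.K,
                "gamma_hat": est.gamma,
                "omega_hat": est.omega,
                "successor": self.map_.successor[s],
                "class": self.stability.classification[s],
            }
            if is_1d:
                row["gamma_lo"], row["gamma_hi"] = dom.gamma_lo, dom.gamma_hi
            else:
                row["domain_area"] = dom.area
                row["domain_centroid"] = dom.centroid()
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        kind = "multilayer" if isinstance(self.model.network, MultilayerNetwork) else "single-layer"
        lines = [
            "Partition pruning results",
            "=" * 64,
            f"network:      {self.model.network!r} ({kind})",
            f"gamma range:  [{self.model.gamma_range[0]:g}, {self.model.gamma_range[1]:g}]",
        ]
        if self.model.omega_range is not None:
            lines.append(
                f"omega range:  [{self.model.omega_range[0]:g}, {self.model.omega_range[1]:g}]"
            )
        if self.K_restriction is not None:
            lines.append(f"restricted:   K = {self.K_restriction}")
        if self.sweep_manifest:
            lines.append(
                f"sweep:        {self.sweep_manifest['total_runs']} runs "
                f"({self.sweep_manifest['backend']})"
            )
        lines += [
            f"pool:         {self.n_pool} unique partitions",
            f"admissible:   {self.n_admissible} somewhere-optimal",
            f"stable:       {len(self.stability.fixed_points)} fixed point(s), "
            f"K = {self.stable_K}",
            f"orbits:       {len(self.stability.orbits)}",
            f"escaped:      {len(self.stability.escaped)}",
            "-" * 64,
        ]
        frame = self.frame()
        with pd.option_context("display.width", 100, "display.max_rows", 200):
            lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    # -- export -------------------------------------------------------------

    def to_report(self) -> dict:
        """JSON-serializable per-state report."""
        states = []
        for s, (part, dom, est) in enumerate(
            zip(self.admissible, self.domains, self.estimates)
        ):
            domain = (
                [dom.gamma_lo, dom.gamma_hi]
                if isinstance(dom, DomainInterval)
                else [list(v) for v in dom.vertices]
            )
            omega = est.omega
            if omega is not None and math.isinf(omega):
                omega = "inf"
            states.append(
                {
                    "state": s,
                    "K": part.K,
                    "domain": domain,
                    "gamma_hat": est.gamma,
                    "omega_hat": omega,
                    "theta_in": est.theta_in,
                    "theta_out": est.theta_out,
                    "p_hat": est.persistence,
                    "successor": self.map_.successor[s],
                    "class": self.stability.classification[s],
                }
            )
        return {
            "n_pool": self.n_pool,
            "n_admissible": self.n_admissible,
            "fixed_points": self.fixed_point_ids,
            "orbits": [list(o) for o in self.stability.orbits],
            "escaped": list(self.stability.escaped),
            "stable_K": self.stable_K,
            "states": states,
        }

    def save_stable_memberships(self, path) -> None:
        """CSV with one membership column per stable partition."""
        import csv

        stable = self.stable_partitions
        ml = isinstance(self.model.network, MultilayerNetwork)
        with open(path, "w", newline="") as fh:
            out = csv.writer(fh)
            header = (["node", "layer"] if ml else ["node"]) + [
                f"stable_{s}_K{p.K}" for s, p in zip(self.stability.fixed_points, stable)
            ]
            out.writerow(header)
            if ml:
                T, n = self.model.network.T, self.model.network.n
                for t in range(T):
                    for i in range(n):
                        out.writerow([i, t] + [int(p.labels[t, i]) for p in stable])
            else:
                for i in range(self.model.network.n):
                    out.writerow([i] + [int(p.labels[i]) for p in stable])

    # -- plotting -----------------------------------------------------------

    def plot_domains(self, ax=None):
        """Domains of optimality colored by K; arrows from domains to estimates."""
        import matplotlib.pyplot as plt
        from matplotlib import cm

        if ax is None:
            _, ax = plt.subplots()
        ks = sorted({p.K for p in self.admissible})
        colors = {K: cm.viridis(i / max(1, len(ks) - 1)) for i, K in enumerate(ks)}
        if self.model.omega_range is None:
            for part, dom, est in zip(self.admissible, self.domains, self.estimates):
                ax.plot(
                    [dom.gamma_lo, dom.gamma_hi], [part.K] * 2,
                    marker="x", color=colors[part.K],
                )
                if est.gamma is not None:
                    ax.annotate(
                        "", xy=(est.gamma, part.K), xytext=(dom.midpoint(), part.K),
                        arrowprops=dict(arrowstyle="->", color="gray", lw=0.8),
                    )
            ax.set_xlabel(r"$\gamma$")
            ax.set_ylabel("K")
        else:
            from matplotlib.patches import Polygon as MplPolygon

            for part, dom, est in zip(self.admissible, self.domains, self.estimates):
                ax.add_patch(
                    MplPolygon(dom.vertices, closed=True, facecolor=colors[part.K],
                               edgecolor="k", lw=0.4, alpha=0.8)
                )
                if est.gamma is not None and est.omega is not None:
                    omega = min(est.omega, self.model.omega_range[1])
                    cx, cy = dom.centroid()
                    ax.annotate(
                        "", xy=(est.gamma, omega), xytext=(cx, cy),
                        arrowprops=dict(arrowstyle="->", color="k", lw=0.6),
                    )
            ax.set_xlim(*self.model.gamma_range)
            ax.set_ylim(*self.model.omega_range)
            ax.set_xlabel(r"$\gamma$")
            ax.set_ylabel(r"$\omega$")
        return ax

    def restricted(self, K: int):
        """Fixed-K map and stability built from the same (already fitted) pool."""
        return restricted_map(
            self.pool, K, self.model.network, self.model.gamma_range,
            self.model.omega_range, self.model.clamp_infinite_omega,
        )
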