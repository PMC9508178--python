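"""Domains of optimality: the upper envelope of partition quality lines/planes.

Each partition's quality is affine in the parameters, Q_tilde(gamma[, omega]) =
A_hat - gamma*P_hat [+ omega*C_hat], so over any set of partitions the pointwise
maximum is a piecewise-linear upper envelope and each partition's domain of
optimality is convex: an interval in gamma, or a convex polygon in (gamma,
omega).  Partitions with an empty domain inside the queried range are nowhere
optimal there; the rest form the admissible subset.

The 1-D envelope is computed by a direct sorted-slope stack sweep (exact up to a
relative tolerance on crossings).  The 2-D envelope first prunes the input to
the upper convex hull of the dual points (-P_hat, C_hat, A_hat) via Qhull and
then clips the query rectangle by the pairwise dominance half-planes of the
surviving planes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .network import (
    Graph,
    MultilayerNetwork,
    QualityCoefficients,
    multilayer_partition_coefficients,
    partition_coefficients,
)

__all__ = [
    "DomainInterval",
    "DomainPolygon",
    "champ_intervals",
    "champ_domains_2d",
    "admissible_subset",
    "compute_coefficients",
]

#: Relative tolerance for crossing/facet comparisons; slivers thinner than this
#: (relative to the query range) are dropped.
REL_TOL = 1e-10


@dataclass(frozen=True)
class DomainInterval:
    """A partition's interval of optimality in gamma."""

    partition_id: int
    gamma_lo: float
    gamma_hi: float
    duplicate_ids: tuple[int, ...] = ()

    @property
    def width(self) -> float:
        return self.gamma_hi - self.gamma_lo

    def contains(self, gamma: float) -> bool:
        return self.gamma_lo <= gamma <= self.gamma_hi

    def midpoint(self) -> float:
        return 0.5 * (self.gamma_lo + self.gamma_hi)


@dataclass(frozen=True)
class DomainPolygon:
    """A partition's convex polygonal domain of optimality in (gamma, omega)."""

    partition_id: int
    vertices: tuple[tuple[float, float], ...]
    duplicate_ids: tuple[int, ...] = ()

    @property
    def area(self) -> float:
        return _polygon_area(np.asarray(self.vertices))

    def centroid(self) -> tuple[float, float]:
        v = np.asarray(self.vertices)
        return (float(v[:, 0].mean()), float(v[:, 1].mean()))

    def contains(self, gamma: float, omega: float, tol: float = 1e-9) -> bool:
        v = np.asarray(self.vertices)
        nxt = np.roll(v, -1, axis=0)
        cross = (nxt[:, 0] - v[:, 0]) * (omega - v[:, 1]) - (nxt[:, 1] - v[:, 1]) * (gamma - v[:, 0])
        return bool(np.all(cross >= -tol) or np.all(cross <= tol))


def _dedup(coeffs: Sequence[QualityCoefficients]) -> tuple[list[int], dict[int, list[int]]]:
    """Collapse exactly-equal coefficient vectors; first occurrence represents."""
    seen: dict[tuple, int] = {}
    dup: dict[int, list[int]] = {}
    order: list[int] = []
    for i, c in enumerate(coeffs):
        key = c.as_tuple()
        if key in seen:
            dup[seen[key]].append(i)
        else:
            seen[key] = i
            dup[i] = []
            order.append(i)
    return order, dup


def champ_intervals(
    coeffs: Sequence[QualityCoefficients], gamma_min: float, gamma_max: float
) -> list[DomainInterval]:
    """Upper envelope of the lines Q_tilde(gamma) = A_hat - gamma*P_hat.

    Returns the admissible intervals sorted by gamma; partitions absent from the
    result are nowhere optimal on [gamma_min, gamma_max].  On a region of exact
    ties the earlier-inserted partition wins.
    """
    if not coeffs:
        raise ValueError("need at least one coefficient set")
    if not gamma_min < gamma_max:
        raise ValueError("gamma_min must be below gamma_max")
    ids, dup = _dedup(coeffs)
    # lines y = a + b*gamma with a = A_hat, b = -P_hat
    lines = [(coeffs[i].A_hat, -coeffs[i].P_hat, i) for i in ids]
    # sort by slope ascending; on slope ties keep only the highest intercept,
    # breaking exact ties toward the earlier id
    lines.sort(key=lambda t: (t[1], -t[0], t[2]))
    filtered: list[tuple[float, float, int]] = []
    for a, b, i in lines:
        if filtered and abs(filtered[-1][1] - b) <= REL_TOL * max(1.0, abs(b)):
            continue  # same slope, lower (or equal) intercept: dominated
        filtered.append((a, b, i))

    def cross(l1, l2) -> float:
        # gamma where l1 and l2 meet
        return (l2[0] - l1[0]) / (l1[1] - l2[1])

    hull: list[tuple[float, float, int]] = []
    breaks: list[float] = []
    for line in filtered:
        while len(hull) >= 2 and cross(hull[-1], line) <= breaks[-1]:
            hull.pop()
            breaks.pop()
        if hull:
            breaks.append(cross(hull[-1], line))
        hull.append(line)

    span = gamma_max - gamma_min
    out: list[DomainInterval] = []
    edges = [gamma_min] + breaks + [gamma_max]
    for (a, b, i), lo, hi in zip(hull, edges[:-1], edges[1:]):
        lo, hi = max(lo, gamma_min), min(hi, gamma_max)
        if hi - lo > REL_TOL * max(1.0, span):
            out.append(DomainInterval(i, lo, hi, tuple(dup[i])))
    return out


def _polygon_area(v: np.ndarray) -> float:
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _clip_halfplane(poly: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Sutherland-Hodgman clip of a convex polygon to a + b*x + c*y >= 0."""
    if len(poly) == 0:
        return poly
    val = a + b * poly[:, 0] + c * poly[:, 1]
    out: list[np.ndarray] = []
    m = len(poly)
    for i in range(m):
        j = (i + 1) % m
        vi, vj = val[i], val[j]
        if vi >= 0:
            out.append(poly[i])
        if (vi >= 0) != (vj >= 0):
            t = vi / (vi - vj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    return np.asarray(out) if out else np.empty((0, 2))


def _upper_hull_candidates(planes: np.ndarray) -> list[int]:
    """Indices of planes on the upper envelope somewhere in (gamma, omega) space.

    Dual points q_i = (-P, C, A); the planes attaining the maximum for some
    (gamma, omega) are the vertices of facets whose outward normal points up in
    the A-direction.
    """
    if len(planes) <= 4:
        return list(range(len(planes)))
    pts = planes[:, [1, 2, 0]].copy()
    pts[:, 0] *= -1.0  # (-P, C, A)
    try:
        hull = ConvexHull(pts, qhull_options="Qt")
    except QhullError:
        return list(range(len(planes)))
    upper: set[int] = set()
    for eq, simplex in zip(hull.equations, hull.simplices):
        if eq[2] > 1e-12:  # outward normal has positive A-component
            upper.update(int(s) for s in simplex)
    return sorted(upper) if upper else list(range(len(planes)))


def champ_domains_2d(
    coeffs: Sequence[QualityCoefficients],
    gamma_range: tuple[float, float],
    omega_range: tuple[float, float],
) -> list[DomainPolygon]:
    """Upper envelope of the planes Q_tilde(gamma, omega) over a query rectangle.

    Each returned polygon is one plane's domain of optimality clipped to the
    rectangle; together they tile it (up to the crossing tolerance).
    """
    if not coeffs:
        raise ValueError("need at least one coefficient set")
    g0, g1 = gamma_range
    w0, w1 = omega_range
    if not (g0 < g1 and w0 < w1):
        raise ValueError("degenerate query rectangle")
    ids, dup = _dedup(coeffs)
    planes = np.array([coeffs[i].as_tuple() for i in ids])  # rows (A, P, C)
    cand = _upper_hull_candidates(planes)
    box = np.array([[g0, w0], [g1, w0], [g1, w1], [g0, w1]], dtype=float)
    box_area = (g1 - g0) * (w1 - w0)
    out: list[DomainPolygon] = []
    for ci in cand:
        A, P, C = planes[ci]
        poly = box
        for cj in cand:
            if cj == ci or len(poly) == 0:
                continue
            Aj, Pj, Cj = planes[cj]
            da, db, dc = A - Aj, -(P - Pj), C - Cj
            if da == db == dc == 0.0:
                continue
            # earlier-inserted id wins exact ties: strict dominance required of later ids
            poly = _clip_halfplane(poly, da, db, dc)
        if len(poly) >= 3 and _polygon_area(poly) > REL_TOL * box_area:
            i = ids[ci]
            out.append(DomainPolygon(i, tuple(map(tuple, poly)), tuple(dup[i])))
    return out


def compute_coefficients(network, partitions) -> list[QualityCoefficients]:
    """Quality coefficients for a list of partitions of a (multilayer) network."""
    if isinstance(network, MultilayerNetwork):
        return [multilayer_partition_coefficients(network, p) for p in partitions]
    return [partition_coefficients(network, p) for p in partitions]


def admissible_subset(
    partitions,
    network,
    gamma_range: tuple[float, float],
    omega_range: Optional[tuple[float, float]] = None,
):
    """The somewhere-optimal partitions and their domains within the query range.

    Partitions are deduplicated by canonical labels first; the returned domain
    list references indices into the deduplicated pool, which is also returned.
    Calling it again on its own output is a no-op (same subset, same domains).
    """
    pool = list(dict.fromkeys(partitions))
    if not pool:
        raise ValueError("empty partition pool")
    coeffs = compute_coefficients(network, pool)
    if omega_range is None:
        domains = champ_intervals(coeffs, *gamma_range)
    else:
        domains = champ_domains_2d(coeffs, gamma_range, omega_range)
    admissible = [pool[d.partition_id] for d in domains]
    return pool, coeffs, domains, admissible
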