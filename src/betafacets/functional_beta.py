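"""Functional beta-diversity from convex-hull volumes in trait space.

Each assemblage is the convex hull of its species' coordinates on the first
m principal axes.  For a pair of assemblages with hull volumes V1, V2 and
shared volume Vi = V(hull1 intersect hull2):

    beta     = (V1 + V2 - 2 Vi) / (V1 + V2 - Vi)
    turnover = (2 min(V1, V2) - 2 Vi) / (2 min(V1, V2) - Vi)
    nestedness = beta - turnover

so beta is the Jaccard-family dissimilarity of volumes and the partition is
additive, mirroring the taxonomic case with volumes in place of species
counts.  The nestedness residual equals the closed form

    (|V1 - V2| / (V1 + V2 - Vi)) * (Vi / (2 min(V1, V2) - Vi)),

which the unit tests verify on analytic fixtures.

The pairwise intersection is computed exactly: the two hulls' facet
halfspaces are pooled, an interior point of the joint system is certified by
a Chebyshev-centre linear program, and the vertex enumeration of the joint
polytope gives the shared volume.  If no interior point of radius greater
than a small tolerance exists the interiors do not meet and the shared
volume is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .io_tables import OccurrenceMatrix
from .taxonomic_beta import BetaTriple, PairwiseBetaTable
from .trait_space import FunctionalSpace

log = logging.getLogger(__name__)

#: Chebyshev radius below which two hulls are declared non-overlapping
INTERIOR_RADIUS_TOL = 1e-9


class DegenerateHullError(ValueError):
    """A point set does not span a full-dimensional convex hull."""


@dataclass
class HullVolumes:
    """Volumes of two assemblage hulls and of their intersection."""

    v1: float
    v2: float
    v_inter: float

    def __post_init__(self) -> None:
        if min(self.v1, self.v2, self.v_inter) < 0:
            raise ValueError("volumes must be non-negative")
        if self.v_inter > min(self.v1, self.v2) * (1 + 1e-9) + 1e-12:
            raise ValueError("intersection volume exceeds min(v1, v2)")


def hull_volume(points: np.ndarray, m: int | None = None, *,
                label: str | None = None) -> float:
    """Volume of the convex hull of a point set.

    Requires at least m+1 affinely independent points; degenerate sets raise
    :class:`DegenerateHullError` naming the assemblage if ``label`` is given.
    """
    hull = _hull(points, m, label)
    return float(hull.volume)


def _hull(points: np.ndarray, m: int | None, label: str | None) -> ConvexHull:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    dim = pts.shape[1] if m is None else m
    if pts.shape[1] != dim:
        raise ValueError(f"points have dimension {pts.shape[1]}, expected {dim}")
    who = f" for assemblage {label!r}" if label else ""
    if pts.shape[0] < dim + 1:
        raise DegenerateHullError(
            f"need at least {dim + 1} points in {dim}-D{who}, got {pts.shape[0]}"
        )
    try:
        return ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate (affinely dependent) point set{who}: {exc}"
        ) from None


def _chebyshev_centre(halfspaces: np.ndarray) -> tuple[np.ndarray, float]:
    """Largest inscribed ball of {x : A x + b <= 0} via linear programming.

    Halfspaces are rows [a, b] in qhull convention (a . x + b <= 0).  Returns
    (centre, radius); radius <= 0 means the interior is empty.
    """
    A = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    dim = A.shape[1]
    c = np.zeros(dim + 1)
    c[-1] = -1.0  # maximise the radius
    res = linprog(
        c,
        A_ub=np.hstack([A, norms]),
        b_ub=-b,
        bounds=[(None, None)] * dim + [(0, None)],
        method="highs",
    )
    if not res.success:
        return np.zeros(dim), -np.inf
    return res.x[:-1], float(res.x[-1])


def intersection_volume(A: np.ndarray, B: np.ndarray, m: int | None = None) -> float:
    """Volume of the intersection of the convex hulls of two point sets.

    Returns 0 when the hull interiors do not meet (certified by the
    Chebyshev-centre program); lower-dimensional contact counts as volume 0.
    """
    hull_a = _hull(A, m, None)
    hull_b = _hull(B, m, None)
    return _intersection_volume_hulls(hull_a.equations, hull_b.equations)


def _intersection_volume_hulls(eq_a: np.ndarray, eq_b: np.ndarray) -> float:
    halfspaces = np.vstack([eq_a, eq_b])
    centre, radius = _chebyshev_centre(halfspaces)
    if radius <= INTERIOR_RADIUS_TOL:
        return 0.0
    try:
        hs = HalfspaceIntersection(halfspaces, centre)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        log.warning("halfspace intersection failed numerically at radius "
                    "%.3g; treating overlap as empty", radius)
        return 0.0


def partition_from_volumes(v1: float, v2: float, v_inter: float) -> BetaTriple:
    """Jaccard-family volume dissimilarity partitioned into turnover and
    nestedness."""
    if v1 <= 0 or v2 <= 0:
        raise DegenerateHullError("both hull volumes must be positive")
    vi = min(v_inter, v1, v2)  # guard tiny numerical overshoot
    union = v1 + v2 - vi
    beta = (v1 + v2 - 2 * vi) / union
    mn2 = 2 * min(v1, v2)
    turnover = (mn2 - 2 * vi) / (mn2 - vi) if (mn2 - vi) > 0 else 0.0
    return BetaTriple(beta=beta, turnover=turnover, nestedness=beta - turnover)


def functional_partition(A: np.ndarray, B: np.ndarray, m: int | None = None) -> BetaTriple:
    """BetaTriple for two assemblages given their species coordinates."""
    hull_a = _hull(A, m, None)
    hull_b = _hull(B, m, None)
    vi = _intersection_volume_hulls(hull_a.equations, hull_b.equations)
    return partition_from_volumes(hull_a.volume, hull_b.volume, vi)


def pairwise_functional(occ: OccurrenceMatrix, space: FunctionalSpace, *,
                        drop_small_basins: bool = False) -> PairwiseBetaTable:
    """Functional BetaTriple for every unordered basin pair.

    Every basin must contain at least m+1 species whose coordinates span a
    full-dimensional hull.  Offending basins are listed in a single
    :class:`DegenerateHullError` before any pair is computed; with
    ``drop_small_basins=True`` they are instead removed (logged) and the
    table covers the remaining basins only.
    """
    idx = {s: k for k, s in enumerate(space.species)}
    missing = [s for s in occ.species if s not in idx]
    if missing:
        raise ValueError(f"species missing from the functional space: {missing[:5]}")
    rows = np.array([idx[s] for s in occ.species])
    hulls: dict[str, ConvexHull] = {}
    bad: list[str] = []
    for j, basin in enumerate(occ.basins):
        present = rows[occ.values[:, j] == 1]
        pts = space.coordinates[present]
        try:
            hulls[basin] = _hull(pts, space.m, basin)
        except DegenerateHullError:
            bad.append(basin)
    if bad:
        if not drop_small_basins:
            raise DegenerateHullError(
                f"basin(s) without a full-dimensional {space.m}-D hull: {bad}"
            )
        log.warning("dropping basin(s) without a full-dimensional hull: %s", bad)
    basins = [b for b in occ.basins if b in hulls]
    pairs = []
    values = []
    for i in range(len(basins)):
        for j in range(i + 1, len(basins)):
            ha, hb = hulls[basins[i]], hulls[basins[j]]
            vi = _intersection_volume_hulls(ha.equations, hb.equations)
            triple = partition_from_volumes(ha.volume, hb.volume, vi)
            pairs.append((basins[i], basins[j]))
            values.append((triple.beta, triple.turnover, triple.nestedness))
    return PairwiseBetaTable(
        facet="functional",
        scenario=occ.scenario,
        basin_pairs=pairs,
        values=np.asarray(values, dtype=float),
    )
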