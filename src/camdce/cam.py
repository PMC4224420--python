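"""Convex analysis of mixtures: vertex identification on the scatter simplex.

Sum-normalized pixel time-courses are nonnegative mixtures of normalized
compartment curves, so they occupy a convex set whose vertices are the
compartment curves themselves (given linear independence and at least one
pure-volume pixel per compartment). This module measures the distance of a
point to the convex hull of a candidate vertex set (the margin of error)
and exhaustively searches all C(M, J) subsets of cluster centers for the
one whose hull most tightly encloses the remaining centers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import nnls

from .clustering import ClusterSet
from .series import DynamicSeries

__all__ = [
    "VertexSolution",
    "margin_of_error",
    "project_onto_hull",
    "enumerate_vertex_sets",
    "convexity_projection",
]

_MARGIN_TOL = 1e-9


@dataclass
class VertexSolution:
    """The minimizing vertex subset of the hull-to-data fitting search."""

    vertex_cluster_index: np.ndarray  # (J,) cluster indices chosen as vertices
    total_margin: float               # sum of exterior margins at the optimum
    per_center_margin: np.ndarray     # (M,) margin of every center (0 at vertices)
    candidate_count: int              # number of subsets searched, C(M, J)

    def __post_init__(self) -> None:
        self.vertex_cluster_index = np.asarray(self.vertex_cluster_index, dtype=int)
        self.per_center_margin = np.asarray(self.per_center_margin, dtype=float)
        if np.unique(self.vertex_cluster_index).size != self.vertex_cluster_index.size:
            raise ValueError("vertex indices must be distinct")
        if self.total_margin < -_MARGIN_TOL or np.any(
            self.per_center_margin < -_MARGIN_TOL
        ):
            raise ValueError("margins must be nonnegative")

    @property
    def n_vertices(self) -> int:
        return self.vertex_cluster_index.size


def project_onto_hull(point: np.ndarray, vertices: np.ndarray) -> tuple[float, np.ndarray]:
    """Euclidean projection of ``point`` onto the convex hull of ``vertices``.

    ``vertices`` is ``(T, J)`` with one column per vertex. Solves

        min_{alpha >= 0, sum(alpha) = 1} || point - vertices @ alpha ||_2

    via nonnegative least squares with a penalty row enforcing the simplex
    constraint, followed by an exact equality-constrained solve on the
    detected support. Returns ``(margin, alpha)``.
    """
    point = np.asarray(point, dtype=float).ravel()
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] == 0:
        raise ValueError("vertex set must be a nonempty (T, J) matrix")
    if v.shape[0] != point.size:
        raise ValueError("point and vertices must share the time dimension")
    t, j = v.shape
    if j == 1:
        alpha = np.array([1.0])
        return float(np.linalg.norm(point - v[:, 0])), alpha

    rho = 1e6 * max(1.0, float(np.abs(v).max()))
    a = np.vstack([v, rho * np.ones((1, j))])
    b = np.concatenate([point, [rho]])
    alpha, _ = nnls(a, b)

    support = np.flatnonzero(alpha > 1e-12)
    if support.size == 0:
        support = np.array([int(np.argmax(alpha))])
    polished = _polish_on_support(point, v, support)
    if polished is not None:
        alpha = polished
    else:
        s = alpha.sum()
        if s > 0:
            alpha = alpha / s
    return float(np.linalg.norm(point - v @ alpha)), alpha


def _polish_on_support(
    point: np.ndarray, v: np.ndarray, support: np.ndarray
) -> np.ndarray | None:
    """Exact equality-constrained least squares on a fixed support.

    Solves the KKT system of min ||x - V_S a||^2 s.t. 1'a = 1 and returns the
    full-length weight vector, or None if the solution leaves the simplex.
    """
    vs = v[:, support]
    k = support.size
    g = vs.T @ vs
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * g
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * (vs.T @ point), [1.0]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    a_s = sol[:k]
    if np.any(a_s < -1e-10):
        return None
    a_s = np.clip(a_s, 0.0, None)
    s = a_s.sum()
    if s <= 0:
        return None
    a_s /= s
    alpha = np.zeros(v.shape[1])
    alpha[support] = a_s
    return alpha


def margin_of_error(point: np.ndarray, vertices: np.ndarray) -> float:
    """Distance between a point and the convex hull of a vertex set.

    Zero (to within 1e-9) exactly when the point lies inside the hull.
    """
    margin, _ = project_onto_hull(point, vertices)
    return margin


def enumerate_vertex_sets(clusters: ClusterSet | np.ndarray, J: int) -> VertexSolution:
    """Exhaustive hull-to-data search for the J most probable vertices.

    Evaluates all C(M, J) subsets of the M cluster centers; the objective of
    a subset is the summed margin of the M - J non-selected centers to the
    subset's convex hull. Ties are broken toward the lexicographically
    smallest index tuple (subsets are visited in that order and only a
    strictly smaller objective replaces the incumbent).
    """
    centers = clusters.centers if isinstance(clusters, ClusterSet) else np.asarray(clusters, float)
    m = centers.shape[0]
    if not 2 <= J <= m:
        raise ValueError(f"J must satisfy 2 <= J <= M (got J={J}, M={m})")

    points = centers.T  # (T, M)
    best_obj = np.inf
    best_subset: tuple[int, ...] | None = None
    best_margins: np.ndarray | None = None
    count = 0
    for subset in combinations(range(m), J):
        count += 1
        v = points[:, subset]
        exterior = np.setdiff1d(np.arange(m), subset, assume_unique=True)
        margins = np.zeros(m)
        obj = 0.0
        for i in exterior:
            margins[i], _ = project_onto_hull(points[:, i], v)
            obj += margins[i]
            if obj >= best_obj:
                break
        else:
            if obj < best_obj:
                best_obj = obj
                best_subset = subset
                best_margins = margins
            continue
    assert best_subset is not None and best_margins is not None
    return VertexSolution(
        vertex_cluster_index=np.array(best_subset),
        total_margin=float(best_obj),
        per_center_margin=best_margins,
        candidate_count=count,
    )


def convexity_projection(
    points: DynamicSeries | ClusterSet | np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Project points onto the 2-D principal plane of the vertex set.

    Used for scatter-simplex visualization: the affine plane through the
    vertex centroid spanned by the top two principal directions of the
    vertices minimizes the summed projection residual of the vertices, so
    the hull stays maximally spread. Affine maps preserve convex
    combinations, so interior points project inside the projected hull.
    """
    if isinstance(points, DynamicSeries):
        x = points.values.T
    elif isinstance(points, ClusterSet):
        x = points.centers
    else:
        x = np.asarray(points, dtype=float)
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] < 3:
        warnings.warn(
            "fewer than 3 vertices; falling back to the first two coordinates",
            RuntimeWarning,
            stacklevel=2,
        )
        return x[:, :2].copy()
    center = v.mean(axis=1)
    _, _, vt = np.linalg.svd((v - center[:, None]).T, full_matrices=False)
    basis = vt[:2]  # (2, T)
    return (x - center) @ basis.T
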