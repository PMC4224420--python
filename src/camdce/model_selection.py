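"""Minimum-description-length selection of the number of compartments.

For each candidate J the vertex search is run on the M cluster centers,
and the candidate model — the convex hull of the J chosen vertex curves —
is scored by its total description length: the negative Gaussian
log-likelihood of the data under "every curve is a convex combination of
the vertices plus i.i.d. noise", plus half the parameter count times the
log of the data size,

    L(J) = -log p(data | model) + (P/2) * log(n),

with P counting the vertex-curve values, the mixing weights that are
actually nonzero, and the noise variance. The preferred likelihood is over
the N pixel time-courses (n = N*T); a cluster-center surrogate is
available when only the centers are at hand. The chosen J is the argmin;
ties break toward the smaller (more parsimonious) J.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cam import VertexSolution, enumerate_vertex_sets, project_onto_hull
from .clustering import ClusterSet
from .series import DynamicSeries

__all__ = ["ModelSelectionResult", "code_length", "select_num_compartments"]

_VAR_FLOOR = 1e-12


@dataclass
class ModelSelectionResult:
    candidates: np.ndarray              # evaluated J values
    code_length: np.ndarray             # MDL value per candidate
    chosen_J: int                       # argmin (smallest J on ties)
    fit_per_J: dict[int, VertexSolution]

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=int)
        self.code_length = np.asarray(self.code_length, dtype=float)
        if self.chosen_J not in self.candidates:
            raise ValueError("chosen_J must be one of the evaluated candidates")
        if not np.all(np.isfinite(self.code_length)):
            raise ValueError("code lengths must be finite")

    @property
    def solution(self) -> VertexSolution:
        """The vertex solution at the chosen J."""
        return self.fit_per_J[self.chosen_J]


def code_length(
    clusters: ClusterSet,
    solution: VertexSolution,
    J: int,
    series: DynamicSeries | None = None,
    weighted: bool = True,
) -> float:
    """MDL code length of a fitted J-vertex compartment model.

    When the normalized ``series`` is supplied (the default inside the
    pipeline), every pixel time-course is modeled as some convex
    combination of the J vertex curves plus i.i.d. Gaussian noise; the
    residual of a pixel is its margin to the hull, the noise variance is
    the maximum-likelihood estimate over all N*T values, and the freely
    adjustable parameters are the J*T vertex-curve values, the per-pixel
    mixing weights that are actually nonzero (the nonnegative projection
    zeroes the rest exactly, so a two-part code need not pay for them) and
    the variance. Charging only the active weights penalizes a vertex in
    proportion to how many pixels truly use it: a vertex that merely
    absorbs a noise dimension attracts few active weights yet still costs
    its T curve values, while an unmodeled compartment leaves a large
    likelihood deficit.

    Without the series the likelihood falls back to the cluster centers:
    size-weighted margins plus the within-cluster scatter when ``weighted``
    (an aggregated surrogate for the pixel likelihood), or the plain
    unweighted center margins otherwise.
    """
    m, t = clusters.centers.shape
    if solution.n_vertices != J:
        raise ValueError("solution was fitted for a different J")
    if series is not None:
        if not series.normalized:
            raise ValueError("code_length expects the sum-normalized series")
        vertices = clusters.centers[solution.vertex_cluster_index].T
        n_data = series.n_pixels
        sse = 0.0
        n_weights = 0
        for i in range(n_data):
            margin, alpha = project_onto_hull(series.values[:, i], vertices)
            sse += margin * margin
            # only the simplex dimensions a pixel actually uses are coded;
            # the nonnegativity constraint zeroes the rest exactly
            n_weights += max(int(np.sum(alpha > 1e-9)) - 1, 0)
    elif weighted and clusters.assignment.size:
        margins_sq = solution.per_center_margin**2
        n_data = clusters.assignment.size
        sse = clusters.within_ss + float(np.sum(clusters.sizes * margins_sq))
        n_weights = m * (J - 1)
    else:
        n_data = m
        sse = float(np.sum(solution.per_center_margin**2))
        n_weights = m * (J - 1)
    n = n_data * t
    var = sse / n
    if var < _VAR_FLOOR:
        warnings.warn(
            "zero residual variance in MDL likelihood; applying floor",
            RuntimeWarning,
            stacklevel=2,
        )
        var = _VAR_FLOOR
    neg_log_lik = 0.5 * n * (np.log(2 * np.pi * var) + 1.0)
    n_params = J * t + n_weights + 1
    return float(neg_log_lik + 0.5 * n_params * np.log(n))


def select_num_compartments(
    clusters: ClusterSet,
    j_min: int = 2,
    j_max: int = 6,
    series: DynamicSeries | None = None,
) -> ModelSelectionResult:
    """Sweep candidate compartment counts and pick the MDL argmin.

    Pass the normalized ``series`` to score candidates with the pixel-level
    likelihood (recommended); otherwise the cluster-center surrogate is
    used.
    """
    if j_min > j_max:
        raise ValueError("j_min must not exceed j_max")
    if j_min < 2:
        raise ValueError("candidate J must be at least 2")
    if j_max > clusters.n_clusters:
        raise ValueError(
            f"j_max={j_max} exceeds the number of clusters M={clusters.n_clusters}"
        )
    candidates = np.arange(j_min, j_max + 1)
    lengths = np.empty(candidates.size)
    fits: dict[int, VertexSolution] = {}
    for i, j in enumerate(candidates):
        fits[int(j)] = enumerate_vertex_sets(clusters, int(j))
        lengths[i] = code_length(clusters, fits[int(j)], int(j), series=series)
    chosen = int(candidates[int(np.argmin(lengths))])  # argmin takes first = smallest J
    return ModelSelectionResult(
        candidates=candidates,
        code_length=lengths,
        chosen_J=chosen,
        fit_per_J=fits,
    )
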