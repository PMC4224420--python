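"""Clustering of normalized pixel time-courses.

Pixel curves are aggregated into M representative clusters before convex
analysis, which denoises the scatter simplex and gives the description-
length criterion a small set of points to score. Clustering is affinity
propagation — an exemplar-based, initialization-free message-passing scheme
— followed by an expectation-maximization refinement of the cluster centers
under a Gaussian mixture with a shared isotropic covariance.

Affinity propagation exchanges two kinds of real-valued messages between
data points. The responsibility r(i, m) accumulates evidence that point m
should serve as the exemplar for point i, and the availability a(i, m)
accumulates evidence that point i should choose m as its exemplar:

    r(i, m) <- s(i, m) - max_{m' != m} [ a(i, m') + s(i, m') ]
    a(i, m) <- min{0, r(m, m) + sum_{i' not in {i, m}} max(0, r(i', m))}
    a(m, m) <- sum_{i' != m} max(0, r(i', m))

Messages are damped (new = lambda*old + (1-lambda)*computed) and iteration
stops once the exemplar set has been stable for a fixed window of
consecutive iterations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import DynamicSeries

__all__ = [
    "ClusterSet",
    "similarity_matrix",
    "affinity_propagation",
    "cluster_series",
    "em_refine",
]

_CENTER_SUM_TOL = 1e-6


@dataclass
class ClusterSet:
    """M cluster centers of normalized pixel time-courses with assignments."""

    centers: np.ndarray          # (M, T), rows are normalized curves
    assignment: np.ndarray       # (N,) pixel -> cluster
    exemplar_index: np.ndarray   # (M,) pixel index of each exemplar
    sizes: np.ndarray            # (M,) member counts
    converged: bool = True
    n_iter: int = 0
    log_likelihood: np.ndarray | None = None  # EM trace when refined
    within_ss: float = 0.0  # total within-cluster sum of squares of the pixels

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.exemplar_index = np.asarray(self.exemplar_index, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        m = self.centers.shape[0]
        if self.exemplar_index.size != m or self.sizes.size != m:
            raise ValueError("exemplar_index and sizes must have one entry per cluster")
        if self.assignment.size and (
            self.assignment.min() < 0 or self.assignment.max() >= m
        ):
            raise ValueError("every pixel must be assigned to a valid cluster")
        if int(self.sizes.sum()) != self.assignment.size:
            raise ValueError("cluster sizes must sum to the number of pixels")
        if self.centers.size:
            if self.centers.min() < -1e-12:
                raise ValueError("cluster centers must be nonnegative")
            sums = self.centers.sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > _CENTER_SUM_TOL:
                raise ValueError("cluster-center rows must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def similarity_matrix(
    series: DynamicSeries,
    preference: float | None = None,
    jitter: float = 1e-6,
) -> np.ndarray:
    """Negative squared Euclidean similarities between normalized pixel curves.

    Off-diagonal: s(i, m) = -||x_i - x_m||^2. The diagonal holds the
    affinity-propagation preference; by default the median of the
    off-diagonal similarities, which yields a moderate number of exemplars.

    ``jitter`` adds a symmetric, deterministic perturbation of relative
    magnitude ``jitter`` times the similarity scale. Identical or
    near-duplicate pixel curves make the message-passing dynamics
    degenerate (tied candidates oscillate indefinitely); a perturbation far
    below the noise level breaks the ties without moving any real
    structure. Set ``jitter=0`` for the exact distances.
    """
    if not series.normalized:
        raise ValueError("similarities are defined on a sum-normalized series")
    x = series.values.T  # (N, T)
    sq = np.sum(x**2, axis=1)
    s = -(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T))
    np.fill_diagonal(s, 0.0)
    s = np.minimum(s, 0.0)  # clamp roundoff
    n = s.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    if jitter and n > 1:
        scale = float(np.median(np.abs(s[off_mask]))) or 1.0
        rng = np.random.default_rng(0)
        noise = jitter * scale * rng.standard_normal(s.shape)
        s = s + (noise + noise.T) / 2.0
        s = np.minimum(s, 0.0)
    if preference is None:
        preference = float(np.median(s[off_mask])) if n > 1 else 0.0
    np.fill_diagonal(s, preference)
    return s


def affinity_propagation(
    similarities: np.ndarray,
    damping: float = 0.7,
    max_iter: int = 1000,
    convergence_window: int = 10,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Run affinity propagation on a square similarity matrix.

    Returns ``(exemplars, labels, n_iter, converged)`` where ``exemplars``
    are data-point indices and ``labels`` maps each point to a position in
    ``exemplars``. Convergence requires the exemplar set to remain unchanged
    for ``convergence_window`` consecutive iterations.
    """
    s = np.asarray(similarities, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must lie in [0.5, 1)")
    n = s.shape[0]
    if n == 1:
        return np.array([0]), np.array([0]), 0, True

    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        asr = a + s
        first = np.argmax(asr, axis=1)
        max1 = asr[idx, first]
        asr[idx, first] = -np.inf
        max2 = np.max(asr, axis=1)
        asr[idx, first] = max1
        r_new = s - max1[:, None]
        r_new[idx, first] = s[idx, first] - max2
        r = damping * r + (1 - damping) * r_new

        # availabilities
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, 0.0)
        col = rp.sum(axis=0)
        a_new = np.minimum(0.0, r[idx, idx][None, :] + col[None, :] - rp)
        a_new[idx, idx] = col
        a = damping * a + (1 - damping) * a_new

        exemplars = np.flatnonzero(np.argmax(a + r, axis=1) == idx)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_window and exemplars.size > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.flatnonzero(np.argmax(a + r, axis=1) == idx)
    if exemplars.size == 0:
        # degenerate run: fall back to the single best self-evidence point
        exemplars = np.array([int(np.argmax(np.diag(a + r)))])
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge in {it} iterations; "
            "returning the current exemplar set",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = np.argmax(s[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    # finalize each exemplar as the most central member of its cluster (the
    # member maximizing the within-cluster similarity sum), the standard
    # post-convergence refinement of the reference algorithm
    for k in range(exemplars.size):
        members = np.flatnonzero(labels == k)
        sub = s[np.ix_(members, members)]
        np.fill_diagonal(sub, 0.0)
        exemplars[k] = members[int(np.argmax(sub.sum(axis=0)))]
    order = np.argsort(exemplars)
    exemplars = exemplars[order]
    labels = np.argmax(s[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    return exemplars, labels, it, converged


def cluster_series(
    series: DynamicSeries,
    damping: float = 0.7,
    preference: float | None = None,
    max_iter: int = 1000,
    convergence_window: int = 10,
    dedupe_limit: int = 32,
) -> ClusterSet:
    """Cluster a normalized series with affinity propagation.

    Cluster centers are the means of member pixel curves, re-normalized to
    the unit simplex (member means of simplex points already sum to one).

    Exactly duplicated time-courses (noise-free or quantized data) are
    collapsed first: they are degenerate input for message passing, and
    aggregating identical pixels is precisely what clustering is for. When
    at most ``dedupe_limit`` distinct profiles remain, each one becomes its
    own cluster and message passing is skipped entirely.
    """
    x = series.values.T
    uniq, first_idx, inverse = np.unique(
        np.round(x, 12), axis=0, return_index=True, return_inverse=True
    )
    if uniq.shape[0] < x.shape[0] and uniq.shape[0] <= dedupe_limit:
        labels = inverse
        exemplars = first_idx
        n_iter, converged = 0, True
    else:
        s = similarity_matrix(series, preference=preference)
        exemplars, labels, n_iter, converged = affinity_propagation(
            s, damping=damping, max_iter=max_iter,
            convergence_window=convergence_window,
        )
    m = exemplars.size
    centers = np.empty((m, x.shape[1]))
    sizes = np.empty(m, dtype=int)
    for k in range(m):
        members = labels == k
        sizes[k] = int(members.sum())
        centers[k] = x[members].mean(axis=0)
    centers /= centers.sum(axis=1, keepdims=True)
    within = float(np.sum((x - centers[labels]) ** 2))
    return ClusterSet(
        centers=centers,
        assignment=labels,
        exemplar_index=exemplars,
        sizes=sizes,
        converged=converged,
        n_iter=n_iter,
        within_ss=within,
    )


def em_refine(
    series: DynamicSeries,
    init: ClusterSet,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterSet:
    """Refine cluster centers by EM under a shared-isotropic Gaussian mixture.

    The mixture has means initialized at the affinity-propagation centers,
    one scalar variance shared by all components, and weights proportional
    to cluster sizes. Returns re-normalized refined centers with hard
    assignments; the per-iteration log-likelihood trace (guaranteed
    non-decreasing) is stored on the result. Deterministic given the
    initialization; ``seed`` is accepted for interface stability.
    """
    del seed  # EM from a fixed initialization is deterministic
    x = series.values.T  # (N, T)
    n, t = x.shape
    mu = init.centers.copy()
    m = mu.shape[0]
    pi = init.sizes / init.sizes.sum()
    d2 = _sqdist(x, mu)
    var = max(float(np.sum(pi * d2.mean(axis=0)) / t), 1e-12)

    trace = []
    prev_ll = -np.inf
    resp = None
    for _ in range(max_iter):
        logp = -0.5 * d2 / var - 0.5 * t * np.log(2 * np.pi * var)
        logw = logp + np.log(np.maximum(pi, 1e-300))
        mx = logw.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logw - mx).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        if ll - prev_ll < tol * max(1.0, abs(ll)) and len(trace) > 1:
            break
        prev_ll = ll
        resp = np.exp(logw - lse[:, None])
        nk = resp.sum(axis=0)
        keep = nk > 1e-10
        if not keep.all():
            warnings.warn(
                "dropping empty mixture component(s) during EM refinement",
                RuntimeWarning,
                stacklevel=2,
            )
            resp = resp[:, keep]
            nk = nk[keep]
            mu = mu[keep]
            m = mu.shape[0]
        pi = nk / n
        mu = (resp.T @ x) / nk[:, None]
        d2 = _sqdist(x, mu)
        var = float(np.sum(resp * d2) / (n * t))
        if var < 1e-12:
            warnings.warn(
                "near-singular shared covariance; applying ridge floor",
                RuntimeWarning,
                stacklevel=2,
            )
            var = 1e-12

    assignment = np.argmax(-0.5 * d2 / var + np.log(np.maximum(pi, 1e-300)), axis=1)
    # guard against components that lost all members in the hard assignment
    used = np.unique(assignment)
    if used.size < m:
        remap = -np.ones(m, dtype=int)
        remap[used] = np.arange(used.size)
        assignment = remap[assignment]
        mu = mu[used]
        m = used.size
    sizes = np.bincount(assignment, minlength=m)
    mu = np.maximum(mu, 0.0)
    mu /= mu.sum(axis=1, keepdims=True)
    exemplar = np.empty(m, dtype=int)
    for k in range(m):
        exemplar[k] = int(np.argmin(np.sum((x - mu[k]) ** 2, axis=1)))
    return ClusterSet(
        centers=mu,
        assignment=assignment,
        exemplar_index=exemplar,
        sizes=sizes,
        converged=True,
        n_iter=len(trace),
        log_likelihood=np.asarray(trace),
        within_ss=float(np.sum((x - mu[assignment]) ** 2)),
    )


def _sqdist(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    return (
        np.sum(x**2, axis=1)[:, None]
        - 2.0 * (x @ mu.T)
        + np.sum(mu**2, axis=1)[None, :]
    )
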