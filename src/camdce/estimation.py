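"""Pharmacokinetic parameter estimation from identified vertex curves.

Once the J vertices of the scatter simplex are identified, the vertex with
the fastest tracer enhancement is taken as the plasma input C_p. Each
tissue vertex curve is fitted by the convolution model
Ktrans * (C_p (*) exp(-kep t)), discretized through a lower-triangular
Toeplitz matrix built from the sampled plasma input. Per-pixel local
volume transfer constants (and the local plasma volume fraction) are then
recovered by nonnegative least squares against the compartment basis.

Because the pipeline operates on sum-normalized curves, Ktrans values are
relative (shape information only); kep is an absolute rate in /min.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz
from scipy.optimize import minimize_scalar, nnls

from .series import DynamicSeries, PlasmaInput

__all__ = [
    "CompartmentBasis",
    "TransferMaps",
    "FluxRateFit",
    "LongitudinalComparison",
    "identify_plasma_vertex",
    "toeplitz_input_matrix",
    "fit_flux_rate",
    "fit_local_transfer_maps",
    "partial_volume_fraction",
    "longitudinal_compare",
]

_BASIS_SUM_TOL = 1e-6


@dataclass
class CompartmentBasis:
    """J normalized compartment curves (the mixing-matrix columns)."""

    curves: np.ndarray            # (T, J), columns sum to 1
    plasma_index: int             # column identified as C_p
    source_vertex: np.ndarray | None = None  # cluster index of each column

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2:
            raise ValueError("curves must be (T, J)")
        if self.curves.min() < -1e-12:
            raise ValueError("compartment curves must be nonnegative")
        sums = self.curves.sum(axis=0)
        if np.max(np.abs(sums - 1.0)) > _BASIS_SUM_TOL:
            raise ValueError("compartment curves must each sum to 1")
        if not 0 <= self.plasma_index < self.curves.shape[1]:
            raise ValueError("plasma_index out of range")
        if np.linalg.matrix_rank(self.curves) < self.curves.shape[1]:
            raise ValueError("compartment curves must be linearly independent")
        if self.source_vertex is not None:
            self.source_vertex = np.asarray(self.source_vertex, dtype=int)

    @property
    def n_compartments(self) -> int:
        return self.curves.shape[1]

    @property
    def tissue_indices(self) -> np.ndarray:
        return np.array(
            [j for j in range(self.n_compartments) if j != self.plasma_index]
        )


@dataclass
class TransferMaps:
    """Per-pixel local transfer constants and plasma volume fraction."""

    ktrans_local: np.ndarray        # (N, J-1) nonnegative, relative units
    vp_local: np.ndarray            # (N,) nonnegative, relative units
    residual: np.ndarray            # (N,) reconstruction residual norms
    partial_volume_flag: np.ndarray  # (N,) True where no compartment dominates
    mixing: np.ndarray              # (N, J) raw simplex weights from the fit

    def __post_init__(self) -> None:
        for name in ("ktrans_local", "vp_local", "residual", "mixing"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.partial_volume_flag = np.asarray(self.partial_volume_flag, dtype=bool)
        if self.ktrans_local.min(initial=0.0) < -1e-12 or self.vp_local.min(initial=0.0) < -1e-12:
            raise ValueError("transfer-constant maps must be nonnegative")
        if self.residual.min(initial=0.0) < 0:
            raise ValueError("residuals must be nonnegative")

    @property
    def n_pixels(self) -> int:
        return self.vp_local.size


@dataclass
class FluxRateFit:
    """Result of fitting one tissue vertex curve to the convolution model."""

    ktrans: float
    kep: float
    residual: float
    reliable: bool = True


def identify_plasma_vertex(curves: np.ndarray) -> int:
    """Index of the vertex with the fastest tracer enhancement.

    The plasma input reaches its peak most rapidly; ties on peak frame are
    broken by the steeper mean upslope from the first frame to the peak.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[1] < 2:
        raise ValueError("need a (T, J) matrix with J >= 2")
    spans = curves.max(axis=0) - curves.min(axis=0)
    if np.all(spans <= 1e-15):
        raise ValueError("all curves are flat; plasma vertex is ambiguous")
    peaks = np.argmax(curves, axis=0)
    candidates = np.flatnonzero(peaks == peaks.min())
    if candidates.size == 1:
        return int(candidates[0])
    # tie-break: steepest mean slope from first frame to the peak
    slopes = np.array(
        [
            (curves[peaks[j], j] - curves[0, j]) / max(peaks[j], 1)
            for j in candidates
        ]
    )
    return int(candidates[int(np.argmax(slopes))])


def toeplitz_input_matrix(cp: PlasmaInput) -> np.ndarray:
    """Lower-triangular Toeplitz discretization of convolution with C_p.

    ``matrix @ h`` equals the left-rectangle discrete convolution
    dt * sum_{j<=n} C_p(t_j) h(t_n - t_j), so multiplying by a sampled
    impulse response reproduces the forward compartment solution.
    """
    dt = cp.frame_interval
    first_col = cp.concentration * dt
    first_row = np.zeros(cp.n_frames)
    first_row[0] = first_col[0]
    return toeplitz(first_col, first_row)


def fit_flux_rate(
    vertex_curve: np.ndarray,
    cp: PlasmaInput,
    kep_bounds: tuple[float, float] = (1e-3, 20.0),
    n_grid: int = 200,
) -> FluxRateFit:
    """Fit (Ktrans, kep) of one tissue vertex curve by Toeplitz deconvolution.

    Minimizes || x - Toeplitz(C_p) @ (Ktrans * exp(-kep t)) ||_2 over
    Ktrans >= 0, kep >= 0 using a log-spaced 1-D grid over kep with the
    closed-form nonnegative amplitude at each candidate, refined by a
    bounded scalar search on the bracketing interval. Because the inputs
    are sum-normalized, the returned Ktrans is a relative amplitude; kep is
    in /min.
    """
    x = np.asarray(vertex_curve, dtype=float).ravel()
    if x.size != cp.n_frames:
        raise ValueError("vertex curve and plasma input lengths differ")
    l_mat = toeplitz_input_matrix(cp)
    t_rel = cp.times - cp.times[0]

    kgrid = np.geomspace(kep_bounds[0], kep_bounds[1], n_grid)
    h = np.exp(-np.outer(t_rel, kgrid))       # (T, n_grid)
    y = l_mat @ h
    num = y.T @ x
    den = np.einsum("tj,tj->j", y, y)
    amp = np.clip(num / np.maximum(den, 1e-300), 0.0, None)
    sse = np.sum(x**2) - 2 * amp * num + amp**2 * den

    best = int(np.argmin(sse))

    def objective(kep: float) -> float:
        yk = l_mat @ np.exp(-kep * t_rel)
        a = max(0.0, float(yk @ x) / max(float(yk @ yk), 1e-300))
        return float(np.sum((x - a * yk) ** 2))

    lo = kgrid[max(best - 1, 0)]
    hi = kgrid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
    )
    kep = float(res.x)
    yk = l_mat @ np.exp(-kep * t_rel)
    ktrans = max(0.0, float(yk @ x) / max(float(yk @ yk), 1e-300))
    residual = float(np.linalg.norm(x - ktrans * yk))

    # non-identifiability guard: a vertex proportional to C_p itself carries
    # no washout information
    cpn = cp.concentration / max(np.linalg.norm(cp.concentration), 1e-300)
    xn = x / max(np.linalg.norm(x), 1e-300)
    reliable = float(cpn @ xn) < 0.999
    if not reliable:
        warnings.warn(
            "vertex curve is nearly proportional to the plasma input; "
            "kep estimate is unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return FluxRateFit(ktrans=ktrans, kep=kep, residual=residual, reliable=reliable)


def fit_local_transfer_maps(
    series: DynamicSeries,
    basis: CompartmentBasis,
    purity_threshold: float = 0.8,
    max_condition: float = 1e8,
) -> TransferMaps:
    """Per-pixel nonnegative least-squares unmixing against the basis.

    Solves min_{w >= 0} || x_i - A w || for every pixel; tissue columns of w
    are the local volume transfer constants K_{i,j} and the plasma column is
    the local plasma volume v_{p,i} (relative units). When the series
    carries its pre-normalization column sums, the weights are rescaled by
    them so maps are proportional to the underlying concentration-scale
    constants.
    """
    if not series.normalized:
        raise ValueError("fit the maps on a sum-normalized series")
    a = basis.curves
    cond = np.linalg.cond(a)
    if cond > max_condition:
        raise ValueError(
            f"compartment basis is ill-conditioned (cond={cond:.3g}); "
            "reduce the number of compartments"
        )
    n = series.n_pixels
    j = basis.n_compartments
    weights = np.empty((n, j))
    residual = np.empty(n)
    for i in range(n):
        weights[i], residual[i] = nnls(a, series.values[:, i])

    totals = weights.sum(axis=1)
    purity = np.zeros(n)
    nz = totals > 0
    purity[nz] = weights[nz].max(axis=1) / totals[nz]
    partial = np.ones(n, dtype=bool)
    partial[nz] = purity[nz] < purity_threshold

    scaled = weights.copy()
    if series.column_scale is not None:
        scaled *= series.column_scale[:, None]
    return TransferMaps(
        ktrans_local=scaled[:, basis.tissue_indices],
        vp_local=scaled[:, basis.plasma_index],
        residual=residual,
        partial_volume_flag=partial,
        mixing=weights,
    )


def partial_volume_fraction(maps: TransferMaps, purity_threshold: float = 0.8) -> float:
    """Fraction of pixels where no single compartment dominates.

    A pixel is pure when its largest weight is at least
    ``purity_threshold`` times the sum of its weights; zero-weight pixels
    are excluded from the denominator.
    """
    totals = maps.mixing.sum(axis=1)
    nz = totals > 0
    if not nz.all():
        warnings.warn(
            f"excluding {int((~nz).sum())} zero-weight pixel(s) from the "
            "partial-volume fraction",
            RuntimeWarning,
            stacklevel=2,
        )
    if not nz.any():
        raise ValueError("no pixels with nonzero weights")
    purity = maps.mixing[nz].max(axis=1) / totals[nz]
    pure = purity >= purity_threshold
    return float(1.0 - pure.mean())


@dataclass
class StudyFit:
    """Per-study summary used in longitudinal comparisons."""

    label: str
    ktrans: np.ndarray              # relative Ktrans per tissue compartment
    kep: np.ndarray                 # /min per tissue compartment
    partial_volume: float | None = None

    def __post_init__(self) -> None:
        self.ktrans = np.atleast_1d(np.asarray(self.ktrans, dtype=float))
        self.kep = np.atleast_1d(np.asarray(self.kep, dtype=float))
        if self.ktrans.shape != self.kep.shape:
            raise ValueError("ktrans and kep must have equal length")


@dataclass
class LongitudinalComparison:
    """Compartment-matched parameter changes across timepoints.

    Compartments are matched across consecutive timepoints by descending
    kep (fast pool to fast pool, slow pool to slow pool), which makes the
    labels invariant to column permutations of either study's basis.
    Unmatched slots (differing J) are reported as NaN deltas.
    """

    timepoint_labels: list[str]
    kep: np.ndarray                 # (n_timepoints, max_pools), NaN-padded
    ktrans: np.ndarray              # same layout, relative units
    kep_delta: np.ndarray           # (n_timepoints-1, max_pools)
    kep_delta_pct: np.ndarray
    ktrans_delta: np.ndarray
    partial_volume: np.ndarray      # (n_timepoints,), NaN when unknown

    def to_frame(self):
        import pandas as pd

        rows = []
        for t, label in enumerate(self.timepoint_labels):
            for p in range(self.kep.shape[1]):
                if np.isnan(self.kep[t, p]):
                    continue
                rows.append(
                    {
                        "timepoint": label,
                        "pool": p,
                        "kep_per_min": self.kep[t, p],
                        "ktrans_rel": self.ktrans[t, p],
                        "kep_delta": self.kep_delta[t - 1, p] if t > 0 else np.nan,
                        "kep_delta_pct": self.kep_delta_pct[t - 1, p] if t > 0 else np.nan,
                        "ktrans_delta": self.ktrans_delta[t - 1, p] if t > 0 else np.nan,
                        "partial_volume_fraction": self.partial_volume[t],
                    }
                )
        return pd.DataFrame(rows)


def longitudinal_compare(results: list[StudyFit]) -> LongitudinalComparison:
    """Match compartments across timepoints and report parameter deltas.

    Pools are ordered by descending kep within each study; pool 0 is the
    fastest. Studies with differing numbers of tissue compartments are
    compared on the shared pools and padded with NaN elsewhere.
    """
    if len(results) < 2:
        raise ValueError("need at least two fitted studies to compare")
    max_pools = max(r.kep.size for r in results)
    n = len(results)
    kep = np.full((n, max_pools), np.nan)
    ktr = np.full((n, max_pools), np.nan)
    pv = np.full(n, np.nan)
    for t, r in enumerate(results):
        order = np.argsort(-r.kep)
        kep[t, : r.kep.size] = r.kep[order]
        ktr[t, : r.kep.size] = r.ktrans[order]
        if r.partial_volume is not None:
            pv[t] = r.partial_volume
    kep_delta = np.diff(kep, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kep_delta_pct = 100.0 * kep_delta / kep[:-1]
    ktrans_delta = np.diff(ktr, axis=0)
    return LongitudinalComparison(
        timepoint_labels=[r.label for r in results],
        kep=kep,
        ktrans=ktr,
        kep_delta=kep_delta,
        kep_delta_pct=kep_delta_pct,
        ktrans_delta=ktrans_delta,
        partial_volume=pv,
    )
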