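"""Forward two-compartment pharmacokinetic model.

Each tissue type j exchanges tracer with plasma through a first-order
compartment model: dC_j/dt = Ktrans_j * C_p(t) - kep_j * C_j(t), whose
solution is the causal convolution C_j = Ktrans_j * (C_p (*) exp(-kep_j t)).
A measured pixel time-course is a nonnegative mixture of the tissue curves
plus a plasma volume term:

    x_i(t) = sum_j K_{i,j} * (C_p (*) exp(-kep_j t)) + v_{p,i} * C_p(t)

where K_{i,j} are local volume transfer constants and v_{p,i} the local
plasma volume fraction. This module provides the impulse response, the
discrete convolution solver, a population arterial-input-function model, and
the pixel-mixing operator used by the synthetic study generator.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import PlasmaInput

__all__ = [
    "PKParameters",
    "AIFParams",
    "tissue_impulse_response",
    "solve_compartment",
    "population_aif",
    "mix_pixels",
]


@dataclass
class PKParameters:
    """Per-compartment pharmacokinetic parameters.

    ``ktrans`` and ``kep`` have one entry per tissue compartment (J-1 of
    them; the J-th compartment is the plasma input). Units are /min. ``vp``
    is the dimensionless plasma volume fraction.
    """

    ktrans: np.ndarray
    kep: np.ndarray
    vp: float = 0.0

    def __post_init__(self) -> None:
        self.ktrans = np.atleast_1d(np.asarray(self.ktrans, dtype=float))
        self.kep = np.atleast_1d(np.asarray(self.kep, dtype=float))
        if self.ktrans.shape != self.kep.shape:
            raise ValueError("ktrans and kep must have equal length")
        if np.any(self.ktrans < 0) or np.any(self.kep < 0):
            raise ValueError("rate constants must be nonnegative")
        if not 0.0 <= self.vp <= 1.0:
            raise ValueError("vp must lie in [0, 1]")

    @property
    def n_tissues(self) -> int:
        return self.ktrans.size


@dataclass
class AIFParams:
    """Parameters of the population plasma-input (AIF) model.

    The curve is a biexponential washout gated by a smooth bolus onset:

        C_p(t) = r(t - t0) * [a1 exp(-m1 (t-t0)) + a2 exp(-m2 (t-t0))]

    for t >= t0 (zero before bolus arrival ``t0``), with onset ramp
    r(u) = 1 - exp(-u / tau) when ``tau`` > 0 and r = 1 otherwise.
    Default washout amplitudes/decays follow the classic two-exponential
    population plasma-clearance model for Gd-DTPA.
    """

    a1: float = 3.99
    m1: float = 0.144
    a2: float = 4.78
    m2: float = 0.0111
    onset: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a1", "m1", "a2", "m2", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"AIF parameter {name} must be nonnegative")
        if self.onset < 0:
            raise ValueError("bolus arrival time must be nonnegative")


def tissue_impulse_response(kep: float, times: np.ndarray) -> np.ndarray:
    """Tissue impulse response exp(-kep * t) evaluated at ``times``.

    ``kep`` is the flux (washout) rate constant in /min; ``times`` are
    nonnegative, increasing minutes.
    """
    if kep < 0:
        raise ValueError("kep must be nonnegative")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size and t.min() < 0:
        raise ValueError("times must be nonnegative")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return np.exp(-kep * t)


def solve_compartment(cp: PlasmaInput, ktrans: float, kep: float) -> np.ndarray:
    """Tissue curve Ktrans * (C_p (*) exp(-kep t)) by discrete convolution.

    Uses left-rectangle quadrature on a uniform frame grid, which is causal
    and exact for impulse inputs:

        C(t_n) = Ktrans * dt * sum_{j<=n} C_p(t_j) exp(-kep (t_n - t_j)).
    """
    if ktrans < 0 or kep < 0:
        raise ValueError("ktrans and kep must be nonnegative")
    if cp.n_frames < 2:
        raise ValueError("plasma input needs at least two frames")
    dt = cp.frame_interval
    t_rel = cp.times - cp.times[0]
    h = np.exp(-kep * t_rel)
    curve = ktrans * dt * np.convolve(cp.concentration, h)[: cp.n_frames]
    # guard against -0.0 / roundoff
    return np.maximum(curve, 0.0)


def population_aif(times: np.ndarray, params: AIFParams | None = None) -> PlasmaInput:
    """Evaluate the population plasma-input model at ``times`` (minutes)."""
    if params is None:
        params = AIFParams()
    t = np.atleast_1d(np.asarray(times, dtype=float))
    u = t - params.onset
    active = u > 0
    conc = np.zeros_like(t)
    ua = u[active]
    washout = params.a1 * np.exp(-params.m1 * ua) + params.a2 * np.exp(-params.m2 * ua)
    if params.tau > 0:
        washout = washout * (1.0 - np.exp(-ua / params.tau))
    conc[active] = washout
    # include the arrival instant itself when there is no onset ramp
    if params.tau == 0:
        at_onset = u == 0
        conc[at_onset] = params.a1 + params.a2
    return PlasmaInput(times=t, concentration=conc)


def mix_pixels(curves: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Mix compartment curves into pixel time-courses: values = curves @ weights.T.

    ``curves`` is ``(T, J)`` with one column per compartment; ``weights`` is
    ``(N, J)`` with the nonnegative local transfer constants (and plasma
    volume) of each pixel. Returns the ``(T, N)`` series matrix.
    """
    curves = np.asarray(curves, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if curves.ndim != 2 or weights.ndim != 2:
        raise ValueError("curves and weights must be 2-D")
    if curves.shape[1] != weights.shape[1]:
        raise ValueError(
            f"curves have {curves.shape[1]} compartments but weights have "
            f"{weights.shape[1]} columns"
        )
    if weights.size and weights.min() < 0:
        raise ValueError("mixing weights must be nonnegative")
    return curves @ weights.T
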