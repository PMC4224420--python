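"""Containers for dynamic imaging series and plasma input curves.

A dynamic contrast-enhanced (DCE) acquisition is represented as a
time-by-pixel matrix: each row is one frame of the dynamic sequence, each
column the tracer-concentration time-course of one pixel. Spatial layout is
carried separately (``shape`` and ``mask``) so that the numerical pipeline
can operate on the flat pixel axis.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["DynamicSeries", "PlasmaInput"]

_SUM_TOL = 1e-9


@dataclass
class DynamicSeries:
    """A time-by-pixel tracer-concentration matrix with acquisition times.

    Parameters
    ----------
    times
        Acquisition timestamps in minutes, strictly increasing, length ``T``.
    values
        ``(T, N)`` nonnegative concentration matrix; row = frame,
        column = pixel.
    shape
        Optional 2-D/3-D pixel-grid dimensions. ``prod(shape) >= N``.
    mask
        Optional boolean grid selecting the ``N`` retained pixels; when
        present its ``True`` count must equal ``N``.
    normalized
        True once each column has been divided by its temporal sum.
    column_scale
        Pre-normalization temporal sums of the columns, kept so per-pixel
        parameter maps can be restored to the raw concentration scale.
    """

    times: np.ndarray
    values: np.ndarray
    shape: tuple[int, ...] | None = None
    mask: np.ndarray | None = None
    normalized: bool = False
    column_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (frames x pixels) matrix")
        if self.times.ndim != 1 or self.times.size != self.values.shape[0]:
            raise ValueError(
                f"times (length {self.times.size}) must match the number of "
                f"frames ({self.values.shape[0]})"
            )
        if not np.all(np.isfinite(self.times)):
            raise ValueError("timestamps must be finite")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentrations must be finite")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("concentrations must be nonnegative")
        if self.shape is not None:
            self.shape = tuple(int(s) for s in self.shape)
            if int(np.prod(self.shape)) < self.n_pixels:
                raise ValueError("prod(shape) must be >= number of pixels")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.shape is not None and self.mask.shape != self.shape:
                raise ValueError("mask shape must match series shape")
            if int(self.mask.sum()) != self.n_pixels:
                raise ValueError(
                    f"mask selects {int(self.mask.sum())} pixels but the "
                    f"series has {self.n_pixels}"
                )
        if self.column_scale is not None:
            self.column_scale = np.asarray(self.column_scale, dtype=float)
            if self.column_scale.shape != (self.n_pixels,):
                raise ValueError("column_scale must have one entry per pixel")
        if self.normalized:
            sums = self.values.sum(axis=0)
            if self.n_pixels and np.max(np.abs(sums - 1.0)) > _SUM_TOL:
                raise ValueError("normalized series columns must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    @property
    def frame_interval(self) -> float:
        """Uniform frame spacing in minutes; raises if spacing is not uniform."""
        dt = np.diff(self.times)
        if dt.size == 0:
            raise ValueError("need at least two frames for a frame interval")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame spacing is not uniform")
        return float(dt[0])

    def copy_with(self, **kwargs) -> "DynamicSeries":
        return replace(self, **kwargs)


@dataclass
class PlasmaInput:
    """The plasma tracer-concentration curve C_p(t) driving the tissue model."""

    times: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.concentration = np.atleast_1d(
            np.asarray(self.concentration, dtype=float)
        )
        if self.times.shape != self.concentration.shape:
            raise ValueError("times and concentration must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("plasma concentrations must be finite")
        if self.concentration.size and self.concentration.min() < 0:
            raise ValueError("plasma concentrations must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        dt = np.diff(self.times)
        if dt.size == 0:
            raise ValueError("need at least two frames for a frame interval")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frame spacing is not uniform")
        return float(dt[0])
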