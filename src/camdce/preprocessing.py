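"""Preprocessing of dynamic series before deconvolution.

The pipeline order is fixed: (1) mask out non-tumor pixels, (2) drop the
initial pre-uptake frames, (3) eliminate uninformative pixels whose
temporal mean or temporal variation falls below 5% of the respective
maximum across pixels, (4) sum-normalize every pixel time-course so the
analysis sees the shape of the kinetics rather than absolute concentration.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .series import DynamicSeries

__all__ = [
    "PreprocessReport",
    "apply_mask",
    "drop_initial_frames",
    "filter_uninformative_pixels",
    "normalize_sum",
    "preprocess",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run.

    ``retained_index`` maps each retained column to its original pixel
    position (raveled grid index when the series came from a grid,
    otherwise the original column number). Pixels failing both the mean and
    the variation rule are counted once, under the mean rule.
    """

    n_frames_removed: int = 0
    n_pixels_in: int = 0
    n_pixels_removed_low_mean: int = 0
    n_pixels_removed_low_variation: int = 0
    n_pixels_out: int = 0
    retained_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.retained_index = np.asarray(self.retained_index, dtype=int)
        removed = self.n_pixels_removed_low_mean + self.n_pixels_removed_low_variation
        if self.n_pixels_out != self.n_pixels_in - removed:
            raise ValueError("pixel counts are inconsistent")
        if np.unique(self.retained_index).size != self.retained_index.size:
            raise ValueError("retained_index must be injective")

    def to_dict(self) -> dict:
        return {
            "n_frames_removed": self.n_frames_removed,
            "n_pixels_in": self.n_pixels_in,
            "n_pixels_removed_low_mean": self.n_pixels_removed_low_mean,
            "n_pixels_removed_low_variation": self.n_pixels_removed_low_variation,
            "n_pixels_out": self.n_pixels_out,
            "retained_index": self.retained_index.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_mask(series: DynamicSeries, mask: np.ndarray) -> DynamicSeries:
    """Retain only the pixels selected by a boolean grid mask.

    The series must cover the full grid (one column per grid cell, in raveled
    order); the returned series carries the mask and keeps frame order.
    """
    mask = np.asarray(mask, dtype=bool)
    if series.shape is not None and mask.shape != series.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match series shape {series.shape}"
        )
    flat = mask.ravel()
    if flat.size != series.n_pixels:
        raise ValueError(
            f"mask selects from {flat.size} grid cells but the series has "
            f"{series.n_pixels} pixel columns"
        )
    if not flat.any():
        raise ValueError("mask selects zero pixels")
    return series.copy_with(
        values=series.values[:, flat],
        shape=mask.shape,
        mask=mask,
        column_scale=None,
    )


def drop_initial_frames(series: DynamicSeries, k: int = 4) -> DynamicSeries:
    """Remove the first ``k`` pre-uptake frames (timestamps included)."""
    if not 0 <= k < series.n_frames:
        raise ValueError(
            f"cannot drop {k} frames from a series with {series.n_frames}"
        )
    if k == 0:
        return series
    return series.copy_with(
        times=series.times[k:], values=series.values[k:], column_scale=None
    )


def filter_uninformative_pixels(
    series: DynamicSeries, mean_frac: float = 0.05, var_frac: float = 0.05
) -> tuple[DynamicSeries, PreprocessReport]:
    """Drop pixels with low temporal mean or low temporal variation.

    A pixel is removed when its temporal mean is below ``mean_frac`` times
    the maximum temporal mean over pixels, or when its temporal standard
    deviation (the "dynamic variation") is below ``var_frac`` times the
    maximum temporal standard deviation.
    """
    if series.n_pixels == 0:
        raise ValueError("series has no pixels")
    means = series.values.mean(axis=0)
    stds = series.values.std(axis=0)
    if means.max() <= 0 or stds.max() <= 0:
        raise ValueError(
            "all pixels are uninformative (no signal or no temporal variation)"
        )
    low_mean = means < mean_frac * means.max()
    low_var = stds < var_frac * stds.max()
    keep = ~(low_mean | low_var)
    if not keep.any():
        raise ValueError("all pixels were removed; thresholds too aggressive")

    if series.mask is not None:
        original = np.flatnonzero(series.mask.ravel())
    else:
        original = np.arange(series.n_pixels)
    report = PreprocessReport(
        n_frames_removed=0,
        n_pixels_in=series.n_pixels,
        n_pixels_removed_low_mean=int(low_mean.sum()),
        n_pixels_removed_low_variation=int((low_var & ~low_mean).sum()),
        n_pixels_out=int(keep.sum()),
        retained_index=original[keep],
    )
    mask = series.mask
    if mask is not None:
        mask = mask.copy().ravel()
        removed_cols = original[~keep]
        mask[removed_cols] = False
        mask = mask.reshape(series.mask.shape)
    filtered = series.copy_with(
        values=series.values[:, keep], mask=mask, column_scale=None
    )
    return filtered, report


def normalize_sum(series: DynamicSeries) -> DynamicSeries:
    """Divide each pixel time-course by its temporal sum.

    Idempotent; records the original column sums in ``column_scale`` so
    fitted per-pixel weights can be mapped back to concentration scale.
    """
    if series.normalized:
        return series
    sums = series.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums <= 0)[0])
        raise ZeroDivisionError(
            f"pixel column {bad} has nonpositive temporal sum; filter "
            "uninformative pixels before normalizing"
        )
    return series.copy_with(
        values=series.values / sums, normalized=True, column_scale=sums
    )


def preprocess(
    series: DynamicSeries,
    mask: np.ndarray | None = None,
    drop_frames: int = 4,
    mean_frac: float = 0.05,
    var_frac: float = 0.05,
) -> tuple[DynamicSeries, PreprocessReport]:
    """Full preprocessing chain: mask, frame removal, filtering, normalization."""
    out = series
    if mask is not None:
        out = apply_mask(out, mask)
    out = drop_initial_frames(out, drop_frames)
    out, report = filter_uninformative_pixels(out, mean_frac, var_frac)
    report.n_frames_removed = drop_frames
    out = normalize_sum(out)
    return out, report
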