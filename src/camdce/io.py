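"""Readers and writers for time-by-pixel series and result tables.

The on-disk convention follows the field's standard for dynamic series
matrices: each row is a time frame, each column a pixel. Supported formats
are delimited text (CSV/TSV/whitespace), MATLAB-style ``.mat`` matrices,
and NumPy ``.npy``/``.npz`` containers.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .series import DynamicSeries

__all__ = ["read_series", "write_series", "detect_format"]

_DELIMITED = {".csv": ",", ".tsv": "\t", ".txt": None}


def detect_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in _DELIMITED:
        return "delimited"
    if suffix == ".mat":
        return "matlab-matrix"
    if suffix in (".npy", ".npz"):
        return "array-container"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _load_matrix(path: Path, fmt: str) -> np.ndarray:
    if fmt == "delimited":
        delimiter = _DELIMITED.get(path.suffix.lower())
        try:
            data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"could not parse {path}: {exc}") from exc
        return data
    if fmt == "matlab-matrix":
        contents = loadmat(path)
        arrays = {
            k: v
            for k, v in contents.items()
            if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim == 2
        }
        if not arrays:
            raise ValueError(f"{path} contains no 2-D numeric matrix")
        if "series" in arrays:
            return np.asarray(arrays["series"], dtype=float)
        if len(arrays) > 1:
            raise ValueError(
                f"{path} holds several matrices ({sorted(arrays)}); store the "
                "series under the variable name 'series'"
            )
        return np.asarray(next(iter(arrays.values())), dtype=float)
    if fmt == "array-container":
        data = np.load(path)
        if isinstance(data, np.lib.npyio.NpzFile):
            key = "series" if "series" in data else data.files[0]
            data = data[key]
        return np.asarray(data, dtype=float)
    raise ValueError(f"unknown format {fmt!r}")


def read_series(
    path: str | Path,
    format: str | None = None,
    frame_interval: float = 0.5,
    times: np.ndarray | None = None,
    transpose: bool = False,
    shape: tuple[int, ...] | None = None,
) -> DynamicSeries:
    """Read a dynamic series matrix (row = frame, column = pixel).

    Timestamps come from ``times`` when given, otherwise uniform spacing at
    ``frame_interval`` minutes (default 0.5 min, i.e. one scan every 30 s).
    ``transpose=True`` reads a pixel-by-time file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or detect_format(path)
    data = _load_matrix(path, fmt)
    if transpose:
        data = data.T
    if np.isnan(data).any():
        frame, pixel = np.argwhere(np.isnan(data))[0]
        raise ValueError(f"NaN cell at frame {frame}, pixel {pixel} in {path}")
    if times is None:
        times = np.arange(data.shape[0]) * frame_interval
    return DynamicSeries(times=np.asarray(times, float), values=data, shape=shape)


def write_series(series: DynamicSeries, path: str | Path, format: str | None = None) -> None:
    """Write a series matrix; lossless round-trip with :func:`read_series`."""
    path = Path(path)
    fmt = format or detect_format(path)
    if fmt == "delimited":
        delimiter = _DELIMITED.get(path.suffix.lower()) or " "
        np.savetxt(path, series.values, delimiter=delimiter, fmt="%.17g")
    elif fmt == "matlab-matrix":
        savemat(path, {"series": series.values, "times": series.times})
    elif fmt == "array-container":
        if path.suffix.lower() == ".npz":
            np.savez(path, series=series.values, times=series.times)
        else:
            np.save(path, series.values)
    else:
        raise ValueError(f"unknown format {fmt!r}")
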