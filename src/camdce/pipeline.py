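"""End-to-end pipeline driver: preprocess -> cluster -> CAM + MDL -> estimate.

`run_pipeline` ties the stages together, writes every artifact (MDL curve,
basis curves, pharmacokinetic table, transfer maps, scatter projection,
manifest) into an output directory, and removes partial outputs when a
stage fails.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cam import convexity_projection
from .clustering import cluster_series, em_refine
from .estimation import (
    CompartmentBasis,
    StudyFit,
    fit_flux_rate,
    fit_local_transfer_maps,
    identify_plasma_vertex,
    partial_volume_fraction,
)
from .io import read_series
from .model_selection import select_num_compartments
from .preprocessing import preprocess
from .series import DynamicSeries, PlasmaInput

__all__ = ["StudyConfig", "PipelineResult", "PipelineError", "run_pipeline", "load_config"]

logger = logging.getLogger("camdce")


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class StudyConfig:
    """Configuration of one pipeline run."""

    input_path: str | None = None
    format: str | None = None
    frame_interval: float = 0.5
    transpose: bool = False
    mask_path: str | None = None
    drop_frames: int = 4
    mean_frac: float = 0.05
    var_frac: float = 0.05
    damping: float = 0.7
    preference: float | None = None
    max_iter: int = 1000
    j_min: int = 2
    j_max: int = 6
    j_fixed: int | None = None
    purity_threshold: float = 0.8
    kep_min: float = 1e-3
    kep_max: float = 20.0
    outdir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of everything one run computes."""

    config: StudyConfig
    series: DynamicSeries
    report: object
    clusters: object
    selection: object | None
    chosen_J: int
    basis: CompartmentBasis
    fits: list
    maps: object
    partial_volume: float
    outputs: list[str] = field(default_factory=list)

    def study_fit(self, label: str = "study") -> StudyFit:
        return StudyFit(
            label=label,
            ktrans=np.array([f.ktrans for f in self.fits]),
            kep=np.array([f.kep for f in self.fits]),
            partial_volume=self.partial_volume,
        )


def load_config(path: str | Path) -> StudyConfig:
    """Parse a plain ``key = value`` config file into a StudyConfig."""
    fields = {f.name: f.type for f in StudyConfig.__dataclass_fields__.values()}
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
        kwargs[key] = _coerce(value)
    return StudyConfig(**kwargs)


def _coerce(value: str):
    low = value.lower()
    if low in ("none", ""):
        return None
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def run_pipeline(
    config: StudyConfig,
    series: DynamicSeries | None = None,
    mask: np.ndarray | None = None,
) -> PipelineResult:
    """Execute the full deconvolution pipeline.

    ``series``/``mask`` may be passed in memory; otherwise they are read
    from the paths in ``config``. Deterministic given the seed; partial
    outputs are removed if any stage raises.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir) if config.outdir else None
    written: list[Path] = []
    try:
        return _run(config, series, mask, outdir, written)
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def _run(config, series, mask, outdir, written) -> PipelineResult:
    if series is None:
        if config.input_path is None:
            raise PipelineError("read", ValueError("no input series or path given"))
        series = _stage("read")(
            read_series,
            config.input_path,
            format=config.format,
            frame_interval=config.frame_interval,
            transpose=config.transpose,
        )
    if mask is None and config.mask_path:
        mask = _stage("read")(np.loadtxt, config.mask_path).astype(bool)
        series = series.copy_with(shape=mask.shape)

    processed, report = _stage("preprocess")(
        preprocess,
        series,
        mask=mask,
        drop_frames=config.drop_frames,
        mean_frac=config.mean_frac,
        var_frac=config.var_frac,
    )
    logger.info("preprocess: %d -> %d pixels, %d frames",
                report.n_pixels_in, report.n_pixels_out, processed.n_frames)

    clusters = _stage("cluster")(
        cluster_series,
        processed,
        damping=config.damping,
        preference=config.preference,
        max_iter=config.max_iter,
    )
    clusters = _stage("cluster")(em_refine, processed, clusters, seed=config.seed)
    logger.info("clustering: M=%d clusters", clusters.n_clusters)

    selection = None
    if config.j_fixed is not None:
        from .cam import enumerate_vertex_sets

        chosen_j = int(config.j_fixed)
        solution = _stage("cam")(enumerate_vertex_sets, clusters, chosen_j)
    else:
        # keep at least one exterior center: at J = M the hull-to-data
        # objective is vacuously zero and the MDL likelihood degenerates
        j_max = min(config.j_max, clusters.n_clusters - 1)
        if j_max < config.j_max:
            logger.warning("restricting j_max to M-1=%d", j_max)
        selection = _stage("select")(
            select_num_compartments, clusters, config.j_min, j_max, processed
        )
        chosen_j = selection.chosen_J
        solution = selection.solution
    logger.info("model selection: J=%d, total_margin=%.4g",
                chosen_j, solution.total_margin)

    curves = clusters.centers[solution.vertex_cluster_index].T
    plasma = _stage("estimate")(identify_plasma_vertex, curves)
    basis = CompartmentBasis(
        curves=curves,
        plasma_index=plasma,
        source_vertex=solution.vertex_cluster_index,
    )
    cp = PlasmaInput(times=processed.times, concentration=curves[:, plasma])
    fits = [
        _stage("estimate")(
            fit_flux_rate, curves[:, j], cp, kep_bounds=(config.kep_min, config.kep_max)
        )
        for j in basis.tissue_indices
    ]
    maps = _stage("estimate")(
        fit_local_transfer_maps, processed, basis, purity_threshold=config.purity_threshold
    )
    pv = _stage("estimate")(partial_volume_fraction, maps, config.purity_threshold)
    for i, fit in enumerate(fits):
        logger.info("pool %d: kep=%.4g /min, relative Ktrans=%.4g", i, fit.kep, fit.ktrans)

    result = PipelineResult(
        config=config,
        series=processed,
        report=report,
        clusters=clusters,
        selection=selection,
        chosen_J=chosen_j,
        basis=basis,
        fits=fits,
        maps=maps,
        partial_volume=pv,
    )
    if outdir is not None:
        _stage("write")(_write_bundle, result, outdir, written)
    return result


def _write_bundle(result: PipelineResult, outdir: Path, written: list[Path]) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = result.config.config_hash()

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)
        result.outputs.append(str(path))

    if result.selection is not None:
        mdl = pd.DataFrame(
            {"J": result.selection.candidates, "code_length": result.selection.code_length}
        )
        emit("mdl_curve.csv", lambda p: mdl.to_csv(p, index=False))
        emit("mdl_curve.png", lambda p: _plot_mdl(result.selection, p))
    basis_df = pd.DataFrame(
        result.basis.curves,
        columns=[
            "plasma" if j == result.basis.plasma_index else f"tissue{j}"
            for j in range(result.basis.n_compartments)
        ],
    )
    basis_df.insert(0, "time_min", result.series.times)
    emit("basis_curves.csv", lambda p: basis_df.to_csv(p, index=False))
    pk = pd.DataFrame(
        {
            "pool": np.arange(len(result.fits)),
            "kep_per_min": [f.kep for f in result.fits],
            "ktrans_rel": [f.ktrans for f in result.fits],
            "fit_residual": [f.residual for f in result.fits],
            "reliable": [f.reliable for f in result.fits],
        }
    )
    emit("pk_parameters.csv", lambda p: pk.to_csv(p, index=False))
    emit("transfer_maps.csv", lambda p: np.savetxt(
        p,
        np.column_stack([result.maps.ktrans_local, result.maps.vp_local]),
        delimiter=",",
        fmt="%.10g",
    ))
    emit("map_images.png", lambda p: _plot_maps(result, p))
    emit("scatter_simplex.png", lambda p: _plot_scatter(result, p))
    manifest = {
        "package_version": __version__,
        "config": asdict(result.config),
        "config_hash": cfg_hash,
        "seed": result.config.seed,
        "n_clusters": int(result.clusters.n_clusters),
        "chosen_J": int(result.chosen_J),
        "total_margin": float(
            result.selection.solution.total_margin
            if result.selection is not None
            else 0.0
        ),
        "partial_volume_fraction": result.partial_volume,
        "kep_per_min": [f.kep for f in result.fits],
        "ktrans_rel": [f.ktrans for f in result.fits],
    }
    emit("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))


def _agg():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_mdl(selection, path: Path) -> None:
    plt = _agg()
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(selection.candidates, selection.code_length, "o-")
    ax.axvline(selection.chosen_J, color="r", ls="--", lw=1)
    ax.set_xlabel("number of compartments J")
    ax.set_ylabel("description code length")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_scatter(result: PipelineResult, path: Path) -> None:
    plt = _agg()
    vertices = result.basis.curves
    coords = convexity_projection(result.series, vertices)
    vcoords = convexity_projection(vertices.T, vertices)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(coords[:, 0], coords[:, 1], s=4, alpha=0.4, label="pixels")
    ax.scatter(vcoords[:, 0], vcoords[:, 1], s=60, c="r", marker="^", label="vertices")
    ax.set_title("scatter simplex (convexity-preserving projection)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_maps(result: PipelineResult, path: Path) -> None:
    plt = _agg()
    maps = np.column_stack([result.maps.ktrans_local, result.maps.vp_local])
    n_maps = maps.shape[1]
    fig, axes = plt.subplots(1, n_maps, figsize=(3 * n_maps, 3))
    axes = np.atleast_1d(axes)
    series = result.series
    for j, ax in enumerate(axes):
        if series.mask is not None:
            img = np.full(series.mask.shape, np.nan)
            img[series.mask] = maps[:, j]
            ax.imshow(img, cmap="gray")
        else:
            ax.plot(maps[:, j])
        title = "v_p" if j == n_maps - 1 else f"K (pool {j})"
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
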