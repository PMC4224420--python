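"""Synthetic DCE study generator with known ground truth.

Emulates the standard validation design for simplex-based deconvolution:
known compartment time-activity curves (tissue pools driven by a shared
plasma input) are multiplied by customized local volume-transfer-constant
maps, and i.i.d. Gaussian noise is added at a chosen SNR. The default
layout mirrors the rim/core picture of an angiogenic tumor: a fast-washout
pool on the peripheral rim, a slow pool in the hypoxic core, and a
plasma-rich center, each with a designated patch of pure-volume pixels so
the finite-vertex identifiability condition holds.

Mixing weights are piecewise-constant regional prototypes multiplied by a
smooth per-pixel gain field. Scaling an entire weight row leaves the
sum-normalized time-course unchanged, so the gain field adds intensity
realism without moving points on the scatter simplex; noise-free studies
therefore contain a small set of distinct normalized profiles, which is
exactly the geometry the vertex-identification step assumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import ndimage

from .kinetics import AIFParams, PKParameters, mix_pixels, population_aif, solve_compartment
from .series import DynamicSeries, PlasmaInput

__all__ = [
    "MapSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_synthetic_study",
    "generate_replicates",
    "default_parameter_grid",
]


def _default_pk() -> PKParameters:
    # fast rim pool ~10x the washout rate of the slow core pool
    return PKParameters(ktrans=(0.25, 0.12), kep=(1.5, 0.15), vp=0.05)


def _default_aif() -> AIFParams:
    # bolus arrives at 1.75 min: the four 0.5-min pre-contrast frames hold no
    # tracer, and the first retained frame (t = 2.0 min) already carries signal
    return AIFParams(onset=1.75, tau=0.12)


@dataclass
class MapSpec:
    """Geometry of the per-compartment transfer-constant maps.

    A circular tumor of radius ``tumor_radius`` (pixels) holds a plasma-rich
    vessel zone at the center and one annulus per tissue pool (slowest pool
    innermost). Each zone is split into ``n_sectors`` angular sectors with
    slightly different mixing prototypes; each compartment additionally gets
    one square patch of pure pixels of side ``pure_patch``.
    """

    tumor_radius: float = 11.0
    vessel_radius: float = 2.5
    pure_patch: int = 2
    n_sectors: int = 3
    gain_amplitude: float = 0.2
    vessel_vp: float = 0.7

    def __post_init__(self) -> None:
        if self.tumor_radius <= self.vessel_radius:
            raise ValueError("tumor radius must exceed vessel radius")
        if self.pure_patch < 1 or self.n_sectors < 1:
            raise ValueError("pure_patch and n_sectors must be >= 1")
        if not 0 < self.vessel_vp <= 1:
            raise ValueError("vessel_vp must lie in (0, 1]")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset family."""

    J: int = 3
    pk: PKParameters = field(default_factory=_default_pk)
    aif_params: AIFParams = field(default_factory=_default_aif)
    grid: tuple[int, int] = (24, 24)
    map_spec: MapSpec = field(default_factory=MapSpec)
    n_frames: int = 19
    frame_interval: float = 0.5
    snr_db: float | None = 30.0
    n_replicates: int = 50
    seed: int = 0
    purity_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("need at least two compartments (J >= 2)")
        if self.pk.n_tissues != self.J - 1:
            raise ValueError(
                f"pk supplies {self.pk.n_tissues} tissue compartments but "
                f"J={self.J} requires {self.J - 1}"
            )
        if self.J > 2 and np.unique(self.pk.kep).size != self.pk.kep.size:
            raise ValueError("tissue kep values must be distinct for identifiability")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            self.snr_db = None  # treat +inf as noise-free
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if min(self.grid) < 2 * self.map_spec.tumor_radius * 0.8:
            raise ValueError("grid too small for the requested tumor radius")
        if not 0.5 < self.purity_threshold <= 1.0:
            raise ValueError("purity_threshold must lie in (0.5, 1]")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic study.

    ``basis`` holds the noise-free compartment curves (tissue pools in pk
    order, plasma last). Maps are defined on the full raveled grid with
    zeros outside the tumor mask. ``mixing`` are the simplex coordinates of
    each pixel's normalized time-course with respect to the normalized
    basis; ``mixed_fraction`` applies the purity rule to those coordinates.
    """

    basis: np.ndarray
    cp: PlasmaInput
    ktrans_local: np.ndarray
    vp_local: np.ndarray
    mask: np.ndarray
    pure_pixel_index: list[np.ndarray]
    mixing: np.ndarray
    mixed_fraction: float
    pk: PKParameters
    purity_threshold: float = 0.8

    @property
    def n_compartments(self) -> int:
        return self.basis.shape[1]

    @property
    def weights(self) -> np.ndarray:
        """Full-grid (G, J) weight matrix [K_{i,1..J-1}, v_{p,i}]."""
        return np.column_stack([self.ktrans_local, self.vp_local])

    def normalized_basis(self) -> np.ndarray:
        return self.basis / self.basis.sum(axis=0, keepdims=True)


def _zone_prototypes(J: int, n_sectors: int) -> dict[str, np.ndarray]:
    """Mixing-proportion prototypes (rows sum to 1) for each zone."""
    n_tissues = J - 1
    dominance = np.linspace(0.62, 0.82, n_sectors)
    vp_share = np.linspace(0.18, 0.12, n_sectors)
    protos: dict[str, np.ndarray] = {}
    for j in range(n_tissues):
        rows = []
        for s in range(n_sectors):
            row = np.empty(J)
            rest = 1.0 - dominance[s] - vp_share[s]
            row[:n_tissues] = rest / max(n_tissues - 1, 1)
            row[j] = dominance[s]
            row[-1] = vp_share[s]
            rows.append(row)
        protos[f"tissue{j}"] = np.array(rows)
    rows = []
    for s in range(n_sectors):
        row = np.empty(J)
        row[:n_tissues] = (1.0 - dominance[s]) / n_tissues
        row[-1] = dominance[s]
        rows.append(row)
    protos["vessel"] = np.array(rows)
    return protos


def _pure_patch_slices(center: np.ndarray, offset: np.ndarray, size: int,
                       grid: tuple[int, int]) -> tuple[slice, slice]:
    pos = np.round(center + offset - (size - 1) / 2).astype(int)
    pos = np.clip(pos, 0, np.array(grid) - size)
    return slice(pos[0], pos[0] + size), slice(pos[1], pos[1] + size)


def _build_maps(config: SyntheticConfig, rng: np.random.Generator):
    """Construct full-grid weight maps, tumor mask and pure-pixel indices."""
    J = config.J
    spec = config.map_spec
    rows, cols = config.grid
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    radius = np.hypot(rr - center[0], cc - center[1])
    angle = np.mod(np.arctan2(cc - center[1], rr - center[0]), 2 * np.pi)
    mask = radius <= spec.tumor_radius

    n_tissues = J - 1
    # slowest pool innermost; annulus bounds between vessel zone and rim
    order = np.argsort(config.pk.kep)  # annulus index -> tissue index
    bounds = np.linspace(spec.vessel_radius, spec.tumor_radius, n_tissues + 1)
    sector = np.floor(angle / (2 * np.pi / spec.n_sectors)).astype(int)
    sector = np.clip(sector, 0, spec.n_sectors - 1)

    protos = _zone_prototypes(J, spec.n_sectors)
    proportions = np.zeros((rows, cols, J))
    vessel = mask & (radius <= spec.vessel_radius)
    proportions[vessel] = protos["vessel"][sector[vessel]]
    for a in range(n_tissues):
        j = order[a]
        zone = mask & (radius > bounds[a]) & (radius <= bounds[a + 1])
        proportions[zone] = protos[f"tissue{j}"][sector[zone]]

    # designated pure-pixel patches: plasma at the center, each tissue pool
    # at the middle of its annulus (one angular position per pool)
    pure_index: list[np.ndarray] = [np.empty(0, int)] * J
    flat = np.arange(rows * cols).reshape(rows, cols)
    angles = 2 * np.pi * np.arange(n_tissues) / max(n_tissues, 1)
    for a in range(n_tissues):
        j = order[a]
        r_mid = 0.5 * (bounds[a] + bounds[a + 1])
        offset = r_mid * np.array([np.cos(angles[a]), np.sin(angles[a])])
        sl = _pure_patch_slices(center, offset, spec.pure_patch, config.grid)
        one_hot = np.zeros(J)
        one_hot[j] = 1.0
        proportions[sl] = one_hot
        pure_index[j] = flat[sl].ravel()
    sl = _pure_patch_slices(center, np.zeros(2), spec.pure_patch, config.grid)
    one_hot = np.zeros(J)
    one_hot[-1] = 1.0
    proportions[sl] = one_hot
    pure_index[-1] = flat[sl].ravel()
    vessel_like = vessel.copy()
    vessel_like[sl] = True

    # per-column amplitude scales: tissue columns carry Ktrans_j; the plasma
    # column carries the local plasma volume, which is near-unity in vessel
    # pixels (a vessel is mostly blood, hence the brightest enhancement)
    # and small in tissue
    vp_tissue = config.pk.vp if config.pk.vp > 0 else 0.05
    weights = proportions.copy()
    weights[..., :-1] *= config.pk.ktrans
    weights[..., -1] *= np.where(vessel_like, spec.vessel_vp, vp_tissue)
    # smooth positive gain field; scales whole rows, invisible after
    # sum normalization
    coarse = rng.standard_normal((5, 5))
    gain_field = ndimage.zoom(coarse, (rows / 5, cols / 5), order=1, mode="nearest")
    gain = np.exp(spec.gain_amplitude * gain_field)
    weights *= gain[..., None]
    weights[~mask] = 0.0
    return weights.reshape(rows * cols, J), mask, pure_index


def _mixing_coordinates(weights: np.ndarray, basis: np.ndarray,
                        mask_flat: np.ndarray) -> np.ndarray:
    """Simplex coordinates of each pixel w.r.t. the normalized basis."""
    col_sums = basis.sum(axis=0)
    mixing = weights * col_sums
    totals = mixing.sum(axis=1)
    out = np.zeros_like(mixing)
    inside = mask_flat & (totals > 0)
    out[inside] = mixing[inside] / totals[inside, None]
    return out


def generate_synthetic_study(config: SyntheticConfig) -> tuple[DynamicSeries, GroundTruth]:
    """Generate one noisy synthetic study plus its ground truth.

    Deterministic given ``config.seed``. The returned series covers the full
    pixel grid (the tumor mask travels in the ground truth and is applied by
    the preprocessing step, as for real data).
    """
    rng = np.random.default_rng(config.seed)
    times = config.times
    cp = population_aif(times, config.aif_params)
    tissue_curves = [
        solve_compartment(cp, 1.0, kep) for kep in config.pk.kep
    ]
    basis = np.column_stack(tissue_curves + [cp.concentration])

    weights, mask, pure_index = _build_maps(config, rng)
    clean = mix_pixels(basis, weights)

    if config.snr_db is None:
        noisy = clean
    else:
        mask_flat = mask.ravel()
        power = float(np.mean(clean[:, mask_flat] ** 2))
        sigma = np.sqrt(power / 10 ** (config.snr_db / 10.0))
        noisy = np.clip(clean + sigma * rng.standard_normal(clean.shape), 0.0, None)

    series = DynamicSeries(times=times, values=noisy, shape=config.grid)
    mixing = _mixing_coordinates(weights, basis, mask.ravel())
    purity = np.zeros(mixing.shape[0])
    inside = mixing.sum(axis=1) > 0
    purity[inside] = mixing[inside].max(axis=1) / mixing[inside].sum(axis=1)
    mixed_fraction = float(np.mean(purity[inside] < config.purity_threshold))
    truth = GroundTruth(
        basis=basis,
        cp=cp,
        ktrans_local=weights[:, :-1],
        vp_local=weights[:, -1],
        mask=mask,
        pure_pixel_index=pure_index,
        mixing=mixing,
        mixed_fraction=mixed_fraction,
        pk=config.pk,
        purity_threshold=config.purity_threshold,
    )
    return series, truth


def generate_replicates(
    config: SyntheticConfig, n: int | None = None
) -> Iterator[tuple[DynamicSeries, GroundTruth]]:
    """Yield ``n`` (default ``config.n_replicates``) independent replicates.

    Replicate seeds are spawned from ``config.seed`` so the whole family is
    reproducible from a single integer.
    """
    n = config.n_replicates if n is None else int(n)
    seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
    for s in seeds:
        yield generate_synthetic_study(replace(config, seed=int(s)))


def default_parameter_grid(base: SyntheticConfig | None = None) -> list[SyntheticConfig]:
    """Twelve default study conditions.

    Varies the kep contrast between the fast and slow pools (10x vs 4x),
    the pure-pixel patch size (2 vs 3 pixels on a side) and the SNR
    (20/30/40 dB).
    """
    base = base or SyntheticConfig()
    configs = []
    for kep in ((1.5, 0.15), (0.6, 0.15)):
        for patch in (2, 3):
            for snr in (20.0, 30.0, 40.0):
                pk = PKParameters(ktrans=base.pk.ktrans.copy(), kep=kep, vp=base.pk.vp)
                spec = replace(base.map_spec, pure_patch=patch)
                configs.append(replace(base, pk=pk, map_spec=spec, snr_db=snr))
    return configs
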