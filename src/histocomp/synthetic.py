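"""Synthetic inputs with planted ground truth.

Every input the analysis consumes can be generated here so that each
pipeline stage is testable against known truth:

* 3D image stacks emulating lightsheet acquisitions of a cleavage-stage
  embryo's animal cap — a hemispherical cell mass of cytoplasmic intensity
  containing bright ellipsoidal nuclei at a planted nuclear/cytoplasmic
  intensity ratio R, over dark background, with Gaussian and optional
  Poisson noise;
* time-lapse frame sequences with per-nucleus motion and optional synchronous
  division;
* per-stage histone-abundance tables emulating quantitative-MS output
  (molecules per embryo per core histone);
* qPCR Ct tables with a constant maternal normalizer and zygotic targets
  that switch on at a planted activation stage.

Axis order is ZYX with 0-based indexing; a voxel's physical position is
``index × voxel_size`` (voxel-centre convention). No optical realism (PSF,
stripe artifacts) is attempted: intensities are piecewise-constant before
noise, which is what makes exact round-trip oracles possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .expression import DEFAULT_CT_FLOOR, DEFAULT_NORMALIZER
from .genome import GenomeModel
from .stoichiometry import CORE_HISTONES, histones_per_genome
from .tables import HistoneAbundanceTable, stage_sort_key


class PlacementError(RuntimeError):
    """Raised when the requested nuclei cannot be placed in the cap."""


@dataclass(frozen=True)
class SyntheticStackSpec:
    """Parameters of one synthetic animal-cap stack.

    ``grid_shape`` and ``voxel_size`` are (z, y, x); the default anisotropic
    voxel (1.0, 0.5, 0.5) µm mimics 1 µm optical sectioning at finer lateral
    sampling. ``nucleus_radius`` is (mean, sd) in µm; nuclei are spheres in
    physical space (ellipsoids in voxel space under anisotropy).
    """

    grid_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: tuple[float, float, float] = (1.0, 0.5, 0.5)
    cap_radius: float = 28.0
    n_nuclei: int = 12
    nucleus_radius: tuple[float, float] = (4.0, 0.3)
    nc_ratio: float = 4.0
    cytoplasm_intensity: float = 100.0
    background_intensity: float = 10.0
    intensity_offset: float = 0.0
    noise_sigma: float = 0.0
    poisson: bool = False
    seed: int = 0
    allow_overlap: bool = False
    placement_margin: float = 2.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nc_ratio <= 0:
            raise ValueError("nc_ratio must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.cap_radius <= 0:
            raise ValueError("cap_radius must be positive")
        cap_vol = 2.0 / 3.0 * np.pi * self.cap_radius**3
        mean_r = self.nucleus_radius[0]
        if self.n_nuclei * 4.0 / 3.0 * np.pi * mean_r**3 > cap_vol:
            raise ValueError("summed nucleus volume exceeds cap volume")


@dataclass
class PlantedNucleus:
    """Ground truth for one nucleus: physical centre, radius, and the exact
    rasterized volume."""

    label: int
    center: tuple[float, float, float]
    radius: float
    volume: float = 0.0


@dataclass
class GroundTruth:
    """Exact planted quantities of a synthetic stack, recorded before noise."""

    label_volume: np.ndarray
    cap_mask: np.ndarray
    nuclei: list[PlantedNucleus]
    planted_v: float
    planted_r: float
    planted_cap_volume: float
    voxel_size: tuple[float, float, float]

    @property
    def centroids(self) -> dict[int, tuple[float, float, float]]:
        return {n.label: n.center for n in self.nuclei}


def _physical_grids(shape, voxel_size):
    axes = [np.arange(n) * s for n, s in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _cap_center(spec: SyntheticStackSpec) -> np.ndarray:
    nz, ny, nx = spec.grid_shape
    vz, vy, vx = spec.voxel_size
    # flat face of the hemisphere one plane above the stack bottom
    return np.array([1.0 * vz, (ny - 1) * vy / 2.0, (nx - 1) * vx / 2.0])


def _rasterize_sphere(label_volume, center, radius, label, voxel_size):
    """Set ``label`` on voxels within ``radius`` of ``center``; returns count."""
    shape = label_volume.shape
    lo = [max(0, int(np.floor((c - radius) / s))) for c, s in zip(center, voxel_size)]
    hi = [
        min(n, int(np.ceil((c + radius) / s)) + 1)
        for c, s, n in zip(center, voxel_size, shape)
    ]
    sub = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = [
        (np.arange(a, b) * s - c)
        for (a, b), s, c in zip(zip(lo, hi), voxel_size, center)
    ]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij", sparse=True)
    inside = zz**2 + yy**2 + xx**2 <= radius**2
    label_volume[sub][inside] = label
    return int(inside.sum())


def _place_nuclei(spec: SyntheticStackSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centres inside the cap."""
    center = _cap_center(spec)
    placed: list[PlantedNucleus] = []
    mean_r, sd_r = spec.nucleus_radius
    for i in range(spec.n_nuclei):
        radius = max(0.5 * mean_r, rng.normal(mean_r, sd_r)) if sd_r > 0 else mean_r
        for _ in range(20000):
            u = rng.uniform(-1.0, 1.0, size=3)
            p = center + u * spec.cap_radius
            if np.linalg.norm(p - center) > spec.cap_radius - radius:
                continue
            if p[0] - center[0] < radius:  # stay above the flat face
                continue
            if not spec.allow_overlap and any(
                np.linalg.norm(p - np.array(q.center))
                < radius + q.radius + spec.placement_margin
                for q in placed
            ):
                continue
            placed.append(PlantedNucleus(label=i + 1, center=tuple(p), radius=radius))
            break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} "
                f"(cap radius {spec.cap_radius} µm, nucleus radius {radius:.1f} µm)"
            )
    return placed


def _render(spec: SyntheticStackSpec, nuclei: list[PlantedNucleus], rng):
    """Rasterize cap + nuclei, apply noise; returns (stack, GroundTruth)."""
    shape = spec.grid_shape
    voxel_vol = float(np.prod(spec.voxel_size))
    center = _cap_center(spec)

    zz, yy, xx = _physical_grids(shape, spec.voxel_size)
    dist2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    cap_mask = (dist2 <= spec.cap_radius**2) & (zz >= center[0])

    label_volume = np.zeros(shape, dtype=np.int32)
    for nuc in nuclei:
        count = _rasterize_sphere(
            label_volume, np.array(nuc.center), nuc.radius, nuc.label, spec.voxel_size
        )
        nuc.volume = count * voxel_vol
    # volumes from the final label image so later-placed labels win overlaps
    if nuclei:
        labels, counts = np.unique(label_volume[label_volume > 0], return_counts=True)
        by_label = dict(zip(labels.tolist(), counts.tolist()))
        for nuc in nuclei:
            nuc.volume = by_label.get(nuc.label, 0) * voxel_vol

    stack = np.full(shape, spec.background_intensity, dtype=np.float64)
    stack[cap_mask] = spec.cytoplasm_intensity
    stack[label_volume > 0] = spec.nc_ratio * spec.cytoplasm_intensity
    # uniform staining/camera offset: the "background" that ratio correction
    # must subtract (measured from secondary-only controls in real data)
    stack += spec.intensity_offset

    cap_volume = float(cap_mask.sum()) * voxel_vol
    total_nuc = sum(n.volume for n in nuclei)
    truth = GroundTruth(
        label_volume=label_volume,
        cap_mask=cap_mask,
        nuclei=nuclei,
        planted_v=total_nuc / cap_volume if cap_volume else 0.0,
        planted_r=spec.nc_ratio,
        planted_cap_volume=cap_volume,
        voxel_size=spec.voxel_size,
    )

    if spec.noise_sigma > 0:
        stack = stack + rng.normal(0.0, spec.noise_sigma, size=shape)
    if spec.poisson:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    np.clip(stack, 0, None, out=stack)
    return stack, truth


def generate_embryo_stack(spec: SyntheticStackSpec):
    """Generate one stack and its ground truth.

    Cap voxels carry ``cytoplasm_intensity``, nucleus voxels
    ``nc_ratio × cytoplasm_intensity``, outside-cap voxels
    ``background_intensity``; noise is applied last. Ground-truth volumes are
    the exact rasterized voxel counts × voxel volume.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _place_nuclei(spec, rng)
    return _render(spec, nuclei, rng)


def generate_timelapse(
    spec: SyntheticStackSpec,
    n_frames: int,
    displacement: float,
    division_frame: int | None = None,
):
    """Generate a frame sequence with per-nucleus random-walk motion.

    Each nucleus moves by ``displacement`` µm per frame in a random direction
    (reflected back if the move would leave the cap). At ``division_frame``
    every nucleus is replaced by two daughters of half the volume. Returns
    ``(stacks, truths, parent_maps)`` where ``parent_maps[f]`` maps each
    label in frame f to its label (or parent label) in frame f−1.
    """
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    center = _cap_center(spec)
    current = _place_nuclei(spec, rng)
    next_label = len(current) + 1

    stacks, truths, parent_maps = [], [], []
    for frame in range(n_frames):
        parent_map: dict[int, int] = {}
        if frame > 0:
            moved = []
            for nuc in current:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                p = np.array(nuc.center) + displacement * direction
                if (
                    np.linalg.norm(p - center) > spec.cap_radius - nuc.radius
                    or p[0] - center[0] < nuc.radius
                ):
                    p = np.array(nuc.center) - displacement * direction
                    if (
                        np.linalg.norm(p - center) > spec.cap_radius - nuc.radius
                        or p[0] - center[0] < nuc.radius
                    ):
                        p = np.array(nuc.center)
                moved.append(
                    PlantedNucleus(label=nuc.label, center=tuple(p), radius=nuc.radius)
                )
                parent_map[nuc.label] = nuc.label
            current = moved
        if division_frame is not None and frame == division_frame:
            daughters = []
            divided_map: dict[int, int] = {}
            for nuc in current:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                r_d = nuc.radius / 2.0 ** (1.0 / 3.0)
                for sign in (+1.0, -1.0):
                    # daughters end up in separate cells: offset by one radius
                    # each side so the two are resolvable as distinct objects
                    p = np.array(nuc.center) + sign * 1.1 * nuc.radius * axis
                    off_center = p - center
                    max_norm = spec.cap_radius - r_d
                    if np.linalg.norm(off_center) > max_norm:
                        p = center + off_center / np.linalg.norm(off_center) * max_norm
                    if p[0] - center[0] < r_d:
                        p[0] = center[0] + r_d
                    daughters.append(
                        PlantedNucleus(label=next_label, center=tuple(p), radius=r_d)
                    )
                    divided_map[next_label] = parent_map.get(nuc.label, nuc.label)
                    next_label += 1
            current = daughters
            parent_map = divided_map
        stack, truth = _render(spec, [PlantedNucleus(n.label, n.center, n.radius) for n in current], rng)
        stacks.append(stack)
        truths.append(truth)
        parent_maps.append(parent_map if frame > 0 else {})
    return stacks, truths, parent_maps


# ---------------------------------------------------------------------------
# Series-level generators: MS abundance tables and qPCR Ct tables
# ---------------------------------------------------------------------------

#: Default per-cell excess (GW) and cell counts across the cleavage series.
#: The per-embryo H2B totals implied by these values rise steeply to the
#: 1K stage and more gently after, as quantitative MS of staged embryos
#: shows; per-cell excess collapses from thousands to single digits because
#: the cell number grows exponentially while totals rise only ~3-fold.
DEFAULT_STAGE_CELLS: tuple[tuple[str, int], ...] = (
    ("1-cell", 1),
    ("8-cell", 8),
    ("64-cell", 64),
    ("128-cell", 128),
    ("256-cell", 256),
    ("512-cell", 512),
    ("1K", 1024),
    ("high", 1900),
    ("oblong", 3700),
    ("sphere", 8000),
    ("dome", 16000),
)

DEFAULT_EXCESS_GW_PER_CELL: dict[str, float] = {
    "1-cell": 3098.0,
    "8-cell": 518.0,
    "64-cell": 80.0,
    "128-cell": 45.0,
    "256-cell": 26.0,
    "512-cell": 15.0,
    "1K": 9.0,
    "high": 5.5,
    "oblong": 3.5,
    "sphere": 2.5,
    "dome": 2.5,
}

#: Relative abundance of each histone vs H2B (H2B is the least abundant and
#: therefore the limiting species for nucleosome assembly).
DEFAULT_HISTONE_RATIOS: dict[str, float] = {"H3": 1.15, "H4": 1.2, "H2A": 1.1, "H2B": 1.0}


def default_htotal_curve(genome: GenomeModel | None = None) -> dict[str, dict[str, float]]:
    """Per-histone, per-stage molecules/embryo implied by the default
    per-cell excess values and the bound share ``g``."""
    genome = genome or GenomeModel()
    hpg = histones_per_genome(genome)
    g = genome.bound_genomes_per_cell
    curve: dict[str, dict[str, float]] = {h: {} for h in CORE_HISTONES}
    for stage, n_cells in DEFAULT_STAGE_CELLS:
        h2b = (DEFAULT_EXCESS_GW_PER_CELL[stage] + g) * n_cells * hpg
        for histone, ratio in DEFAULT_HISTONE_RATIOS.items():
            curve[histone][stage] = h2b * ratio
    return curve


@dataclass(frozen=True)
class GeneModel:
    """Planted behaviour of one qPCR target gene.

    Before ``activation_stage`` the gene sits at the detection-floor Ct;
    from activation onward its Ct is ``floor + delta_ct_by_stage[stage]``
    (negative deltas, i.e. more template, fewer cycles).
    """

    activation_stage: str
    delta_ct_by_stage: dict[str, float]


@dataclass(frozen=True)
class SyntheticSeriesSpec:
    """Parameters of a synthetic developmental series (MS + qPCR tables)."""

    stages: tuple[tuple[str, int], ...] = DEFAULT_STAGE_CELLS
    htotal_curve: dict[str, dict[str, float]] | None = None
    noise_sd: float = 0.1
    n_replicates: int = 3
    normalizer_ct: float = 15.0
    ct_floor: float = DEFAULT_CT_FLOOR
    ct_noise_sd: float = 0.15
    genes: dict[str, GeneModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [n for _, n in self.stages]
        if any(b < a for a, b in zip(counts, counts[1:])):
            raise ValueError("cell counts must be non-decreasing across stages")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_ms_table(
    spec: SyntheticSeriesSpec, genome: GenomeModel | None = None
) -> HistoneAbundanceTable:
    """Per-stage, per-histone molecules/embryo with multiplicative noise.

    The noiseless planted value is retained in a
    ``molecules_per_embryo_true`` column.
    """
    rng = np.random.default_rng(spec.seed)
    curve = spec.htotal_curve or default_htotal_curve(genome)
    rows = []
    for stage, _ in spec.stages:
        for histone in CORE_HISTONES:
            truth = curve[histone][stage]
            if truth < 0:
                raise ValueError("htotal values must be non-negative")
            for rep in range(1, spec.n_replicates + 1):
                noisy = truth * max(0.0, 1.0 + rng.normal(0.0, spec.noise_sd)) if spec.noise_sd else truth
                rows.append(
                    {
                        "stage": stage,
                        "histone": histone,
                        "replicate": rep,
                        "molecules_per_embryo": noisy,
                        "molecules_per_embryo_true": truth,
                    }
                )
    return HistoneAbundanceTable(pd.DataFrame(rows))


def generate_cell_counts(spec: SyntheticSeriesSpec) -> pd.DataFrame:
    """Per-stage cell-count table (stage, n_cells)."""
    return pd.DataFrame([{"stage": s, "n_cells": n} for s, n in spec.stages])


def generate_qpcr_table(spec: SyntheticSeriesSpec, normalizer: str = DEFAULT_NORMALIZER) -> pd.DataFrame:
    """Ct table with a constant maternal normalizer and planted activation.

    Target genes sit at the detection-floor Ct before their activation stage
    and at ``floor + delta_ct`` afterwards; Gaussian cycle noise is added per
    technical replicate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    stage_names = [s for s, _ in spec.stages]
    rows = []
    for stage in stage_names:
        for rep in range(1, spec.n_replicates + 1):
            noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
            rows.append(
                {
                    "sample": f"{stage}-r{rep}",
                    "stage": stage,
                    "gene": normalizer,
                    "replicate": rep,
                    "ct": spec.normalizer_ct + noise,
                }
            )
            for gene, model in spec.genes.items():
                active = stage_sort_key(stage) >= stage_sort_key(model.activation_stage)
                if active:
                    delta = model.delta_ct_by_stage.get(stage, 0.0)
                    ct = spec.ct_floor + delta
                else:
                    ct = spec.ct_floor
                noise = rng.normal(0.0, spec.ct_noise_sd) if spec.ct_noise_sd else 0.0
                rows.append(
                    {
                        "sample": f"{stage}-r{rep}",
                        "stage": stage,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disk IO
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, stack: np.ndarray, voxel_size) -> None:
    """Write a ZYX stack as multi-page TIFF with voxel-size metadata."""
    vz, vy, vx = voxel_size
    tifffile.imwrite(
        str(path),
        stack.astype(np.float32),
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"axes": "ZYX", "spacing": vz, "unit": "um"},
        imagej=True,
    )


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def save_synthetic_stack(outdir: str | Path, spec: SyntheticStackSpec) -> None:
    """Generate a stack and save image, label TIFF, and JSON ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack, truth = generate_embryo_stack(spec)
    write_stack(outdir / "stack.tif", stack, spec.voxel_size)
    tifffile.imwrite(str(outdir / "labels.tif"), truth.label_volume.astype(np.uint16))
    sidecar = {
        "voxel_size_um": list(spec.voxel_size),
        "planted_v": truth.planted_v,
        "planted_r": truth.planted_r,
        "planted_cap_volume_um3": truth.planted_cap_volume,
        "nuclei": [
            {
                "label": n.label,
                "center_um": list(n.center),
                "radius_um": n.radius,
                "volume_um3": n.volume,
            }
            for n in truth.nuclei
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
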