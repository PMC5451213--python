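"""Tabular containers: histone abundances and per-stage geometry.

CSV layouts follow the supplementary-table convention of per-stage
quantitative MS output: one row per (stage, histone, replicate) with
molecules per embryo, and a per-stage geometry table carrying cell counts
and the imaging-derived volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .stoichiometry import CORE_HISTONES

#: Canonical staging vocabulary (cleavage through early gastrula).
STAGE_ORDER = (
    "1-cell",
    "2-cell",
    "4-cell",
    "8-cell",
    "16-cell",
    "32-cell",
    "64-cell",
    "128-cell",
    "256-cell",
    "512-cell",
    "1K",
    "high",
    "oblong",
    "sphere",
    "dome",
    "shield",
)


def stage_sort_key(stage: str) -> int:
    """Ordering index for a stage name; unknown stages sort last."""
    try:
        return STAGE_ORDER.index(stage)
    except ValueError:
        return len(STAGE_ORDER)


@dataclass
class HistoneAbundanceTable:
    """Per-stage, per-histone molecule counts per embryo.

    Wraps a DataFrame with columns ``stage, histone, replicate,
    molecules_per_embryo`` (replicate optional on input, filled with 1).
    """

    data: pd.DataFrame

    REQUIRED = ("stage", "histone", "molecules_per_embryo")

    def __post_init__(self) -> None:
        df = self.data
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if "replicate" not in df.columns:
            df = df.assign(replicate=1)
        if (df["molecules_per_embryo"] < 0).any():
            raise ValueError("molecule counts must be non-negative")
        bad = set(df["histone"]) - set(CORE_HISTONES)
        if bad:
            raise ValueError(f"unknown histone(s): {sorted(bad)}")
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HistoneAbundanceTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def stages(self) -> list[str]:
        return sorted(set(self.data["stage"]), key=stage_sort_key)

    def mean_per_stage(self, histone: str) -> pd.Series:
        """Replicate-averaged molecules/embryo for one histone, stage-indexed."""
        if histone not in CORE_HISTONES:
            raise ValueError(f"unknown histone {histone!r}")
        sub = self.data[self.data["histone"] == histone]
        out = sub.groupby("stage")["molecules_per_embryo"].mean()
        return out.reindex(sorted(out.index, key=stage_sort_key))

    def sem_per_stage(self, histone: str) -> pd.Series:
        sub = self.data[self.data["histone"] == histone]
        out = sub.groupby("stage")["molecules_per_embryo"].sem()
        return out.reindex(sorted(out.index, key=stage_sort_key))


@dataclass(frozen=True)
class StageGeometry:
    """Imaging-derived geometry of one developmental stage.

    Attributes
    ----------
    stage : str
        Stage name (see :data:`STAGE_ORDER`).
    n_cells : int
        Cells in the embryo at this stage.
    cap_volume : float
        Total animal-cap volume V_total, µm³.
    nuclear_volume_fraction : float
        v = (summed nuclear volume) / V_total, dimensionless.
    single_nucleus_volume : float
        Mean single-nucleus volume V_nucleus, µm³.
    """

    stage: str
    n_cells: int
    cap_volume: float
    nuclear_volume_fraction: float
    single_nucleus_volume: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cap_volume <= 0 or self.single_nucleus_volume <= 0:
            raise ValueError("volumes must be positive")
        if not 0 <= self.nuclear_volume_fraction < 1:
            raise ValueError("nuclear_volume_fraction must be in [0, 1)")

    def check_consistency(self, rtol: float = 0.2) -> bool:
        """Whether n_cells × V_nucleus ≈ v × V_total within ``rtol``."""
        expected = self.nuclear_volume_fraction * self.cap_volume
        got = self.n_cells * self.single_nucleus_volume
        if expected == 0:
            return got == 0
        return abs(got - expected) <= rtol * expected


def read_stage_geometry(path: str | Path) -> list[StageGeometry]:
    """Read a geometry CSV (stage, n_cells, cap_volume_um3, v, nucleus_volume_um3)."""
    df = pd.read_csv(path)
    cols = {"stage", "n_cells", "cap_volume_um3", "v", "nucleus_volume_um3"}
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"geometry CSV missing column(s): {sorted(missing)}")
    rows = [
        StageGeometry(
            stage=str(r.stage),
            n_cells=int(r.n_cells),
            cap_volume=float(r.cap_volume_um3),
            nuclear_volume_fraction=float(r.v),
            single_nucleus_volume=float(r.nucleus_volume_um3),
        )
        for r in df.itertuples()
    ]
    return sorted(rows, key=lambda g: stage_sort_key(g.stage))


def write_stage_geometry(geoms: Iterable[StageGeometry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "stage": g.stage,
                "n_cells": g.n_cells,
                "cap_volume_um3": g.cap_volume,
                "v": g.nuclear_volume_fraction,
                "nucleus_volume_um3": g.single_nucleus_volume,
            }
            for g in geoms
        ]
    ).to_csv(path, index=False)


def read_cell_counts(path: str | Path) -> dict[str, int]:
    """Read a per-stage cell-count CSV (stage, n_cells)."""
    df = pd.read_csv(path)
    if not {"stage", "n_cells"} <= set(df.columns):
        raise ValueError("cell-count CSV needs columns: stage, n_cells")
    return {str(r.stage): int(r.n_cells) for r in df.itertuples()}
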