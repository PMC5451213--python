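"""Two-compartment allocation of histones between nucleus and cytoplasm.

The embryo-wide histone amount H_total must be accounted for by the summed
nuclear and cytoplasmic compartments of all cells:

    H_total = [H_nuclear]·v·V_total + [H_cytoplasm]·(1−v)·V_total

with v the fraction of the animal-cap volume V_total occupied by nuclei.
Taking the immunofluorescence nuclear-over-cytoplasmic intensity ratio R as
the concentration ratio, R ≈ [H_nuclear]/[H_cytoplasm], the system solves in
closed form:

    [H_nuclear] = (H_total / V_total) · R / (1 + v(R − 1))

The measured nuclear concentration includes chromatin-bound histones; the
non-DNA-bound ("free") nuclear concentration subtracts g genomes worth per
nucleus volume:

    [H_free] = [H_nuclear] − g / V_nucleus

Canonical internal unit is molecules/µm³; genomes-worth and nanomolar views
are derived through the genome model and Avogadro conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GenomeModel
from .stoichiometry import histones_per_genome
from .tables import HistoneAbundanceTable, StageGeometry, stage_sort_key
from .units import molecules_per_um3_to_nanomolar


@dataclass(frozen=True)
class ConcentrationInputs:
    """Everything the two-compartment model needs for one stage.

    ``h_total`` is in molecules per embryo; volumes in µm³; ``v`` and ``r``
    dimensionless; ``g`` in genomes worth bound per nucleus.
    """

    h_total: float
    cap_volume: float
    nuclear_volume_fraction: float
    nc_ratio: float
    single_nucleus_volume: float
    genome: GenomeModel

    def __post_init__(self) -> None:
        if self.h_total < 0:
            raise ValueError("h_total must be non-negative")
        if self.cap_volume <= 0 or self.single_nucleus_volume <= 0:
            raise ValueError("volumes must be positive")
        if not 0 <= self.nuclear_volume_fraction < 1:
            raise ValueError("nuclear volume fraction must be in [0, 1)")
        if self.nc_ratio <= 0:
            raise ValueError("N/C ratio must be positive")


@dataclass(frozen=True)
class ConcentrationResult:
    """Nuclear, cytoplasmic and free-nuclear concentrations for one stage.

    All concentration fields are molecules/µm³. ``deficit`` flags a negative
    free concentration (more chromatin-bound histone assumed than measured in
    the nucleus), which is reported, not clamped: it diagnoses inconsistent
    inputs.
    """

    stage: str
    nuclear: float
    cytoplasm: float
    free_nuclear: float
    nuclear_amount: float
    cytoplasm_amount: float
    deficit: bool
    genome: GenomeModel

    def gw_per_um3(self, which: str = "free_nuclear") -> float:
        """A concentration field in genomes worth per µm³."""
        return getattr(self, which) / histones_per_genome(self.genome)

    def nanomolar(self, which: str = "free_nuclear") -> float:
        """A concentration field in nM."""
        return molecules_per_um3_to_nanomolar(getattr(self, which))


def nuclear_concentration(inputs: ConcentrationInputs) -> tuple[float, float]:
    """Closed-form [H_nuclear] and [H_cytoplasm] in molecules/µm³.

    Raises if the partition denominator 1 + v(R−1) is non-positive, which
    cannot happen for valid inputs and therefore guards corrupt ones.
    """
    v, r = inputs.nuclear_volume_fraction, inputs.nc_ratio
    denom = 1.0 + v * (r - 1.0)
    if denom <= 0:
        raise ValueError(f"invalid partition: 1 + v(R-1) = {denom} <= 0")
    h_nuc = inputs.h_total / inputs.cap_volume * r / denom
    return h_nuc, h_nuc / r


def free_nuclear_concentration(
    h_nuclear: float, inputs: ConcentrationInputs
) -> tuple[float, bool]:
    """[H_free] = [H_nuclear] − g·(histones per genome)/V_nucleus.

    Returns the value (molecules/µm³) and a deficit flag for negative
    results.
    """
    bound = (
        inputs.genome.bound_genomes_per_cell
        * histones_per_genome(inputs.genome)
        / inputs.single_nucleus_volume
    )
    free = h_nuclear - bound
    return free, free < 0


def concentration_result(stage: str, inputs: ConcentrationInputs) -> ConcentrationResult:
    """Run the full two-compartment calculation for one stage."""
    h_nuc, h_cyt = nuclear_concentration(inputs)
    free, deficit = free_nuclear_concentration(h_nuc, inputs)
    v = inputs.nuclear_volume_fraction
    return ConcentrationResult(
        stage=stage,
        nuclear=h_nuc,
        cytoplasm=h_cyt,
        free_nuclear=free,
        nuclear_amount=h_nuc * v * inputs.cap_volume,
        cytoplasm_amount=h_cyt * (1.0 - v) * inputs.cap_volume,
        deficit=deficit,
        genome=inputs.genome,
    )


def stage_series(
    ms: HistoneAbundanceTable,
    geometry: list[StageGeometry],
    ratios: dict[str, float],
    genome: GenomeModel,
    histone: str = "H4",
) -> list[ConcentrationResult]:
    """Per-stage concentration results combining MS, volumes and N/C ratios.

    The designated histone is H4, the species detected by the endogenous
    immunofluorescence that provides R. Raises if a stage present in the
    geometry lacks an MS value or ratio, naming the stage.
    """
    totals = ms.mean_per_stage(histone)
    results = []
    for geom in sorted(geometry, key=lambda g: stage_sort_key(g.stage)):
        if geom.stage not in totals.index:
            raise KeyError(f"stage {geom.stage!r} missing from abundance table")
        if geom.stage not in ratios:
            raise KeyError(f"stage {geom.stage!r} missing from N/C ratio table")
        inputs = ConcentrationInputs(
            h_total=float(totals[geom.stage]),
            cap_volume=geom.cap_volume,
            nuclear_volume_fraction=geom.nuclear_volume_fraction,
            nc_ratio=float(ratios[geom.stage]),
            single_nucleus_volume=geom.single_nucleus_volume,
            genome=genome,
        )
        results.append(concentration_result(geom.stage, inputs))
    return results


def series_to_frame(results: list[ConcentrationResult]) -> pd.DataFrame:
    """Tabulate a concentration series in all three unit views."""
    rows = []
    for r in results:
        hpg = histones_per_genome(r.genome)
        rows.append(
            {
                "stage": r.stage,
                "nuclear_per_um3": r.nuclear,
                "cytoplasm_per_um3": r.cytoplasm,
                "free_nuclear_per_um3": r.free_nuclear,
                "nuclear_gw_per_um3": r.nuclear / hpg,
                "cytoplasm_gw_per_um3": r.cytoplasm / hpg,
                "free_nuclear_gw_per_um3": r.free_nuclear / hpg,
                "nuclear_nM": r.nanomolar("nuclear"),
                "cytoplasm_nM": r.nanomolar("cytoplasm"),
                "free_nuclear_nM": r.nanomolar("free_nuclear"),
                "deficit": r.deficit,
            }
        )
    return pd.DataFrame(rows)
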