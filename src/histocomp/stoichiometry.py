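"""Histone stoichiometry: genomes-worth conversion and per-cell excess.

Given absolute histone amounts per embryo (from quantitative mass
spectrometry) and a :class:`~histocomp.genome.GenomeModel`, these functions
express amounts as multiples of what is needed to chromatinise one diploid
genome ("genomes worth", GW), subtract the chromatin-bound share per cell,
and convert per-embryo excesses into concentrations over the animal-cap
volume.

All returned scalars are unit-tagged (:class:`histocomp.units.UnitValue`) so
that per-embryo and per-cell quantities, molecule counts and GW cannot be
mixed silently.
"""

from __future__ import annotations

import logging

from .genome import GenomeModel
from .units import AVOGADRO, L_PER_UM3, UnitValue

log = logging.getLogger(__name__)

CORE_HISTONES = ("H3", "H4", "H2A", "H2B")


def histones_per_genome(model: GenomeModel) -> int:
    """Copies of each core histone needed to wrap one full genome.

    The nucleosome count ``ploidy × haploid_length / NRL`` is rounded to the
    nearest integer before doubling (each histone appears twice per
    nucleosome), so the result is always even.
    """
    nucleosomes = round(model.ploidy * model.haploid_length / model.nucleosome_repeat_length)
    return int(nucleosomes) * model.histones_per_nucleosome_per_type


def genomes_worth(copies: float, model: GenomeModel) -> UnitValue:
    """Express a histone copy number as genomes worth (GW)."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    return UnitValue(copies / histones_per_genome(model), "GW")


def gw_to_molecules(gw: float, model: GenomeModel) -> UnitValue:
    """Inverse of :func:`genomes_worth` (explicit unit conversion)."""
    return UnitValue(float(gw) * histones_per_genome(model), "molecules")


def excess_gw_per_cell(
    h2b_total: float, n_cells: int, model: GenomeModel
) -> UnitValue:
    """Non-DNA-bound genomes worth of histone per cell.

    ``h2b_total`` is the embryo-wide H2B copy number. H2B is the designated
    histone for this calculation because it is the least abundant of the four
    core histones and therefore potentially limiting for nucleosome assembly.
    The chromatin-bound share ``g`` (GW per cell, between 1 and the ploidy)
    is subtracted after dividing by the cell count.

    A negative result (histone deficit) is returned as-is but logged.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if h2b_total < 0:
        raise ValueError("h2b_total must be non-negative")
    per_cell = genomes_worth(h2b_total, model).value / n_cells
    excess = per_cell - model.bound_genomes_per_cell
    if excess < 0:
        log.warning(
            "histone deficit: %.3f GW/cell available, %.3f GW assumed bound",
            per_cell,
            model.bound_genomes_per_cell,
        )
    return UnitValue(excess, "GW/cell")


def total_free_concentration(
    excess_gw_embryo: float, cap_volume: float
) -> tuple[UnitValue, UnitValue]:
    """Embryo-wide excess histone concentration over the animal cap.

    Parameters
    ----------
    excess_gw_embryo : float
        Total non-DNA-bound histone in the embryo, genomes worth.
    cap_volume : float
        Animal-cap volume in µm³.

    Returns
    -------
    (gw_per_um3, nanomolar_equivalent)
        The GW/µm³ value and its nanomolar view (one GW treated as one
        "molecule" of a genome-wrapping unit; useful only for relative
        comparisons across stages).
    """
    if cap_volume <= 0:
        raise ValueError("cap_volume must be positive")
    conc = excess_gw_embryo / cap_volume
    nanomolar = conc / (AVOGADRO * L_PER_UM3) * 1e9
    return UnitValue(conc, "GW/um3"), UnitValue(nanomolar, "nM(GW)")


def cocktail_genomes_worth(
    copies_per_histone: dict[str, float] | tuple[float, float, float, float],
    model: GenomeModel,
) -> UnitValue:
    """GW of a four-histone cocktail, set by the limiting histone.

    Nucleosomes need all four core histones in equal copy number, so the
    usable genomes worth of a mixture is the minimum over the four types.
    """
    if isinstance(copies_per_histone, dict):
        missing = set(CORE_HISTONES) - set(copies_per_histone)
        if missing:
            raise ValueError(f"missing histone(s): {sorted(missing)}")
        counts = [copies_per_histone[h] for h in CORE_HISTONES]
    else:
        counts = list(copies_per_histone)
        if len(counts) != 4:
            raise ValueError("expected four copy numbers (H3, H4, H2A, H2B)")
    if any(c < 0 for c in counts):
        raise ValueError("copy numbers must be non-negative")
    return UnitValue(min(counts) / histones_per_genome(model), "GW")
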