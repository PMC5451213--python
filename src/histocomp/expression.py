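"""qPCR expression arithmetic: ΔCt relative expression, fold differences,
ChIP percent-input, and DNA-scaling expectations.

Relative mRNA expression is computed against a maternally loaded normalizer
gene (eif4g2a in this system) as 1/2^(Ct_gene − Ct_norm), assuming an
amplification efficiency of 2 per cycle. "Not detected" reactions are
represented by a detection-floor Ct (default 35 cycles) and flagged rather
than silently treated as numeric zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_CT_FLOOR = 35.0
DEFAULT_NORMALIZER = "eif4g2a"


@dataclass(frozen=True)
class RelativeExpression:
    """A ΔCt-derived expression level with a detection flag."""

    value: float
    detected: bool


def relative_expression(
    ct_gene: float,
    ct_norm: float,
    efficiency: float = 2.0,
    ct_floor: float = DEFAULT_CT_FLOOR,
) -> RelativeExpression:
    """Relative expression 1/efficiency^(Ct_gene − Ct_norm).

    A gene Ct at or beyond the detection floor yields the floor-level value
    flagged ``detected=False``.
    """
    if not (math.isfinite(ct_gene) and math.isfinite(ct_norm)):
        raise ValueError("Ct values must be finite; encode non-detection as the floor Ct")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    detected = ct_gene < ct_floor
    return RelativeExpression(
        value=1.0 / efficiency ** (ct_gene - ct_norm), detected=detected
    )


def fold_difference(rel_test: float, rel_control: float) -> float:
    """Ratio of two relative expression levels (test over control)."""
    if rel_control <= 0:
        raise ValueError("control relative expression must be positive")
    return rel_test / rel_control


def chip_percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 1.0
) -> float:
    """ChIP enrichment as percent of input chromatin.

    The input aliquot is only ``input_fraction`` of the IP'd chromatin, so
    its Ct is first adjusted down by log2(1/input_fraction) cycles to what
    the full input would give; percent input is then
    100 × 2^(Ct_input_adjusted − Ct_IP).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (ct_input_adjusted - ct_ip)


def expected_dna_fold(n_cells_a: int, n_cells_b: int) -> float:
    """Fold change in DNA amount expected between two stages.

    At constant ploidy the genomic DNA per embryo scales with cell number,
    so a chromatin-bound signal scaling with DNA should change by
    n_cells_b / n_cells_a.
    """
    if n_cells_a < 1 or n_cells_b < 1:
        raise ValueError("cell counts must be >= 1")
    return n_cells_b / n_cells_a


def expression_table(
    ct: pd.DataFrame,
    normalizer: str = DEFAULT_NORMALIZER,
    efficiency: float = 2.0,
    ct_floor: float = DEFAULT_CT_FLOOR,
) -> pd.DataFrame:
    """Per-(sample, stage, gene) relative expression from a Ct table.

    Expects columns ``sample, stage, gene, replicate, ct``. Technical
    replicates are averaged in Ct space before transformation; each sample's
    genes are normalized against that same sample's normalizer Ct
    (normalize-then-average order across samples is left to the caller).
    """
    required = {"sample", "stage", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    mean_ct = (
        ct.groupby(["sample", "stage", "gene"])["ct"].mean().rename("ct").reset_index()
    )
    norm = mean_ct[mean_ct["gene"] == normalizer].set_index(["sample", "stage"])["ct"]
    rows = []
    for r in mean_ct.itertuples():
        key = (r.sample, r.stage)
        if key not in norm.index:
            raise ValueError(f"normalizer {normalizer!r} missing for sample/stage {key}")
        rel = relative_expression(r.ct, float(norm[key]), efficiency, ct_floor)
        rows.append(
            {
                "sample": r.sample,
                "stage": r.stage,
                "gene": r.gene,
                "relative_expression": rel.value,
                "detected": rel.detected,
            }
        )
    return pd.DataFrame(rows)


def activation_stage(
    expr: pd.DataFrame,
    gene: str,
    stage_order: list[str],
    min_fold: float = 2.0,
) -> str | None:
    """First stage at which a gene exceeds ``min_fold`` over its
    pre-activation floor (the minimum across earlier stages).

    Returns None if the gene never activates within the covered stages.
    """
    sub = expr[expr["gene"] == gene]
    by_stage = sub.groupby("stage")["relative_expression"].mean()
    floor = None
    for stage in stage_order:
        if stage not in by_stage.index:
            continue
        level = float(by_stage[stage])
        if floor is not None and level >= min_fold * floor:
            return stage
        floor = level if floor is None else min(floor, level)
    return None
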