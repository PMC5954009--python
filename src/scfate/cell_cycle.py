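"""Cell-cycle phase assignment from phase-specific gene signatures.

The procedure is deliberately simple and reference-anchored:

1. each gene is max-normalized — divided by its maximum over all cells in
   the analysis set (reference cells included, so reference and test cells
   share one scale);
2. a cell's G1 score and S/G2/M score are the averages of its normalized
   expression over the G1-phase and S/G2/M-phase signature genes;
3. the S/G2/M-score threshold is calibrated on a reference population of
   control HSCs, of which around 90% are known to sit in G0/G1: the cutoff
   is the smallest reference score such that at least the requested
   fraction of reference cells falls at or below it;
4. cells with an S/G2/M score strictly above the cutoff are called S/G2/M,
   everything else G0/G1 (ties go to the quiescent side).

Only the S/G2/M score drives the call; the G1 score is reported for
plotting (phase scatter) and sanity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenePanel

G0G1 = "G0G1"
SG2M = "SG2M"

#: Default fraction of reference HSCs expected in G0/G1.
DEFAULT_REFERENCE_FRACTION = 0.90

#: Minimum reference cells for a trustworthy calibration.
MIN_REFERENCE_CELLS = 10


@dataclass
class PhaseThreshold:
    """Calibrated S/G2/M-score cutoff."""

    sg2m_cutoff: float
    reference_fraction: float
    reference_n: int


def max_normalize(
    matrix: ExpressionMatrix, gene_subset: list[str] | None = None
) -> ExpressionMatrix:
    """Divide each gene by its maximum over all cells in the analysis set.

    Output values lie in [0, 1]; an entirely undetected gene maps to all
    zeros (no division by zero).
    """
    genes = gene_subset if gene_subset is not None else matrix.gene_ids
    if not genes:
        raise ValueError("gene subset must be nonempty")
    sub = matrix.subset_genes(list(genes))
    maxima = sub.values.max(axis=0)
    safe = maxima.replace(0.0, 1.0)
    return ExpressionMatrix(sub.values / safe)


def phase_scores(
    matrix: ExpressionMatrix, panel: GenePanel
) -> pd.DataFrame:
    """Per-cell G1 and S/G2/M signature scores (uncalled).

    Scores are means of max-normalized expression over the panel's
    ``cc_g1`` and ``cc_sg2m`` genes; normalization maxima are taken over
    the full cohort present in ``matrix``.
    """
    g1_genes = [g for g in panel.genes("cc_g1") if g in matrix.values.columns]
    sg2m_genes = [g for g in panel.genes("cc_sg2m") if g in matrix.values.columns]
    if not g1_genes or not sg2m_genes:
        raise ValueError(
            "panel must contribute at least one cc_g1 and one cc_sg2m gene "
            "present in the matrix"
        )
    norm = max_normalize(matrix, g1_genes + sg2m_genes)
    return pd.DataFrame(
        {
            "g1_score": norm.values[g1_genes].mean(axis=1),
            "sg2m_score": norm.values[sg2m_genes].mean(axis=1),
            "call": "uncalled",
        },
        index=matrix.values.index,
    )


def calibrate_threshold(
    reference_scores: pd.DataFrame,
    reference_fraction: float = DEFAULT_REFERENCE_FRACTION,
) -> PhaseThreshold:
    """Lower-tail-inclusive empirical quantile of reference S/G2/M scores.

    The cutoff is the smallest observed reference score such that the
    fraction of reference cells with score <= cutoff is at least
    ``reference_fraction`` (and minimal among achievable fractions).
    """
    if not 0.0 < reference_fraction <= 1.0:
        raise ValueError("reference_fraction must be in (0, 1]")
    scores = np.sort(reference_scores["sg2m_score"].to_numpy())
    n = scores.size
    if n < MIN_REFERENCE_CELLS:
        raise ValueError(
            f"calibration needs >= {MIN_REFERENCE_CELLS} reference cells, "
            f"got {n}"
        )
    # k-th order statistic with k = ceil(fraction * n) gives the smallest
    # score whose lower-tail-inclusive empirical CDF reaches the fraction.
    k = int(np.ceil(reference_fraction * n))
    cutoff = float(scores[k - 1])
    return PhaseThreshold(cutoff, reference_fraction, n)


def classify_phase(
    scores: pd.DataFrame, threshold: PhaseThreshold
) -> pd.DataFrame:
    """Call G0/G1 vs S/G2/M: S/G2/M iff sg2m_score > cutoff."""
    out = scores.copy()
    out["call"] = np.where(
        out["sg2m_score"] > threshold.sg2m_cutoff, SG2M, G0G1
    )
    return out


def phase_foldchange(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    calls: pd.DataFrame,
    panel: GenePanel,
    gene_category: str = "mep_platelet",
    reference_population: str = "HSC",
    reference_phase: str = G0G1,
) -> pd.DataFrame:
    """Mean category-gene expression per (population, phase) stratum,
    as fold change relative to a reference stratum.

    Mirrors a lineage-priming readout: e.g. mean MEP/platelet-gene
    expression of each population in each phase, relative to HSCs in
    G0/G1.  Empty strata yield NaN with a warning; a zero reference mean
    is an error.
    """
    genes = [g for g in panel.genes(gene_category) if g in matrix.values.columns]
    if not genes:
        raise ValueError(f"no {gene_category!r} genes in matrix")
    sub = matrix.values[genes]
    strata = pd.DataFrame(
        {
            "population": annotation["population"],
            "phase": calls.loc[annotation.index, "call"],
            "mean_expr": sub.mean(axis=1),
        }
    )
    ref = strata[
        (strata["population"] == reference_population)
        & (strata["phase"] == reference_phase)
    ]
    if ref.empty:
        raise ValueError(
            f"reference stratum ({reference_population}, {reference_phase}) "
            "is empty"
        )
    ref_mean = ref["mean_expr"].mean()
    if ref_mean == 0:
        raise ValueError("reference stratum mean expression is zero")

    populations = list(dict.fromkeys(annotation["population"]))
    phases = [G0G1, SG2M]
    table = pd.DataFrame(index=populations, columns=phases, dtype=float)
    for pop in populations:
        for ph in phases:
            cell_mask = (strata["population"] == pop) & (strata["phase"] == ph)
            if not cell_mask.any():
                warnings.warn(
                    f"empty stratum ({pop}, {ph}); fold change set to NaN",
                    stacklevel=2,
                )
                continue
            table.loc[pop, ph] = strata.loc[cell_mask, "mean_expr"].mean() / ref_mean
    return table
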