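"""Reading, writing and preprocessing of expression tables.

The on-disk format is plain delimited text (TSV or CSV) with cell and gene
ids in the header row/column.  Raw Ct tables are converted to the
nonnegative "Et" expression scale ``Et = lod_ct - Ct`` (limit-of-detection
minus threshold cycle), which makes larger values mean more expressed and
maps nondetects to exactly 0.  Confounding sampling effects (batch, plate)
are removed gene-wise by an additive linear model fitted on detected
values only, leaving the detection pattern untouched so the hurdle model's
two parts stay identifiable.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import (
    ExpressionMatrix,
    GenePanel,
    MatrixValidationError,
    validate_annotation,
)

#: Floor applied to corrected detected values so residualization can never
#: turn a detected entry into an apparent nondetect.
DETECTED_FLOOR = 1e-6


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(
    path: str | Path, orientation: str = "cells_by_genes"
) -> ExpressionMatrix:
    """Read a delimited expression table.

    Parameters
    ----------
    orientation
        ``"cells_by_genes"`` (rows are cells) or ``"genes_by_cells"``
        (rows are genes, as in a heat-map export); the matrix is
        normalized internally to cells x genes.
    """
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    # pandas silently renames duplicate header fields; check them verbatim
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    dup = sorted({h for h in header if header.count(h) > 1})
    if dup:
        raise MatrixValidationError(f"duplicate ids in header of {path}: {dup}")
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise MatrixValidationError(f"cannot parse {path}: {exc}") from exc
    if orientation == "genes_by_cells":
        df = df.T
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_numeric:
        raise MatrixValidationError(
            f"non-numeric entries in columns {non_numeric} of {path}"
        )
    if df.isna().any().any():
        cells = df.index[df.isna().any(axis=1)].tolist()
        raise MatrixValidationError(f"NaN/missing values for cells {cells}")
    return ExpressionMatrix(df)


def write_matrix(
    matrix: ExpressionMatrix, path: str | Path,
    orientation: str = "cells_by_genes",
) -> None:
    df = matrix.values
    if orientation == "genes_by_cells":
        df = df.T
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation: {orientation!r}")
    df.to_csv(path, sep=_sep_for(path))


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "is_reference" in ann.columns:
        ann["is_reference"] = ann["is_reference"].astype(bool)
    return validate_annotation(ann)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep=_sep_for(path), index_label="cell_id")


def ct_to_expression(
    ct_table: pd.DataFrame, lod_ct: float = 24.0
) -> ExpressionMatrix:
    """Convert raw Ct values (cells x genes) to Et expression.

    ``Et = max(lod_ct - Ct, 0)``.  Nondetects may be encoded as NaN/empty
    or as any Ct at or beyond the limit of detection (the common "999"
    sentinel included); all map to 0 with the mask false.
    """
    if lod_ct <= 0:
        raise ValueError("lod_ct must be positive")
    ct = ct_table.astype(float)
    if (ct.to_numpy() < 0).any():
        raise MatrixValidationError("negative Ct values")
    et = (lod_ct - ct).clip(lower=0.0).fillna(0.0)
    return ExpressionMatrix(et)


def correct_confounders(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    covariates: list[str],
) -> ExpressionMatrix:
    """Remove additive confounder effects from detected values, gene-wise.

    For each gene an ordinary least squares model with the categorical
    covariates is fitted on the detected (positive) values only; the
    returned detected values are the residuals plus the grand mean of the
    gene's detected values, floored at a small epsilon.  Zeros (nondetects)
    pass through untouched, so detection frequencies are preserved exactly.

    Covariates with a single level overall are dropped (no-op).  A gene
    whose detected cells do not span >= 2 levels of some remaining
    covariate is skipped with a warning.
    """
    validate_annotation(annotation, matrix)
    for cov in covariates:
        if cov not in annotation.columns:
            raise KeyError(f"covariate {cov!r} missing from annotation")
        if annotation[cov].isna().any():
            raise MatrixValidationError(f"covariate {cov!r} has missing values")

    active = [c for c in covariates if annotation[c].nunique() >= 2]
    if not active:
        return ExpressionMatrix(matrix.values.copy())

    out = matrix.values.copy()
    for gene in matrix.gene_ids:
        col = matrix.values[gene]
        det = col > 0
        if det.sum() < 2:
            continue
        sub_ann = annotation.loc[det]
        if any(sub_ann[c].nunique() < 2 for c in active):
            warnings.warn(
                f"gene {gene}: covariate confounded with detection pattern; "
                "skipped",
                stacklevel=2,
            )
            continue
        design = pd.get_dummies(
            sub_ann[active].astype(str), drop_first=True, dtype=float
        )
        X = sm.add_constant(design, has_constant="add")
        y = col[det].to_numpy()
        fit = sm.OLS(y, X).fit()
        corrected = y - fit.fittedvalues + y.mean()
        out.loc[det, gene] = np.maximum(corrected, DETECTED_FLOOR)
    return ExpressionMatrix(out)


def subset_panel(
    matrix: ExpressionMatrix, panel: GenePanel, categories: list[str] | set[str]
) -> ExpressionMatrix:
    """Keep only genes whose panel tag is in ``categories`` (matrix order)."""
    if not categories:
        raise ValueError("categories must be nonempty")
    wanted = set(panel.genes(*categories))
    keep = [g for g in matrix.gene_ids if g in wanted]
    if not keep:
        raise ValueError(
            f"no genes in matrix for categories {sorted(categories)}"
        )
    return matrix.subset_genes(keep)
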