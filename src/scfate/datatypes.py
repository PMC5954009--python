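"""Core containers for single-cell qPCR expression analysis.

Expression values live on a nonnegative "Et"/dCt-like scale where larger
means more expressed and exactly 0 encodes "not detected".  The detection
mask is therefore derived, never stored separately: ``value > 0  <=>
detected``.  All downstream statistics (the hurdle test in particular)
rely on this convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Gene-panel category tags.
PANEL_CATEGORIES = frozenset(
    {"hsc", "mep_platelet", "myeloid", "erythroid", "cc_g1", "cc_sg2m", "other"}
)

#: G1-phase cell-cycle signature genes.
CC_G1_GENES = ("Ccne1", "Cdk2", "Cdkn1a", "Cdkn1c")

#: S/G2/M-phase cell-cycle signature genes.
CC_SG2M_GENES = (
    "Cdkn2d",
    "E2f4",
    "Cdk6",
    "Cdkn2c",
    "Ccng2",
    "Ccnf",
    "Mki67",
    "Ccna2",
    "Ccnb1",
    "Ccnb2",
    "Cdc20",
)

#: Synthetic stand-in panel members: megakaryocyte/erythroid ("MEP/platelet")
#: lineage genes and HSC/stemness genes.  The gene symbols are real murine
#: lineage markers, but their membership here is a synthetic default panel
#: (the full measured panel of the motivating study is not public), used by
#: the simulator and as a packaged example.
SYNTHETIC_MEP_PLATELET_GENES = (
    "Itga2b",
    "Vwf",
    "Pf4",
    "Gata1",
    "Gp1bb",
    "Gp9",
    "Klf1",
    "Epor",
    "Zfpm1",
    "Nfe2",
    "Mpl",
    "Tal1",
)

SYNTHETIC_HSC_GENES = (
    "Procr",
    "Hlf",
    "Mecom",
    "Fgd5",
    "Hoxa9",
    "Mllt3",
    "Pdzk1ip1",
    "Slamf1",
)


class MatrixValidationError(ValueError):
    """Raised when an expression table violates the container contract."""


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with an implied detection mask.

    Parameters
    ----------
    values
        DataFrame indexed by cell id, columns are gene ids.  Entries are
        nonnegative floats; 0 means the gene was not detected in that cell.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate cell ids: {dup}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene ids: {dup}")
        arr = v.to_numpy()
        if np.isnan(arr).any():
            raise MatrixValidationError("expression values contain NaN")
        if (arr < 0).any():
            raise MatrixValidationError("expression values must be nonnegative")

    # -- views ------------------------------------------------------------
    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask; True exactly where value > 0."""
        return self.values > 0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self.values[genes].copy())

    def subset_cells(self, cells: list[str]) -> "ExpressionMatrix":
        missing = [c for c in cells if c not in self.values.index]
        if missing:
            raise KeyError(f"cells not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[cells].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)


def concat_matrices(*matrices: ExpressionMatrix) -> ExpressionMatrix:
    """Stack matrices cell-wise; gene sets must agree."""
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if m.gene_ids != genes:
            raise MatrixValidationError("gene sets differ between matrices")
    return ExpressionMatrix(pd.concat([m.values for m in matrices], axis=0))


@dataclass
class GenePanel:
    """Mapping of gene id to functional category tag."""

    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.categories.values()} - PANEL_CATEGORIES
        if bad:
            raise ValueError(
                f"unknown panel categories {sorted(bad)}; "
                f"valid: {sorted(PANEL_CATEGORIES)}"
            )

    def genes(self, *categories: str) -> list[str]:
        """Genes carrying any of the given tags, in panel order."""
        unknown = set(categories) - PANEL_CATEGORIES
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        return [g for g, c in self.categories.items() if c in categories]

    @property
    def all_genes(self) -> list[str]:
        return list(self.categories)

    @classmethod
    def default(cls) -> "GenePanel":
        """Packaged default panel.

        The 15 cell-cycle signature genes (4 G1-phase + 11 S/G2/M-phase)
        plus the synthetic MEP/platelet and HSC stand-in sets.
        """
        cats: dict[str, str] = {}
        for g in SYNTHETIC_HSC_GENES:
            cats[g] = "hsc"
        for g in SYNTHETIC_MEP_PLATELET_GENES:
            cats[g] = "mep_platelet"
        for g in CC_G1_GENES:
            cats[g] = "cc_g1"
        for g in CC_SG2M_GENES:
            cats[g] = "cc_sg2m"
        return cls(cats)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.categories, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenePanel":
        return cls(json.loads(Path(path).read_text()))


#: Columns an annotation table may carry.  ``cell_id`` is the index.
ANNOTATION_COLUMNS = (
    "population",
    "batch",
    "is_reference",
    "dye_intensity",
    "true_phase",
    "true_generation",
)


def validate_annotation(
    annotation: pd.DataFrame, matrix: ExpressionMatrix | None = None
) -> pd.DataFrame:
    """Check a per-cell annotation table and return it.

    The table is indexed by cell id and holds population label, batch,
    reference flag, optional dye intensity and (synthetic-only) ground
    truth columns.  When ``matrix`` is given the cell ids must match.
    """
    if annotation.index.duplicated().any():
        dup = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate cell ids in annotation: {dup}")
    if "dye_intensity" in annotation.columns:
        dye = annotation["dye_intensity"].dropna()
        if (dye <= 0).any():
            raise MatrixValidationError("dye_intensity must be positive")
    if matrix is not None and list(annotation.index) != matrix.cell_ids:
        raise MatrixValidationError(
            "annotation cell ids do not match expression matrix"
        )
    return annotation
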