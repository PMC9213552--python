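"""Core in-memory containers.

The central object is :class:`ExpressionMatrix`: a cells x genes matrix of
expression values together with a boolean missing-value mask and an assay
tag.  Three assays are distinguished:

``ct``
    raw qPCR cycle-threshold values (higher Ct = lower expression),
``counts``
    normalized read counts from scRNA-seq (0 = undetected),
``normalized``
    relative expression, e.g. 2^-dCt values or log-scale expression.

Masked entries are excluded from every statistic computed downstream; they
are written out as ``NA``.  Cell annotations (stage, genotype, embryo,
population) travel in an ordinary :class:`pandas.DataFrame` validated by
:func:`validate_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

ASSAYS = ("ct", "counts", "normalized")

#: columns an annotation table must provide (``population`` is optional)
ANNOTATION_COLUMNS = ("cell_id", "stage", "genotype", "embryo_id")


@dataclass
class ExpressionMatrix:
    """Cells x genes expression values with a missing-value mask.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` float array.  Entries under a ``True`` mask
        are ignored by all statistics (their stored value is arbitrary).
    mask
        Boolean array of the same shape; ``True`` marks a missing entry.
    assay
        One of ``"ct"``, ``"counts"``, ``"normalized"``.
    gene_ids, cell_ids
        Unique, ordered identifiers (opaque strings).
    flagged_genes
        Genes carried along but excluded from analyses by default
        (e.g. housekeeping genes after normalization).
    """

    values: np.ndarray
    mask: np.ndarray
    assay: str
    gene_ids: list[str]
    cell_ids: list[str]
    flagged_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.assay not in ASSAYS:
            raise InputError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.values.ndim != 2:
            raise InputError("values must be a 2-D cells x genes array")
        if self.values.shape != self.mask.shape:
            raise InputError("values and mask shapes differ")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise InputError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise InputError(f"duplicated {kind} ids: {dupes}")
        if self.assay == "ct":
            observed = self.values[~self.mask]
            if observed.size and np.nanmin(observed) < 0:
                raise InputError("ct assay requires non-negative Ct values")

    # -- indexing helpers -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise InputError(f"gene {gene!r} not present in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        """Values of one gene with masked entries as NaN."""
        j = self.gene_index(gene)
        out = self.values[:, j].copy()
        out[self.mask[:, j]] = np.nan
        return out

    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.mask)

    def nan_values(self) -> np.ndarray:
        """Dense copy with masked entries replaced by NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def subset(
        self,
        cells: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``cells`` and/or ``genes``
        (order follows the argument, not the original matrix)."""
        rows = (
            np.arange(self.n_cells)
            if cells is None
            else np.array([self._cell_index(c) for c in cells])
        )
        cols = (
            np.arange(self.n_genes)
            if genes is None
            else np.array([self.gene_index(g) for g in genes])
        )
        cell_ids = [self.cell_ids[i] for i in rows]
        gene_ids = [self.gene_ids[j] for j in cols]
        return ExpressionMatrix(
            values=self.values[np.ix_(rows, cols)],
            mask=self.mask[np.ix_(rows, cols)],
            assay=self.assay,
            gene_ids=gene_ids,
            cell_ids=cell_ids,
            flagged_genes={g for g in self.flagged_genes if g in gene_ids},
        )

    def _cell_index(self, cell: str) -> int:
        try:
            return self.cell_ids.index(cell)
        except ValueError:
            raise InputError(f"cell {cell!r} not present in matrix") from None

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            mask=self.mask.copy(),
            assay=self.assay,
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            flagged_genes=set(self.flagged_genes),
        )

    # -- pandas interop ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Cells x genes DataFrame with NaN at masked entries."""
        return pd.DataFrame(self.nan_values(), index=self.cell_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, assay: str) -> "ExpressionMatrix":
        values = frame.to_numpy(dtype=float)
        mask = np.isnan(values)
        values = np.where(mask, 0.0, values)
        return cls(
            values=values,
            mask=mask,
            assay=assay,
            gene_ids=[str(c) for c in frame.columns],
            cell_ids=[str(i) for i in frame.index],
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.assay == other.assay
            and self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(
                np.where(self.mask, 0.0, self.values),
                np.where(other.mask, 0.0, other.values),
            )
        )


def validate_annotation(ann: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Check an annotation table and (optionally) its pairing with a matrix.

    Requires the columns in :data:`ANNOTATION_COLUMNS`; ``population`` and
    any extra columns are carried through untouched.  When ``matrix`` is
    given, every matrix cell must be annotated.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise InputError(f"annotation table lacks columns: {missing}")
    ids = ann["cell_id"].astype(str)
    if ids.duplicated().any():
        raise InputError("annotation table has duplicated cell_id entries")
    if matrix is not None:
        absent = set(matrix.cell_ids) - set(ids)
        if absent:
            raise InputError(f"cells without annotation: {sorted(absent)[:5]}...")
    return ann


def annotation_for(ann: pd.DataFrame, cells: Iterable[str]) -> pd.DataFrame:
    """Annotation rows for ``cells``, in that order."""
    indexed = ann.set_index(ann["cell_id"].astype(str))
    return indexed.loc[list(cells)].reset_index(drop=True)
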