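"""Reading, writing, normalization, QC and marker-positivity rules.

Expression matrices travel as delimited text (TSV by default, CSV by
extension): a header row of gene ids, a first column of cell ids, ``NA``
for missing entries.  The single-cell qPCR conventions implemented here:

* cells whose housekeeping Ct is absent or above a cutoff are removed
  (:func:`housekeeping_qc`),
* Ct values are normalized to the housekeeping mean via the 2^-dCt method
  (:func:`normalize_dct`),
* relative expression is rescaled to the mean of a reference cell set
  (:func:`rescale_to_reference`),
* cells are split into anchor-positive / anchor-negative populations by
  the Ct > 35 rule (qPCR) or the reads == 0 rule (RNA-seq)
  (:func:`split_by_anchor`),
* a dot-plot summary marks a cell positive for a gene when its value
  exceeds 0.10 x that gene's maximal intensity (:func:`dotplot_summary`).
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ASSAYS, ExpressionMatrix, validate_annotation
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

#: tokens interpreted as a missing entry on read
NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null"}

#: default housekeeping pair of the mouse qPCR panel
DEFAULT_HOUSEKEEPING = ("Rps17", "Rpl30")

#: Ct above this value (or an undetected transcript) calls a cell
#: anchor-negative
CT_NEGATIVE_THRESHOLD = 35.0

#: dot-plot positivity: value must exceed this fraction of the gene's
#: maximal intensity
DOTPLOT_POSITIVE_FRACTION = 0.10


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, assay: str) -> ExpressionMatrix:
    """Parse a delimited cells x genes table into an :class:`ExpressionMatrix`.

    The first header field is ignored (it labels the id column).  Raises
    :class:`FormatError` naming the offending row/column on ragged rows,
    duplicated ids or non-numeric entries.
    """
    path = Path(path)
    if assay not in ASSAYS:
        raise InputError(f"unknown assay {assay!r}")
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0][1:]]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise FormatError(f"{path}: duplicated gene ids in header: {dupes}")
    n_fields = len(rows[0])
    cell_ids: list[str] = []
    values = np.zeros((len(rows) - 1, len(header)))
    mask = np.zeros_like(values, dtype=bool)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n_fields:
            raise FormatError(
                f"{path}: row {r} has {len(row)} fields, expected {n_fields}"
            )
        cell_ids.append(row[0].strip())
        for c, token in enumerate(row[1:]):
            token = token.strip()
            if token in NA_TOKENS:
                mask[r - 2, c] = True
            else:
                try:
                    values[r - 2, c] = float(token)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {token!r} at row {r}, "
                        f"column {header[c]!r}"
                    ) from None
    if len(set(cell_ids)) != len(cell_ids):
        dupes = sorted({c for c in cell_ids if cell_ids.count(c) > 1})
        raise FormatError(f"{path}: duplicated cell ids: {dupes}")
    return ExpressionMatrix(values=values, mask=mask, assay=assay,
                            gene_ids=header, cell_ids=cell_ids)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as delimited text with ``NA`` for masked entries."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["cell_id", *m.gene_ids])
        for i, cid in enumerate(m.cell_ids):
            row: list[str] = [cid]
            for j in range(m.n_genes):
                row.append("NA" if m.mask[i, j] else repr(float(m.values[i, j])))
            writer.writerow(row)


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    ann = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    ann.to_csv(path, sep=_sep_for(path), index=False)


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column table (e.g. mouse_symbol, human_symbol) -> mapping dict.

    Symbol mapping is always explicit input; it is never inferred from
    capitalization.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Cells removed by housekeeping QC plus per-cell notes."""

    removed: list[str]
    max_ct: float
    notes: dict[str, str] = field(default_factory=dict)


def housekeeping_qc(
    m: ExpressionMatrix,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
    max_ct: float = 32.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove cells with absent or low housekeeping expression.

    A cell is removed when all housekeeping Cts are missing, or when the
    mean of its available housekeeping Cts exceeds ``max_ct``.  A cell
    with exactly one missing housekeeping value is kept on the strength
    of the remaining one and flagged in the log.

    Returns the filtered matrix and the removed cell ids.
    """
    if m.assay != "ct":
        raise InputError("housekeeping_qc applies to ct matrices")
    cols = [m.gene_index(g) for g in housekeeping]  # InputError if absent
    hk = m.values[:, cols].astype(float)
    hk_mask = m.mask[:, cols]
    removed: list[str] = []
    kept: list[str] = []
    for i, cid in enumerate(m.cell_ids):
        avail = ~hk_mask[i]
        if not avail.any():
            removed.append(cid)
            continue
        if avail.sum() < len(cols):
            logger.info("housekeeping_qc: cell %s has a missing housekeeping "
                        "value; using the mean of the available ones", cid)
        if hk[i, avail].mean() > max_ct:
            removed.append(cid)
        else:
            kept.append(cid)
    logger.info("housekeeping_qc: removed %d/%d cells (max_ct=%.3g)",
                len(removed), m.n_cells, max_ct)
    return m.subset(cells=kept), removed


def normalize_dct(
    m: ExpressionMatrix,
    housekeeping: Sequence[str] = DEFAULT_HOUSEKEEPING,
) -> ExpressionMatrix:
    """2^-dCt normalization to the mean of the housekeeping genes.

    Per cell, each gene's Ct is referenced to the mean housekeeping Ct:
    ``value = 2 ** -(Ct_gene - mean(Ct_housekeeping))``.  Masked inputs
    stay masked.  Housekeeping columns are retained but flagged so that
    downstream analyses skip them.
    """
    if m.assay != "ct":
        raise InputError("normalize_dct applies to ct matrices")
    cols = [m.gene_index(g) for g in housekeeping]
    hk = np.ma.masked_array(m.values[:, cols], mask=m.mask[:, cols])
    hk_mean = hk.mean(axis=1)  # per cell
    out = m.copy()
    no_ref = np.ma.getmaskarray(hk_mean)
    if no_ref.any():
        warnings.warn(
            "normalize_dct: cells without any housekeeping value are fully "
            "masked (run housekeeping_qc first)"
        )
    ref = np.where(no_ref, 0.0, hk_mean.filled(0.0))
    out.values = 2.0 ** -(m.values - ref[:, None])
    out.mask = m.mask | no_ref[:, None]
    out.assay = "normalized"
    out.flagged_genes |= set(housekeeping)
    return out


def rescale_to_reference(
    m: ExpressionMatrix, reference_cells: Sequence[str]
) -> ExpressionMatrix:
    """Divide each gene by its mean over a reference cell set.

    Masked entries are excluded from the reference mean.  A gene whose
    reference values are all masked (or whose mean is zero) is masked in
    the output with a warning.
    """
    if m.assay != "normalized":
        raise InputError("rescale_to_reference applies to normalized matrices")
    if not len(reference_cells):
        raise InputError("reference cell set is empty")
    ref = m.subset(cells=list(reference_cells))
    ref_vals = np.ma.masked_array(ref.values, mask=ref.mask)
    means = ref_vals.mean(axis=0)
    dead = np.ma.getmaskarray(means) | (means.filled(0.0) == 0.0)
    if dead.any():
        bad = [m.gene_ids[j] for j in np.flatnonzero(dead)]
        warnings.warn(f"rescale_to_reference: genes masked in output "
                      f"(no usable reference values): {bad}")
    denom = np.where(dead, 1.0, means.filled(1.0))
    out = m.copy()
    out.values = m.values / denom[None, :]
    out.mask = m.mask | dead[None, :]
    return out


def log2_transform(m: ExpressionMatrix, pseudo: float | None = None) -> ExpressionMatrix:
    """log2 transform for PCA input.

    ``counts`` use ``log2(x + 1)``; ``normalized`` values use a pseudo-floor
    for zeros, ``log2(max(x, pseudo))`` with ``pseudo = 2**-15`` by default.
    Rank-based statistics are invariant to this transform; it only matters
    for PCA and mean-level summaries.
    """
    out = m.copy()
    if m.assay == "counts":
        p = 1.0 if pseudo is None else pseudo
        out.values = np.log2(np.maximum(m.values, 0.0) + p)
    elif m.assay == "normalized":
        p = 2.0 ** -15 if pseudo is None else pseudo
        out.values = np.log2(np.maximum(m.values, p))
    else:
        raise InputError("log2_transform applies to counts or normalized matrices")
    out.values[out.mask] = 0.0
    out.assay = "normalized"
    return out


# ---------------------------------------------------------------------------
# marker positivity
# ---------------------------------------------------------------------------


@dataclass
class AnchorSplit:
    """Exhaustive, disjoint partition of cells by anchor-gene positivity."""

    anchor: str
    positive: list[str]
    negative: list[str]
    rule: str

    def is_positive(self) -> pd.Series:
        s = pd.Series(False, index=self.positive + self.negative, dtype=bool)
        s.loc[self.positive] = True
        return s


def split_by_anchor(m: ExpressionMatrix, anchor: str) -> AnchorSplit:
    """Partition cells into anchor-positive and anchor-negative.

    qPCR (``ct``): a cell is negative when its Ct exceeds 35 or the
    transcript is undetected (masked); all other cells are positive
    (Ct = 35.0 exactly is positive, the inequality is strict).
    RNA-seq (``counts``): a cell is negative when its normalized raw
    reads equal 0 (an undetected/masked entry also counts as negative).
    """
    if m.assay not in ("ct", "counts"):
        raise InputError(
            "split_by_anchor needs raw ct or counts values; the positivity "
            "rule is undefined for a 'normalized' matrix"
        )
    j = m.gene_index(anchor)
    vals = m.values[:, j]
    missing = m.mask[:, j]
    if m.assay == "ct":
        neg = missing | (vals > CT_NEGATIVE_THRESHOLD)
        rule = f"ct>{CT_NEGATIVE_THRESHOLD:g} or undetected"
    else:
        neg = missing | (vals == 0)
        rule = "reads==0"
    positive = [c for c, n in zip(m.cell_ids, neg) if not n]
    negative = [c for c, n in zip(m.cell_ids, neg) if n]
    return AnchorSplit(anchor=anchor, positive=positive, negative=negative, rule=rule)


def dotplot_summary(
    m: ExpressionMatrix,
    groups: Mapping[str, Sequence[str]],
    positive_fraction: float = DOTPLOT_POSITIVE_FRACTION,
) -> pd.DataFrame:
    """Per-gene, per-group mean expression and fraction of positive cells.

    A cell is positive for a gene when its value exceeds
    ``positive_fraction`` x the gene's maximal intensity over *all* cells.
    Returns a tidy frame with columns ``gene``, ``group``,
    ``mean_expression``, ``fraction_positive`` (NaN where every value in
    the group is masked).
    """
    if not groups or any(len(cells) == 0 for cells in groups.values()):
        raise InputError("dotplot_summary requires non-empty groups")
    vals = np.ma.masked_array(m.values, mask=m.mask)
    gene_max = vals.max(axis=0)  # masked where a gene is fully masked
    rows = []
    for name, cells in groups.items():
        sub = m.subset(cells=list(cells))
        sub_vals = np.ma.masked_array(sub.values, mask=sub.mask)
        for j, gene in enumerate(m.gene_ids):
            col = sub_vals[:, j]
            if col.mask.all() or np.ma.is_masked(gene_max[j]):
                rows.append((gene, name, np.nan, np.nan))
                continue
            thresh = positive_fraction * float(gene_max[j])
            positives = int(((col > thresh) & ~np.ma.getmaskarray(col)).sum())
            rows.append((gene, name, float(col.mean()), positives / len(cells)))
    return pd.DataFrame(rows, columns=["gene", "group", "mean_expression",
                                       "fraction_positive"])
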