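"""Anchor-gene correlation signatures and coordination summaries.

The operational definition of the epiblast state used throughout the
package: starting from an anchor gene (*Fgf4* in mouse, *FGF4* or *NANOG*
in human), every expressed gene is screened by Spearman correlation with
the anchor; genes passing an absolute-rho threshold form the signature.
Pairwise Spearman correlations among signature genes are discretized to
{-1, 0, 1} at the same threshold, ordered by hierarchical clustering, and
summarized by the *coordination fraction* -- the share of gene pairs with
a nonzero discretized correlation.  Coordinated (specified) populations
show a high fraction; progenitor populations sit near the chance level of
the threshold.

Spearman rho is computed from average-ranked data (pairwise-complete over
the missing-value mask) and its two-sided p-value from the t
approximation ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2``
degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, t as t_dist

from .containers import ExpressionMatrix
from .errors import InputError

logger = logging.getLogger(__name__)

#: published absolute-rho thresholds for the two corpus sizes analysed
#: in the source datasets (p <= 0.05 at those sample sizes)
PUBLISHED_RHO_THRESHOLDS = {40: 0.3, 33: 0.345}

#: a gene is "expressed" when at least this fraction of cells is
#: non-masked (and the observed values are not constant)
MIN_EXPRESSED_FRACTION = 0.25

MIN_COMPLETE_PAIRS = 4


@dataclass
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def _spearman_core(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """rho and two-sided t-approximate p on complete data (no NaN)."""
    n = x.size
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan, np.nan, n
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0, n
    stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * t_dist.sf(abs(stat), n - 2))
    return rho, p, n


def spearman(x, y) -> SpearmanResult:
    """Spearman correlation of two paired value vectors.

    NaN entries are dropped pairwise; at least 4 complete pairs are
    required.  A constant vector has no defined rank correlation: the
    result is returned as NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("spearman requires paired vectors of equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < MIN_COMPLETE_PAIRS:
        raise InputError(
            f"spearman needs >= {MIN_COMPLETE_PAIRS} complete pairs, "
            f"got {int(keep.sum())}"
        )
    rho, p, n = _spearman_core(x[keep], y[keep])
    if np.isnan(rho):
        warnings.warn("spearman: constant vector, rho undefined")
    return SpearmanResult(rho=rho, p_value=p, n=n)


def pairwise_spearman(m: ExpressionMatrix, genes: list[str] | None = None) -> np.ndarray:
    """Genes x genes Spearman rho matrix, pairwise-complete over the mask.

    Columns without masked entries are ranked once and correlated in a
    single pass; pairs touching masked entries fall back to per-pair
    computation.  Undefined correlations (constant data, too few pairs)
    are NaN.
    """
    if genes is not None:
        m = m.subset(genes=genes)
    vals = m.nan_values()
    n, g = vals.shape
    rho = np.full((g, g), np.nan)
    np.fill_diagonal(rho, 1.0)
    complete_cols = ~np.isnan(vals).any(axis=0)
    idx = np.flatnonzero(complete_cols)
    if idx.size >= 2:
        ranks = np.apply_along_axis(rankdata, 0, vals[:, idx])
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(ranks, rowvar=False)
        # constant columns give NaN rows/cols, which is what we want
        rho[np.ix_(idx, idx)] = sub
        np.fill_diagonal(rho, 1.0)
    incomplete = np.flatnonzero(~complete_cols)
    pairs = [(a, b) for a in range(g) for b in range(a + 1, g)
             if a in incomplete or b in incomplete]
    for a, b in pairs:
        xa, xb = vals[:, a], vals[:, b]
        keep = ~(np.isnan(xa) | np.isnan(xb))
        if keep.sum() < MIN_COMPLETE_PAIRS:
            continue
        r, _, _ = _spearman_core(xa[keep], xb[keep])
        rho[a, b] = rho[b, a] = r
    return rho


def threshold_for_n(n: int, mode: str = "published_table") -> float:
    """Absolute-rho threshold at which the two-sided p reaches 0.05.

    ``published_table`` returns the published thresholds for n = 40 (0.3) and
    n = 33 (0.345) and refuses other sample sizes.  ``t_approx`` returns
    the smallest rho on a 3-decimal grid whose two-sided t-approximate
    p-value is <= 0.05 (this differs from the published table at the
    third decimal; both conventions are exposed).  ``auto`` uses the
    table when listed, the t approximation otherwise.
    """
    if n < 5:
        raise InputError("threshold_for_n requires n >= 5")
    if mode == "auto":
        mode = "published_table" if n in PUBLISHED_RHO_THRESHOLDS else "t_approx"
    if mode == "published_table":
        if n not in PUBLISHED_RHO_THRESHOLDS:
            raise InputError(
                f"no published threshold for n={n}; use mode='t_approx'"
            )
        return PUBLISHED_RHO_THRESHOLDS[n]
    if mode != "t_approx":
        raise InputError(f"unknown mode {mode!r}")
    grid = np.round(np.arange(0.001, 1.0, 0.001), 3)
    stat = grid * np.sqrt((n - 2) / (1.0 - grid**2))
    p = 2.0 * t_dist.sf(stat, n - 2)
    ok = np.flatnonzero(p <= 0.05)
    return float(grid[ok[0]])


def discretize(rho: np.ndarray, threshold: float) -> np.ndarray:
    """Map a rho matrix to {-1, 0, 1}: 1 = correlated (rho >= threshold),
    -1 = anticorrelated (rho <= -threshold), 0 = no correlation.
    NaN (undefined) correlations map to 0; the diagonal is 1."""
    out = np.zeros_like(rho, dtype=int)
    with np.errstate(invalid="ignore"):
        out[rho >= threshold] = 1
        out[rho <= -threshold] = -1
    np.fill_diagonal(out, 1)
    return out


def _dendrogram_order(disc: np.ndarray) -> np.ndarray:
    """Hierarchical ordering of the discretized matrix rows
    (Euclidean distance, complete linkage); ties break by input order."""
    if disc.shape[0] < 2:
        return np.arange(disc.shape[0])
    if disc.shape[0] == 2:
        return np.arange(2)
    link = complete(pdist(disc.astype(float)))
    return np.asarray(leaves_list(link))


@dataclass
class SignatureResult:
    """An anchor-correlation signature over one cell population."""

    anchor: str | None
    n_cells: int
    rho_threshold: float
    #: (gene, rho, p, sign) for every gene passing |rho| >= threshold
    correlates: list[tuple[str, float, float, int]]
    #: genes listed in ``matrix_genes`` order
    matrix_genes: list[str] = field(default_factory=list)
    pairwise_rho: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    discretized: np.ndarray = field(default_factory=lambda: np.empty((0, 0), dtype=int))
    dendrogram_order: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def correlate_genes(self) -> list[str]:
        return [g for g, *_ in self.correlates]


def _expressed_genes(m: ExpressionMatrix, min_fraction: float) -> list[str]:
    vals = m.nan_values()
    keep = []
    for j, gene in enumerate(m.gene_ids):
        if gene in m.flagged_genes:
            continue
        col = vals[:, j]
        obs = col[~np.isnan(col)]
        if obs.size < max(MIN_COMPLETE_PAIRS, int(np.ceil(min_fraction * m.n_cells))):
            continue
        if np.nanmin(obs) == np.nanmax(obs):
            continue
        keep.append(gene)
    return keep


def build_signature(
    m: ExpressionMatrix,
    anchor: str,
    rho_threshold: float,
    min_expressed_fraction: float = MIN_EXPRESSED_FRACTION,
) -> SignatureResult:
    """Screen all expressed genes against the anchor and build the
    discretized co-expression matrix of the selected correlates.

    Genes that are all-masked, constant, or observed in fewer than
    ``min_expressed_fraction`` of cells are excluded (logged).  Selection
    uses the signed rho against a single absolute threshold; the sign of
    each correlate is recorded from its rho.  The pairwise matrix spans
    the anchor plus its correlates.
    """
    anchor_vals = m.gene_values(anchor)
    if (~np.isnan(anchor_vals)).sum() < MIN_COMPLETE_PAIRS:
        raise InputError(f"anchor {anchor!r} observed in fewer than "
                         f"{MIN_COMPLETE_PAIRS} cells")
    expressed = _expressed_genes(m, min_expressed_fraction)
    skipped = [g for g in m.gene_ids
               if g not in expressed and g not in m.flagged_genes and g != anchor]
    if skipped:
        logger.info("build_signature: %d genes excluded as not expressed: %s",
                    len(skipped), skipped[:10])
    if anchor not in expressed:
        raise InputError(f"anchor {anchor!r} is not an expressed gene")

    correlates: list[tuple[str, float, float, int]] = []
    for gene in expressed:
        if gene == anchor:
            continue
        try:
            res = spearman(anchor_vals, m.gene_values(gene))
        except InputError:
            continue
        if np.isnan(res.rho):
            continue
        if abs(res.rho) >= rho_threshold:
            correlates.append((gene, res.rho, res.p_value, 1 if res.rho >= 0 else -1))

    if len(correlates) < 2:
        warnings.warn(
            f"build_signature: anchor {anchor!r} has {len(correlates)} "
            "correlates; returning an empty matrix"
        )
        return SignatureResult(anchor=anchor, n_cells=m.n_cells,
                               rho_threshold=rho_threshold, correlates=correlates)

    genes = [anchor] + [g for g, *_ in correlates]
    rho = pairwise_spearman(m, genes=genes)
    disc = discretize(rho, rho_threshold)
    return SignatureResult(
        anchor=anchor,
        n_cells=m.n_cells,
        rho_threshold=rho_threshold,
        correlates=correlates,
        matrix_genes=genes,
        pairwise_rho=rho,
        discretized=disc,
        dendrogram_order=_dendrogram_order(disc),
    )


def transfer_signature(
    m_other: ExpressionMatrix,
    genes: list[str],
    rho_threshold_other: float,
    anchor: str | None = None,
) -> SignatureResult:
    """Recompute the pairwise discretized matrix of a fixed gene list on
    another population, at the threshold appropriate to its cell count.

    Genes absent from ``m_other`` are dropped with a warning.  Applied to
    the very matrix the genes were selected on, this reproduces the
    ``build_signature`` pairwise output.
    """
    present = [g for g in genes if g in m_other.gene_ids]
    dropped = [g for g in genes if g not in m_other.gene_ids]
    if dropped:
        warnings.warn(f"transfer_signature: {len(dropped)} genes absent from "
                      f"target matrix and dropped: {dropped[:10]}")
    if len(present) < 2:
        raise InputError("transfer_signature needs >= 2 transferable genes")
    rho = pairwise_spearman(m_other, genes=present)
    disc = discretize(rho, rho_threshold_other)
    return SignatureResult(
        anchor=anchor,
        n_cells=m_other.n_cells,
        rho_threshold=rho_threshold_other,
        correlates=[],
        matrix_genes=present,
        pairwise_rho=rho,
        discretized=disc,
        dendrogram_order=_dendrogram_order(disc),
    )


@dataclass
class CoordinationSummary:
    """Scalar coordination statistic of one (or a pair of) signature(s)."""

    fraction_significant_pairs: float
    n_pairs_tested: int
    cross_regime_delta: float | None = None


def coordination_fraction(sig: SignatureResult) -> CoordinationSummary:
    """Fraction of off-diagonal gene pairs whose discretized correlation
    is nonzero."""
    g = sig.discretized.shape[0]
    if g < 2:
        raise InputError("coordination_fraction requires a non-empty pairwise matrix")
    iu = np.triu_indices(g, k=1)
    nonzero = int((sig.discretized[iu] != 0).sum())
    return CoordinationSummary(
        fraction_significant_pairs=nonzero / len(iu[0]),
        n_pairs_tested=len(iu[0]),
    )


def compare_coordination(sig_a: SignatureResult, sig_b: SignatureResult) -> CoordinationSummary:
    """Coordination fraction of ``sig_a`` with the difference to
    ``sig_b`` recorded as ``cross_regime_delta`` (a - b)."""
    a = coordination_fraction(sig_a)
    b = coordination_fraction(sig_b)
    return CoordinationSummary(
        fraction_significant_pairs=a.fraction_significant_pairs,
        n_pairs_tested=a.n_pairs_tested,
        cross_regime_delta=a.fraction_significant_pairs - b.fraction_significant_pairs,
    )
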