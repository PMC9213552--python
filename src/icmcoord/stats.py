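"""Nonparametric group comparisons used across the analyses.

Thin, contract-enforcing wrappers over the scipy implementations, with a
recorded computation mode so small-sample exactness is auditable:

* :func:`wilcoxon_rank_sum` -- two-sided Wilcoxon-Mann-Whitney; exact
  enumeration when the combined sample is small and tie-free, otherwise
  the tie-corrected normal approximation (without continuity correction,
  so identical groups give p = 1 exactly),
* :func:`kruskal_wallis_with_pairwise` -- Kruskal-Wallis followed by
  pairwise Wilcoxon tests gated on the omnibus p-value (uncorrected by
  default; optional Holm adjustment, logged when enabled),
* :func:`fligner_killeen` -- rank-based homogeneity-of-variance test,
* :func:`boxplot_stats` -- quartiles (linear interpolation), median and
  1.5 x IQR whiskers matching the plotting convention used for all
  boxplot figures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    sidedness: str = "two_sided"
    mode: str = ""


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact enumeration of the U distribution when the combined sample has
    at most 12 tie-free values; continuity- and tie-corrected normal
    approximation otherwise (a U statistic exactly at the null center
    gives p = 1, as the two-sided tail there covers everything).  The
    mode used is recorded in the result.
    """
    a, b = _clean(a), _clean(b)
    if min(a.size, b.size) < 2:
        raise ValueError("wilcoxon_rank_sum needs >= 2 values per group")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MAX_N and not has_ties:
        mode = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        mode = "asymptotic_tie_corrected"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = 1.0 if res.statistic == a.size * b.size / 2.0 else float(res.pvalue)
    return TestResult(statistic=float(res.statistic), p_value=min(p, 1.0),
                      method="wilcoxon_rank_sum", n_per_group=(a.size, b.size),
                      mode=mode)


@dataclass
class KruskalWallisReport:
    omnibus: TestResult
    pairwise: dict[tuple[int, int], TestResult] = field(default_factory=dict)
    gate_alpha: float = 0.05
    holm_adjusted: bool = False


def kruskal_wallis_with_pairwise(
    groups,
    alpha: float = 0.05,
    holm: bool = False,
) -> KruskalWallisReport:
    """Kruskal-Wallis omnibus test with gated pairwise Wilcoxon follow-up.

    Pairwise tests run only when the omnibus p-value is <= ``alpha``
    (set ``alpha=1.0`` to always run them).  Pairwise p-values are
    reported uncorrected, mirroring the gated-comparison convention;
    ``holm=True`` applies a Holm adjustment instead (logged).
    """
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 3:
        raise ValueError("kruskal_wallis_with_pairwise needs >= 3 groups")
    if any(g.size < 2 for g in cleaned):
        raise ValueError("every group needs >= 2 values")
    if np.unique(np.concatenate(cleaned)).size == 1:
        omnibus = TestResult(statistic=0.0, p_value=1.0, method="kruskal_wallis",
                             n_per_group=tuple(g.size for g in cleaned),
                             mode="degenerate_constant")
    else:
        stat, p = sps.kruskal(*cleaned)
        omnibus = TestResult(statistic=float(stat), p_value=float(p),
                             method="kruskal_wallis",
                             n_per_group=tuple(g.size for g in cleaned),
                             mode="chi2_tie_corrected")
    report = KruskalWallisReport(omnibus=omnibus, gate_alpha=alpha, holm_adjusted=holm)
    if omnibus.p_value <= alpha:
        pairs = list(combinations(range(len(cleaned)), 2))
        results = {pair: wilcoxon_rank_sum(cleaned[pair[0]], cleaned[pair[1]])
                   for pair in pairs}
        if holm:
            logger.info("kruskal_wallis_with_pairwise: Holm adjustment enabled")
            from statsmodels.stats.multitest import multipletests

            raw = [results[p].p_value for p in pairs]
            adj = multipletests(raw, method="holm")[1]
            for pair, p_adj in zip(pairs, adj):
                r = results[pair]
                results[pair] = TestResult(
                    statistic=r.statistic, p_value=float(p_adj), method=r.method,
                    n_per_group=r.n_per_group, mode=r.mode + "+holm")
        report.pairwise = results
    return report


def fligner_killeen(a, b) -> TestResult:
    """Fligner-Killeen test for homogeneity of variance (two groups).

    Normal scores of the ranked absolute deviations from the group
    medians, chi-square p-value on 1 degree of freedom.  Constant pooled
    data has no dispersion to compare: statistic 0, p = 1, warning.
    """
    a, b = _clean(a), _clean(b)
    if min(a.size, b.size) < 3:
        raise ValueError("fligner_killeen needs >= 3 values per group")
    centered = np.concatenate([np.abs(a - np.median(a)), np.abs(b - np.median(b))])
    if np.unique(centered).size == 1:
        warnings.warn("fligner_killeen: no dispersion differences measurable "
                      "(constant absolute deviations); p=1")
        return TestResult(statistic=0.0, p_value=1.0, method="fligner_killeen",
                          n_per_group=(a.size, b.size), mode="degenerate_constant")
    stat, p = sps.fligner(a, b)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="fligner_killeen", n_per_group=(a.size, b.size),
                      mode="chi2_df1")


@dataclass
class BoxplotStats:
    """Summary convention of all boxplots: quartile box, median line,
    whiskers at the furthest points within 1.5 x IQR, the rest outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    quantile_method: str = "linear"  # type-7 interpolation


def boxplot_stats(values) -> BoxplotStats:
    v = _clean(values)
    if v.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    return BoxplotStats(
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_bound) | (v > hi_bound)]),
    )
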