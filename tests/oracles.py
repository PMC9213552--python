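"""Independent oracles used by the test suite.

Everything here is deliberately written through a different route than
the package code it checks: exhaustive enumeration for the exact tests,
direct textbook formulas for the rank statistics, and a stand-alone
Monte-Carlo simulation of the generator's marginal model for null
calibration.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


# -- Wilcoxon-Mann-Whitney: full enumeration --------------------------------

def wilcoxon_exact_p(a, b) -> float:
    """Two-sided exact p by enumerating all rank assignments (no ties).

    Counts assignments whose U statistic is at least as extreme (in
    either tail of the symmetric null distribution) as the observed one.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    n1, n2 = a.size, b.size
    order = np.argsort(pooled)
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, pooled.size + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    all_ranks = np.arange(1, pooled.size + 1)
    for subset in combinations(range(pooled.size), n1):
        u = all_ranks[list(subset)].sum() - n1 * (n1 + 1) / 2
        if u <= lo or u >= n1 * n2 - lo:
            count += 1
        total += 1
    return count / total


# -- Fisher exact: hypergeometric enumeration -------------------------------

def fisher_exact_p(table) -> float:
    """Two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    the observed table's (computed in exact rational arithmetic)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(k) <= p_obs:
            total += pmf(k)
    return float(total)


# -- Spearman: textbook rank formula + exact permutation null ---------------

def spearman_rho_oracle(x, y) -> float:
    """Pearson correlation of average ranks, via pandas ranking."""
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def spearman_exact_perm_p(x, y) -> float:
    """Exact two-sided permutation p of |rho| (n <= 7)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    obs = abs(spearman_rho_oracle(x, y))
    count = 0
    total = 0
    for perm in permutations(y):
        if abs(spearman_rho_oracle(x, np.array(perm))) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


# -- Fligner-Killeen: direct formula ----------------------------------------

def fligner_oracle(a, b) -> tuple[float, float]:
    """Normal scores of ranked absolute deviations from group medians;
    chi-square statistic on 1 df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    devs = np.concatenate([np.abs(a - np.median(a)), np.abs(b - np.median(b))])
    ranks = pd.Series(devs).rank().to_numpy()
    n = devs.size
    scores = norm.ppf(0.5 + ranks / (2.0 * (n + 1.0)))
    grand = scores.mean()
    v = ((scores - grand) ** 2).sum() / (n - 1)
    stat = 0.0
    sizes = (a.size, b.size)
    offsets = (0, a.size)
    for size, off in zip(sizes, offsets):
        stat += size * (scores[off:off + size].mean() - grand) ** 2 / v
    return float(stat), float(chi2.sf(stat, 1))


# -- Boxplot quartiles: direct type-7 formula -------------------------------

def quartiles_oracle(values) -> tuple[float, float, float]:
    v = np.sort(np.asarray(values, float))
    n = v.size

    def q(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


# -- null-calibration Monte Carlo -------------------------------------------

INDUCED_MU = -2.0
SIG_RANGE = (2.0, 5.0)
BG_RANGE = (1.0, 5.0)


def _marginal_panel(rng, n_cells, n_genes=36, n_sig=12, dropout=0.05,
                    missing=0.02):
    """One fully independent draw of the generator's marginal model,
    written independently of the package: log-normal levels, detection
    threshold at half a read, expression-dependent dropout, missing as
    NaN."""
    mu = np.empty(n_genes)
    mu[0] = INDUCED_MU
    mu[1:n_sig] = rng.uniform(*SIG_RANGE, size=n_sig - 1)
    mu[n_sig:] = rng.uniform(*BG_RANGE, size=n_genes - n_sig)
    z = mu[None, :] + rng.standard_normal((n_cells, n_genes))
    reads = 2.0 ** z
    x = np.where(reads < 0.5, 0.0, reads)
    x[rng.random(z.shape) < dropout * 2.0 ** (-np.maximum(z, 0.0))] = 0.0
    x[rng.random(z.shape) < missing] = np.nan
    return x


def null_pair_fraction(rng, n_cells, threshold=0.3, n_genes=36) -> float:
    """Fraction of gene pairs with |rho| >= threshold in one independent
    panel draw (pairwise-complete Spearman, re-ranked per pair)."""
    x = _marginal_panel(rng, n_cells, n_genes=n_genes)
    hits = 0
    n_pairs = 0
    for a in range(n_genes):
        for b in range(a + 1, n_genes):
            keep = ~(np.isnan(x[:, a]) | np.isnan(x[:, b]))
            n_pairs += 1
            if keep.sum() < 4:
                continue
            rho = spearman_rho_oracle(x[keep, a], x[keep, b])
            if not np.isnan(rho) and abs(rho) >= threshold:
                hits += 1
    return hits / n_pairs


def null_exceedance_mc(seed: int, n_cells: int, reps: int = 200,
                       threshold: float = 0.3) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, SE over reps) of the expected pair
    fraction exceeding the threshold under full independence, with the
    generator's marginal structure."""
    rng = np.random.default_rng(seed)
    fracs = [null_pair_fraction(rng, n_cells, threshold) for _ in range(reps)]
    fracs = np.asarray(fracs)
    return float(fracs.mean()), float(fracs.std(ddof=1) / np.sqrt(reps))


# -- adjusted Rand index: contingency formula -------------------------------

def ari_oracle(a, b) -> float:
    a = pd.factorize(np.asarray(a))[0]
    b = pd.factorize(np.asarray(b))[0]
    n = a.size
    cont = np.zeros((a.max() + 1, b.max() + 1))
    for i, j in zip(a, b):
        cont[i, j] += 1

    def c2(x):
        return x * (x - 1) / 2.0

    sum_ij = c2(cont).sum()
    sum_a = c2(cont.sum(axis=1)).sum()
    sum_b = c2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / c2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
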