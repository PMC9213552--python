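"""Consensus k-means, Fisher enrichment, and the human ICM staging rule.

``repeated_kmeans`` reruns k-means (k-means++ initialization) many times,
aligns every run's labels to the best run by exact bipartite matching,
and keeps the per-cell majority label; the mean agreement with that
consensus quantifies stability.  ``anchor_cluster_enrichment`` tests
whether anchor-positive cells concentrate in one of two clusters with a
two-sided Fisher exact test.  ``classify_human_icm`` implements the
nested classification of human blastocyst cells into TE, ICM progenitors
(ICMp) and differentiating ICM cells (ICMd): stage-1 k-means (k = 4) on
PCA coordinates, stage-2 k-means (k = 3) inside the progenitor cluster
to peel off residual TE cells, and removal of progenitor cells from
embryos in which no TE cell was identified (potential earlier embryos).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix
from .errors import InputError
from .io import AnchorSplit
from .pca import PCAResult

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Consensus labels of repeated k-means runs."""

    labels: np.ndarray
    k: int
    n_restarts: int
    consensus_agreement: float
    seed: int
    per_restart_labels: np.ndarray | None = None
    cell_ids: list[str] = field(default_factory=list)


def _align(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Permute ``labels`` to best overlap ``reference`` (exact matching)."""
    contingency = np.zeros((k, k))
    for a, b in zip(labels, reference):
        contingency[a, b] += 1
    rows, cols = linear_sum_assignment(-contingency)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm[labels]


def repeated_kmeans(
    points: np.ndarray,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    cell_ids: list[str] | None = None,
) -> ClusterResult:
    """Consensus clustering over ``n_restarts`` independently initialized
    k-means runs.

    Restart labelings are aligned to the run with the lowest
    within-cluster sum of squares; the consensus label is the per-cell
    majority and ``consensus_agreement`` the mean fraction of restarts
    agreeing with it.  All points identical is handled as a single
    cluster with a warning; fewer distinct points than ``k`` is an error.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    distinct = np.unique(points, axis=0).shape[0]
    if distinct == 1:
        warnings.warn("repeated_kmeans: all points identical; returning a "
                      "single cluster")
        return ClusterResult(labels=np.zeros(n, dtype=int), k=k,
                             n_restarts=n_restarts, consensus_agreement=1.0,
                             seed=seed, cell_ids=list(cell_ids or []))
    if distinct < k:
        raise InputError(f"k={k} exceeds the {distinct} distinct points")

    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2**31 - 1, size=n_restarts)
    all_labels = np.empty((n_restarts, n), dtype=int)
    inertias = np.empty(n_restarts)
    for r, state in enumerate(states):
        km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                    random_state=int(state)).fit(points)
        all_labels[r] = km.labels_
        inertias[r] = km.inertia_
    best = int(np.argmin(inertias))
    aligned = np.empty_like(all_labels)
    for r in range(n_restarts):
        aligned[r] = _align(all_labels[r], all_labels[best], k)
    # per-cell majority vote (ties break toward the smaller label)
    consensus = np.empty(n, dtype=int)
    for i in range(n):
        counts = np.bincount(aligned[:, i], minlength=k)
        consensus[i] = int(np.argmax(counts))
    agreement = float((aligned == consensus[None, :]).mean())
    return ClusterResult(labels=consensus, k=k, n_restarts=n_restarts,
                         consensus_agreement=agreement, seed=seed,
                         per_restart_labels=aligned,
                         cell_ids=list(cell_ids or []))


@dataclass
class EnrichmentResult:
    """2x2 Fisher exact test of cluster membership vs anchor positivity."""

    contingency: np.ndarray
    p_value: float
    odds_ratio: float
    odds_ratio_kind: str = "sample"


def anchor_cluster_enrichment(
    clusters: ClusterResult,
    split: AnchorSplit | np.ndarray,
) -> EnrichmentResult:
    """Two-sided Fisher exact test on the cluster x anchor+/- table.

    ``split`` is either an :class:`AnchorSplit` (matched through
    ``clusters.cell_ids``) or a boolean is-positive array aligned with
    the cluster labels.  The two-sided p sums all hypergeometric table
    probabilities not exceeding the observed one.  An empty margin gives
    p = 1 with a warning.
    """
    if clusters.k != 2:
        raise InputError("anchor_cluster_enrichment requires k=2 clusters")
    if isinstance(split, AnchorSplit):
        if not clusters.cell_ids:
            raise InputError("ClusterResult lacks cell_ids; pass a boolean array")
        pos = set(split.positive)
        missing = [c for c in clusters.cell_ids if c not in pos and c not in set(split.negative)]
        if missing:
            raise InputError(f"anchor partition does not cover cells: {missing[:5]}")
        is_positive = np.array([c in pos for c in clusters.cell_ids])
    else:
        is_positive = np.asarray(split, dtype=bool)
        if is_positive.shape[0] != clusters.labels.shape[0]:
            raise InputError("boolean split length does not match labels")
    table = np.zeros((2, 2), dtype=int)
    for lab, p in zip(clusters.labels, is_positive):
        table[lab, 0 if p else 1] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("anchor_cluster_enrichment: empty margin; p=1")
        return EnrichmentResult(contingency=table, p_value=1.0, odds_ratio=np.nan)
    odds, p = fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(contingency=table, p_value=float(p),
                            odds_ratio=float(odds))


# ---------------------------------------------------------------------------
# human ICM staging
# ---------------------------------------------------------------------------

HUMAN_LABELS = ("TE", "discarded_no_TE_embryo", "ICMp", "ICMd")


@dataclass
class HumanICMResult:
    """Per-cell stage labels plus the audit trail of the nested rule."""

    labels: pd.Series
    stage1: ClusterResult
    te_clusters_stage1: list[int]
    progenitor_cluster: int
    te_subclusters_stage2: list[int]
    discarded_no_te: list[str]
    log: list[str] = field(default_factory=list)


def _te_score(m: ExpressionMatrix, te_markers: list[str]) -> np.ndarray:
    """Per-cell mean log2(1 + x) over the TE markers (masked-aware)."""
    present = [g for g in te_markers if g in m.gene_ids]
    if not present:
        raise InputError(f"none of the TE markers {te_markers} are in the matrix")
    sub = m.subset(genes=present)
    vals = np.ma.masked_array(np.log2(1.0 + np.maximum(sub.values, 0.0)),
                              mask=sub.mask)
    return np.asarray(vals.mean(axis=1))


def _flag_te_clusters(
    labels: np.ndarray,
    cluster_ids: list[int],
    te_score: np.ndarray,
    margin: float,
    log: list[str],
    stage: str,
) -> list[int]:
    """Clusters whose mean TE score exceeds the all-cell mean by
    ``margin`` x the all-cell SD (strict) are flagged TE."""
    grand_mean = float(te_score.mean())
    grand_sd = float(te_score.std())
    flagged = []
    for c in cluster_ids:
        cells = labels == c
        if not cells.any():
            continue
        mean_c = float(te_score[cells].mean())
        if grand_sd > 0 and mean_c > grand_mean + margin * grand_sd:
            flagged.append(c)
            log.append(f"{stage}: cluster {c} flagged TE "
                       f"(mean score {mean_c:.2f} vs {grand_mean:.2f} "
                       f"+ {margin:g} x {grand_sd:.2f})")
    return flagged


def classify_human_icm(
    m: ExpressionMatrix,
    ann: pd.DataFrame,
    pca: PCAResult,
    te_markers: list[str],
    seed: int = 0,
    k_stage1: int = 4,
    k_stage2: int = 3,
    n_restarts: int = 100,
    te_margin: float = 1.0,
) -> HumanICMResult:
    """Nested k-means staging of human blastocyst cells.

    Stage 1: k-means (k = 4) on the PCA scores; clusters with elevated
    TE-marker expression (mean TE score above the all-cell mean by
    ``te_margin`` SD) are labelled TE.  The progenitor cluster is the
    non-TE cluster whose centroid lies closest to the origin of the
    (centered) score space; the remaining clusters are ICMd.  Stage 2:
    k-means (k = 3) inside the progenitor cluster discards TE-scoring
    sub-clusters.  Stage 3: progenitor cells from embryos without any
    TE-labelled cell are discarded as possible earlier embryos.  Every
    assignment and discard reason is logged.
    """
    if m.n_cells < k_stage1:
        raise InputError("fewer cells than stage-1 clusters")
    log: list[str] = []
    te_score = _te_score(m, te_markers)
    stage1 = repeated_kmeans(pca.scores, k=k_stage1, n_restarts=n_restarts,
                             seed=seed, cell_ids=list(m.cell_ids))
    te_clusters = _flag_te_clusters(stage1.labels, list(range(k_stage1)),
                                    te_score, te_margin, log, "stage1")
    if not te_clusters:
        warnings.warn("classify_human_icm: no TE cluster identified; all "
                      "cells pass to ICMp/ICMd")
        log.append("stage1: no cluster exceeded the TE-marker margin")

    non_te = [c for c in range(k_stage1) if c not in te_clusters]
    if not non_te:
        raise InputError("all stage-1 clusters flagged as TE")
    # progenitor cluster: non-TE centroid nearest the score-space origin
    norms = {c: float(np.linalg.norm(pca.scores[stage1.labels == c].mean(axis=0)))
             for c in non_te if (stage1.labels == c).any()}
    progenitor = min(norms, key=norms.get)
    log.append(f"stage1: progenitor cluster = {progenitor} "
               f"(centroid norms {norms})")

    labels = pd.Series("ICMd", index=list(m.cell_ids), dtype=object, name="label")
    for c in te_clusters:
        labels.iloc[np.flatnonzero(stage1.labels == c)] = "TE"

    prog_idx = np.flatnonzero(stage1.labels == progenitor)
    te_sub: list[int] = []
    if prog_idx.size >= k_stage2:
        sub_ids = [m.cell_ids[i] for i in prog_idx]
        stage2 = repeated_kmeans(pca.scores[prog_idx], k=k_stage2,
                                 n_restarts=n_restarts, seed=seed + 1,
                                 cell_ids=sub_ids)
        te_sub = _flag_te_clusters(stage2.labels, list(range(k_stage2)),
                                   te_score[prog_idx], te_margin, log, "stage2")
        for c in te_sub:
            for i in prog_idx[stage2.labels == c]:
                labels.iloc[i] = "TE"
    else:
        log.append("stage2: progenitor cluster too small to subcluster")
    for i in prog_idx:
        if labels.iloc[i] == "ICMd":
            labels.iloc[i] = "ICMp"

    # stage 3: discard progenitor cells from embryos without any TE cell;
    # meaningless when no TE cell was identified anywhere (vacuous markers)
    ann_idx = ann.set_index(ann["cell_id"].astype(str))
    embryo = ann_idx.loc[list(m.cell_ids), "embryo_id"].to_numpy()
    te_embryos = set(embryo[(labels == "TE").to_numpy()])
    discarded: list[str] = []
    if te_embryos:
        for i, cid in enumerate(m.cell_ids):
            if labels.iloc[i] == "ICMp" and embryo[i] not in te_embryos:
                labels.iloc[i] = "discarded_no_TE_embryo"
                discarded.append(cid)
    else:
        log.append("stage3: skipped (no TE cells identified in any embryo)")
    if discarded:
        log.append(f"stage3: discarded {len(discarded)} progenitor cells "
                   f"from embryos without TE cells")
    counts = labels.value_counts().to_dict()
    logger.info("classify_human_icm: %s", counts)
    log.append(f"label counts: {counts}")
    return HumanICMResult(labels=labels, stage1=stage1,
                          te_clusters_stage1=te_clusters,
                          progenitor_cluster=progenitor,
                          te_subclusters_stage2=te_sub,
                          discarded_no_te=discarded, log=log)


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two labelings (permutation-invariant)."""
    from sklearn.metrics import adjusted_rand_score

    a = pd.factorize(np.asarray(a))[0]
    b = pd.factorize(np.asarray(b))[0]
    return float(adjusted_rand_score(a, b))


# small exhaustive helper kept for k <= 4 diagnostics / tests
def best_label_permutation(labels: np.ndarray, reference: np.ndarray, k: int) -> np.ndarray:
    """Exhaustively search the label permutation maximizing agreement
    with ``reference`` (exact for any k, intended for k <= 4)."""
    best_perm, best_score = None, -1
    for perm in itertools.permutations(range(k)):
        mapped = np.array(perm)[labels]
        score = int((mapped == reference).sum())
        if score > best_score:
            best_perm, best_score = mapped, score
    return best_perm
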