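"""End-to-end stage analyses with config, logging and report bundles.

Two orchestrations mirror the two species' workflows:

* :func:`run_mouse_stage_analysis` -- per stage: (qPCR only)
  housekeeping QC and 2^-dCt normalization, log2 transform, PCA,
  anchor-positive/negative split, repeated k-means (k = 2) with Fisher
  enrichment; then the anchor-correlation signature at the latest stage,
  its transfer onto the earliest stage, and the coordination-fraction
  pair quantifying the random-to-coordinated transition.
* :func:`run_human_stage_analysis` -- PCA over the marker + TE-marker
  panel, nested TE/ICMp/ICMd staging, anchor signatures (FGF4- and
  NANOG-anchored) on ICMd cells, transfer onto ICMp, the overlap of the
  two anchor gene lists, and per-marker group tests.

A single YAML-loadable config drives both; species differences are data
(assay, panel), not code forks.  All randomness flows from one seed;
per-step sub-seeds are derived deterministically.  Reports carry a run
manifest recording every default actually used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (ClusterResult, EnrichmentResult, HumanICMResult,
                      anchor_cluster_enrichment, classify_human_icm,
                      repeated_kmeans)
from .containers import ExpressionMatrix, validate_annotation
from .coordination import (CoordinationSummary, SignatureResult,
                           build_signature, compare_coordination,
                           coordination_fraction, threshold_for_n,
                           transfer_signature)
from .errors import ConfigurationError, InputError
from .io import (DEFAULT_HOUSEKEEPING, housekeeping_qc, log2_transform,
                 normalize_dct, read_annotation, read_matrix, split_by_anchor,
                 write_matrix)
from .pca import PCAResult, fit_pca
from .simulate import HUMAN_TE_MARKERS
from .stats import TestResult, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


def _sub_seed(seed: int, step: str) -> int:
    """Deterministic per-step sub-seed (< 2**31)."""
    h = 0
    for ch in step:
        h = (h * 131 + ord(ch)) % 1_000_003
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31 - 1))


def resolve_threshold(n: int, mode) -> float:
    """A numeric mode is used verbatim; otherwise see
    :func:`icmcoord.coordination.threshold_for_n`."""
    if isinstance(mode, (int, float)) and not isinstance(mode, bool):
        return float(mode)
    return threshold_for_n(n, mode=str(mode))


@dataclass
class PipelineConfig:
    """Shared configuration for both species' pipelines."""

    assay: str = "counts"
    anchor: str = "Fgf4"
    housekeeping: tuple[str, str] = DEFAULT_HOUSEKEEPING
    qc_max_ct: float = 32.0
    rho_mode: object = "auto"          # "published_table" | "t_approx" | "auto" | float
    k: int = 2
    n_restarts: int = 100
    n_components: int = 2
    human_n_components: int = 3   # TE/ICMp/Epi/PrE need PC3 to separate
    pca_method: str = "ppca_em"
    seed: int = 0
    te_markers: list[str] = field(default_factory=lambda: list(HUMAN_TE_MARKERS))
    human_anchors: tuple[str, str] = ("FGF4", "NANOG")
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("pipeline config must set an explicit seed")
        return cls(**raw)

    def manifest(self) -> dict:
        d = asdict(self)
        d["package_version"] = __version__
        d["decisions"] = {
            "qc_missing_housekeeping": "mean over available housekeeping values",
            "anchor_negative_rule": "ct>35 or undetected; counts==0",
            "pca": "EM probabilistic PCA over masked entries (bpca-style)",
            "signature_selection": "signed rho, single absolute threshold, "
                                   "no multiple-testing correction",
            "dendrogram": "euclidean distance, complete linkage on the "
                          "discretized matrix rows",
            "te_cluster_rule": "mean TE-marker log score > all-cell mean "
                               "+ 1 SD (configurable margin)",
        }
        return d


@dataclass
class StageReport:
    name: str
    matrix: ExpressionMatrix
    pca: PCAResult
    clusters: ClusterResult
    enrichment: EnrichmentResult
    removed_by_qc: list[str] = field(default_factory=list)


@dataclass
class MouseReport:
    stages: dict[str, StageReport]
    signature: SignatureResult
    transfer: SignatureResult
    summary_late: CoordinationSummary
    summary_early: CoordinationSummary
    cross_regime: CoordinationSummary
    manifest: dict


def _load(matrix, assay: str) -> ExpressionMatrix:
    if isinstance(matrix, ExpressionMatrix):
        return matrix
    return read_matrix(matrix, assay=assay)


def _analyse_stage(name: str, m: ExpressionMatrix, config: PipelineConfig) -> StageReport:
    removed: list[str] = []
    raw = m
    if m.assay == "ct":
        m, removed = housekeeping_qc(m, config.housekeeping, max_ct=config.qc_max_ct)
        raw = m
        m = normalize_dct(m, config.housekeeping)
    if config.anchor not in raw.gene_ids:
        raise InputError(f"stage {name}: anchor gene {config.anchor!r} missing")
    logm = log2_transform(m)
    analysis_genes = [g for g in logm.gene_ids if g not in logm.flagged_genes]
    pca = fit_pca(logm.subset(genes=analysis_genes),
                  n_components=config.n_components, method=config.pca_method,
                  seed=_sub_seed(config.seed, f"pca:{name}"))
    split = split_by_anchor(raw, config.anchor)
    clusters = repeated_kmeans(pca.scores, k=config.k,
                               n_restarts=config.n_restarts,
                               seed=_sub_seed(config.seed, f"kmeans:{name}"),
                               cell_ids=list(raw.cell_ids))
    enrichment = anchor_cluster_enrichment(clusters, split)
    return StageReport(name=name, matrix=m, pca=pca, clusters=clusters,
                       enrichment=enrichment, removed_by_qc=removed)


def run_mouse_stage_analysis(
    stages: Mapping[str, ExpressionMatrix | str | Path],
    config: PipelineConfig,
) -> MouseReport:
    """Run the mouse workflow on >= 2 stage matrices.

    ``stages`` maps stage name -> matrix (or path), ordered from earliest
    to latest; the signature is built at the latest stage and transferred
    onto the earliest.  Any stage error aborts with a stage-named
    diagnostic.
    """
    if len(stages) < 2:
        raise InputError("run_mouse_stage_analysis needs matrices for >= 2 stages")
    reports: dict[str, StageReport] = {}
    for name, matrix in stages.items():
        try:
            reports[name] = _analyse_stage(name, _load(matrix, config.assay), config)
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc

    names = list(stages)
    early, late = names[0], names[-1]
    late_m = reports[late].matrix
    thr_late = resolve_threshold(late_m.n_cells, config.rho_mode)
    signature = build_signature(late_m, config.anchor, thr_late)
    early_m = reports[early].matrix
    thr_early = resolve_threshold(early_m.n_cells, config.rho_mode)
    genes = signature.matrix_genes or [config.anchor] + signature.correlate_genes
    transfer = transfer_signature(early_m, genes, thr_early, anchor=config.anchor)
    summary_late = coordination_fraction(signature)
    summary_early = coordination_fraction(transfer)
    cross = compare_coordination(signature, transfer)

    report = MouseReport(stages=reports, signature=signature, transfer=transfer,
                         summary_late=summary_late, summary_early=summary_early,
                         cross_regime=cross, manifest=config.manifest())
    if config.outdir:
        _write_mouse_report(report, config)
    return report


@dataclass
class HumanReport:
    staging: HumanICMResult
    pca: PCAResult
    signatures: dict[str, SignatureResult]
    transfers: dict[str, SignatureResult | None]
    summaries: dict[str, CoordinationSummary | None]
    anchor_overlap_fraction: float | None
    marker_tests: dict[str, TestResult]
    manifest: dict


def run_human_stage_analysis(
    matrix: ExpressionMatrix | str | Path,
    annotation: pd.DataFrame | str | Path,
    config: PipelineConfig,
) -> HumanReport:
    """Human workflow: stage cells into TE/ICMp/ICMd, build the FGF4- and
    NANOG-anchored signatures on ICMd cells, transfer them onto ICMp,
    report the overlap of the two anchor gene lists and per-marker
    FGF4+/FGF4- ICMd group tests."""
    m = _load(matrix, "counts")
    ann = annotation if isinstance(annotation, pd.DataFrame) else read_annotation(annotation)
    validate_annotation(ann, m)
    logm = log2_transform(m)
    pca = fit_pca(logm, n_components=config.human_n_components,
                  method=config.pca_method,
                  seed=_sub_seed(config.seed, "pca:human"))
    staging = classify_human_icm(m, ann, pca, te_markers=config.te_markers,
                                 seed=_sub_seed(config.seed, "kmeans:human"),
                                 n_restarts=config.n_restarts)
    icmd_cells = [c for c in m.cell_ids if staging.labels[c] == "ICMd"]
    icmp_cells = [c for c in m.cell_ids if staging.labels[c] == "ICMp"]
    if not icmp_cells:
        logger.warning("run_human_stage_analysis: no ICMp cells identified")
    icmd = m.subset(cells=icmd_cells)
    icmp = m.subset(cells=icmp_cells) if icmp_cells else None

    signatures: dict[str, SignatureResult] = {}
    transfers: dict[str, SignatureResult | None] = {}
    summaries: dict[str, CoordinationSummary | None] = {}
    # the published corpus uses |rho| >= 0.3 for the ICM populations
    thr = (config.rho_mode if isinstance(config.rho_mode, (int, float))
           and not isinstance(config.rho_mode, bool) else 0.3)
    for anchor in config.human_anchors:
        sig = build_signature(icmd, anchor, float(thr))
        signatures[anchor] = sig
        key_d, key_p = f"{anchor}_icmd", f"{anchor}_icmp"
        summaries[key_d] = (coordination_fraction(sig)
                            if sig.discretized.size else None)
        if icmp is not None and len(sig.matrix_genes) >= 2 and icmp.n_cells >= 4:
            tr = transfer_signature(icmp, sig.matrix_genes, float(thr), anchor=anchor)
            transfers[anchor] = tr
            summaries[key_p] = coordination_fraction(tr)
        else:
            transfers[anchor] = None
            summaries[key_p] = None

    a0, a1 = config.human_anchors
    set0 = set(signatures[a0].correlate_genes)
    set1 = set(signatures[a1].correlate_genes)
    overlap = len(set0 & set1) / len(set0) if set0 else None

    # per-marker expression tests: FGF4+ vs FGF4- within ICMd
    marker_tests: dict[str, TestResult] = {}
    if icmd.n_cells >= 4:
        split = split_by_anchor(icmd, a0)
        if len(split.positive) >= 2 and len(split.negative) >= 2:
            pos = icmd.subset(cells=split.positive)
            neg = icmd.subset(cells=split.negative)
            for gene in m.gene_ids:
                x = pos.gene_values(gene)
                y = neg.gene_values(gene)
                try:
                    marker_tests[gene] = wilcoxon_rank_sum(x, y)
                except ValueError:
                    continue

    report = HumanReport(staging=staging, pca=pca, signatures=signatures,
                         transfers=transfers, summaries=summaries,
                         anchor_overlap_fraction=overlap,
                         marker_tests=marker_tests, manifest=config.manifest())
    if config.outdir:
        _write_human_report(report, config)
    return report


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------


def _signature_frames(sig: SignatureResult) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    correlates = pd.DataFrame(sig.correlates, columns=["gene", "rho", "p", "sign"])
    genes = sig.matrix_genes
    rho = pd.DataFrame(sig.pairwise_rho, index=genes, columns=genes)
    disc = pd.DataFrame(sig.discretized, index=genes, columns=genes)
    return correlates, rho, disc


def _dump_signature(sig: SignatureResult, outdir: Path, prefix: str) -> None:
    correlates, rho, disc = _signature_frames(sig)
    correlates.to_csv(outdir / f"{prefix}_correlates.tsv", sep="\t", index=False)
    rho.to_csv(outdir / f"{prefix}_pairwise_rho.tsv", sep="\t")
    disc.to_csv(outdir / f"{prefix}_discretized.tsv", sep="\t")


def _summary_dict(s: CoordinationSummary | None) -> dict | None:
    return None if s is None else {
        "fraction_significant_pairs": s.fraction_significant_pairs,
        "n_pairs_tested": s.n_pairs_tested,
        "cross_regime_delta": s.cross_regime_delta,
    }


def _write_mouse_report(report: MouseReport, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, st in report.stages.items():
        pd.DataFrame(st.pca.scores, index=st.pca.cell_ids,
                     columns=[f"PC{i + 1}" for i in range(st.pca.n_components)]
                     ).to_csv(outdir / f"{name}_scores.tsv", sep="\t")
        pd.Series(st.clusters.labels, index=st.clusters.cell_ids, name="cluster"
                  ).to_csv(outdir / f"{name}_clusters.tsv", sep="\t")
        write_matrix(st.matrix, outdir / f"{name}_normalized.tsv")
    _dump_signature(report.signature, outdir, "signature")
    _dump_signature(report.transfer, outdir, "transfer")
    payload = {
        "enrichment": {
            name: {"p_value": st.enrichment.p_value,
                   "odds_ratio": st.enrichment.odds_ratio,
                   "contingency": st.enrichment.contingency.tolist()}
            for name, st in report.stages.items()
        },
        "coordination": {
            "late": _summary_dict(report.summary_late),
            "early": _summary_dict(report.summary_early),
            "cross_regime_delta": report.cross_regime.cross_regime_delta,
        },
        "explained_fraction": {
            name: st.pca.explained_fraction.tolist()
            for name, st in report.stages.items()
        },
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2,
                                                     sort_keys=True, default=str))


def _write_human_report(report: HumanReport, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.staging.labels.rename_axis("cell_id").to_csv(
        outdir / "human_labels.tsv", sep="\t")
    for anchor, sig in report.signatures.items():
        _dump_signature(sig, outdir, f"icmd_{anchor}")
    for anchor, tr in report.transfers.items():
        if tr is not None:
            _dump_signature(tr, outdir, f"icmp_{anchor}")
    payload = {
        "label_counts": report.staging.labels.value_counts().to_dict(),
        "anchor_overlap_fraction": report.anchor_overlap_fraction,
        "coordination": {k: _summary_dict(v) for k, v in report.summaries.items()},
        "marker_tests": {g: {"p_value": t.p_value, "mode": t.mode}
                         for g, t in report.marker_tests.items()},
        "staging_log": report.staging.log,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2,
                                                     sort_keys=True, default=str))
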