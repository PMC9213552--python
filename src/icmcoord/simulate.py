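"""Synthetic single-cell expression data with a controllable coordination
structure.

Two regimes emulate the two ICM heterogeneity states:

``independent``
    every gene fluctuates independently across cells (the "primary
    heterogeneity" of unspecified progenitors),
``coordinated``
    a latent binary cell state (Epi-initiated vs not) shifts all
    signature genes jointly, producing the coordinated, salt-and-pepper
    expression of a specified epiblast.

The expression model is a per-gene log-normal latent level: gene *g* in
cell *i* has log2-level ``z = mu_g + delta * s_i * [g in signature] + eps``
with unit-SD noise, latent state ``s_i ~ Bernoulli(latent_positive_fraction)``
and coupling ``delta`` in SD units.  The assay boundary then encodes
dropout exactly where the downstream positivity rules look for it:

* ``counts``: normalized reads ``2**z`` with a detection threshold --
  levels below half a read give exactly 0, as in normalized scRNA-seq
  count tables; technical dropout zeroes an entry,
* ``ct``: ``Ct = 34 - z`` (one qPCR cycle per log2 unit, clipped to
  [10, 40], placing the detection boundary Ct 35 one cycle below the
  induced gene's on-state mode); dropout is recorded as Ct 40 (> 35,
  hence anchor-negative), and two housekeeping genes are appended.

Baselines mirror the two kinds of signature gene seen in vivo: the
first signature gene is an *induced* marker (like *Fgf4*) sitting at the
detection limit (log2 mean -2), so positivity is rare before coupling
and common in latent-positive cells; the remaining signature genes are
*expressed* pluripotency factors (log2 mean uniform on [2, 5]) whose
levels become coordinated without switching on or off.  Background
genes draw their baseline from [1, 5].  Technical dropout is
expression-dependent -- the per-entry probability is ``dropout_rate``
at or below the detection level and halves per log2 unit above it --
so abundant transcripts essentially never drop out.  Missing entries
(failed reactions) are masked at rate ``missing_rate`` independently of
value.

A separate generator builds human-like blastocyst mixtures of TE, ICM
progenitor (ICMp), Epi-like and PrE-like cells over the marker panel
plus TE markers, including whole embryos lacking TE cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix
from .errors import ConfigurationError
from .io import write_annotation, write_matrix

logger = logging.getLogger(__name__)

# -- gene panels ------------------------------------------------------------
# A synthetic stand-in for a 36-gene qPCR panel: 12 Epi/pluripotency
# signature genes (anchored on Fgf4) and 24 background genes covering PrE,
# FGF-pathway and early markers.  Panel membership is a configuration
# input for real data; this list only names the simulated genes.

EPI_SIGNATURE_GENES = [
    "Fgf4", "Nanog", "Sox2", "Prdm14", "Klf2", "Klf4",
    "Tdgf1", "Sox21", "Bmp4", "Zfp42", "Esrrb", "Enox1",
]

BACKGROUND_GENES = [
    "Gata6", "Gata4", "Sox17", "Pdgfra", "Foxq1", "Fgfr2",
    "Dab2", "Lrpap1", "Zscan4", "Tcfcp2l1", "Pou5f1", "Pecam1",
    "Lats2", "Socs3", "Zfp281", "Carm1", "Fgfr1", "Sox7",
    "Cubn", "Aqp3", "Id2", "Hnf4a", "Serpinh1", "Dppa1",
]

MOUSE_PANEL = EPI_SIGNATURE_GENES + BACKGROUND_GENES

HOUSEKEEPING_GENES = ["Rps17", "Rpl30"]

#: human orthologue panel (identity mapping by capitalization is used only
#: for these synthetic names; real data take an explicit ortholog table)
HUMAN_PANEL = [g.upper() for g in MOUSE_PANEL]

HUMAN_TE_MARKERS = ["TACSTD2", "ENPEP", "ABCG2", "GATA2", "GATA3"]

HUMAN_EPI_MARKERS = [g.upper() for g in EPI_SIGNATURE_GENES]
HUMAN_PRE_MARKERS = ["GATA6", "GATA4", "SOX17", "PDGFRA", "FOXQ1", "FGFR2",
                     "DAB2", "LRPAP1", "SOX7", "CUBN", "HNF4A"]

#: baseline log2 mean of the induced (anchor-like) signature gene,
#: near the detection limit
INDUCED_BASELINE_LOG2 = -2.0

#: baseline log2-mean range of the expressed signature genes
SIGNATURE_LOG2_RANGE = (2.0, 5.0)

#: baseline log2-mean range of background genes
BACKGROUND_LOG2_RANGE = (1.0, 5.0)

#: normalized reads below this level are recorded as 0 (undetected)
COUNTS_DETECTION_THRESHOLD = 0.5

#: Ct mapping: Ct = CT_INTERCEPT - log2 level, clipped to CT_RANGE
CT_INTERCEPT = 34.0
CT_RANGE = (10.0, 40.0)
CT_DROPOUT = 40.0


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class RegimeConfig:
    """Parameters for one simulated stage/genotype.

    ``coupling_effect`` is the standardized mean shift (in noise-SD units)
    applied to signature genes in latent-positive cells; the coordinated
    regime with ``coupling_effect=0`` is bit-identical to the independent
    regime under the same seed.
    """

    n_cells: int = 40
    n_genes: int = 36
    n_signature_genes: int = 12
    regime: str = "coordinated"
    coupling_effect: float = 2.0
    latent_positive_fraction: float = 0.4
    dropout_rate: float = 0.05
    missing_rate: float = 0.02
    assay: str = "counts"
    housekeeping_mean_ct: float = 18.0
    seed: int = 0
    stage: str = "32C"
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.regime not in ("independent", "coordinated"):
            raise ConfigurationError(
                f"regime must be 'independent' or 'coordinated', got {self.regime!r}"
            )
        if self.assay not in ("ct", "counts"):
            raise ConfigurationError(f"assay must be 'ct' or 'counts', got {self.assay!r}")
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes cannot exceed n_genes")
        if min(self.n_cells, self.n_genes, self.n_signature_genes) < 1:
            raise ConfigurationError("counts must be positive")
        for name in ("latent_positive_fraction", "dropout_rate", "missing_rate"):
            _check_prob(name, getattr(self, name))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegimeConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _panel_for(config: RegimeConfig) -> tuple[list[str], list[str]]:
    """Gene names: signature genes first, then background."""
    sig = [EPI_SIGNATURE_GENES[i] if i < len(EPI_SIGNATURE_GENES) else f"Sig{i + 1:02d}"
           for i in range(config.n_signature_genes)]
    n_bg = config.n_genes - config.n_signature_genes
    bg = [BACKGROUND_GENES[i] if i < len(BACKGROUND_GENES) else f"Bg{i + 1:02d}"
          for i in range(n_bg)]
    return sig, bg


def simulate_regime(config: RegimeConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one expression matrix plus its cell annotation.

    The annotation records the latent binary state (``latent_state``,
    0/1) whether or not the regime couples to it, alongside stage,
    genotype and a per-cell embryo id (cells are i.i.d.; embryo ids are
    bookkeeping only).  Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    sig_genes, bg_genes = _panel_for(config)
    genes = sig_genes + bg_genes
    n, g = config.n_cells, config.n_genes
    n_sig = config.n_signature_genes

    mu = np.empty(g)
    mu[0] = INDUCED_BASELINE_LOG2
    if n_sig > 1:
        mu[1:n_sig] = rng.uniform(*SIGNATURE_LOG2_RANGE, size=n_sig - 1)
    mu[n_sig:] = rng.uniform(*BACKGROUND_LOG2_RANGE, size=g - n_sig)

    latent = rng.random(n) < config.latent_positive_fraction
    shift = config.coupling_effect if config.regime == "coordinated" else 0.0
    z = mu[None, :] + rng.standard_normal((n, g))
    z[:, :n_sig] += shift * latent[:, None]

    # expression-dependent technical dropout: full rate at/below the
    # detection level, halving per log2 unit above it
    p_drop = config.dropout_rate * 2.0 ** (-np.maximum(z, 0.0))
    dropout = rng.random((n, g)) < p_drop
    missing = rng.random((n, g)) < config.missing_rate

    if config.assay == "counts":
        reads = 2.0 ** z
        values = np.where(reads < COUNTS_DETECTION_THRESHOLD, 0.0, reads)
        values[dropout] = 0.0
        gene_ids = genes
        mask = missing
    else:
        ct = np.clip(CT_INTERCEPT - z, *CT_RANGE)
        ct[dropout] = CT_DROPOUT
        hk = np.clip(
            config.housekeeping_mean_ct + 0.5 * rng.standard_normal((n, 2)),
            *CT_RANGE,
        )
        hk_missing = rng.random((n, 2)) < config.missing_rate
        values = np.hstack([ct, hk])
        mask = np.hstack([missing, hk_missing])
        gene_ids = genes + HOUSEKEEPING_GENES

    values = values.astype(float)
    values[mask] = 0.0
    cell_ids = [f"cell{i + 1:03d}" for i in range(n)]
    matrix = ExpressionMatrix(values=values, mask=mask, assay=config.assay,
                              gene_ids=list(gene_ids), cell_ids=cell_ids)
    ann = pd.DataFrame({
        "cell_id": cell_ids,
        "stage": config.stage,
        "genotype": config.genotype,
        "embryo_id": [f"embryo{1 + i // 10:02d}" for i in range(n)],
        "population": np.where(latent, "latent_pos", "latent_neg"),
        "latent_state": latent.astype(int),
    })
    logger.info("simulate_regime: %s regime, %d cells x %d genes, seed=%d",
                config.regime, n, g, config.seed)
    return matrix, ann


# ---------------------------------------------------------------------------
# human-like blastocyst mixtures
# ---------------------------------------------------------------------------

POPULATION_LABELS = ("TE", "ICMp", "Epi", "PrE")


@dataclass
class PopulationSpec:
    """One cell population: label, cells per embryo, marker shift.

    ``marker_shift`` maps gene -> additive log2 shift applied on top of
    the shared per-gene baseline.
    """

    label: str
    n_per_embryo: int
    marker_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in POPULATION_LABELS:
            raise ConfigurationError(
                f"population label {self.label!r} not in {POPULATION_LABELS}"
            )
        if self.n_per_embryo < 0:
            raise ConfigurationError("population counts must be >= 0")


def default_human_populations(separation: float = 3.0) -> list[PopulationSpec]:
    """TE / ICMp / Epi / PrE populations with marker shifts of
    ``separation`` log2 units on the respective lineage markers; ICMp is
    the unshifted baseline cloud."""
    return [
        PopulationSpec("TE", 3, {m: separation for m in HUMAN_TE_MARKERS}),
        PopulationSpec("ICMp", 2, {}),
        PopulationSpec("Epi", 2, {m: separation for m in HUMAN_EPI_MARKERS}),
        PopulationSpec("PrE", 2, {m: separation for m in HUMAN_PRE_MARKERS}),
    ]


@dataclass
class HumanMixtureConfig:
    """A corpus of blastocysts sampled at E5-E7.

    ``fraction_embryos_without_te`` embryos (rounded to the nearest
    integer count) contribute no TE cells, mimicking earlier embryos in
    which the TE/ICM split is not yet resolved.
    """

    n_embryos: int = 54
    populations: list[PopulationSpec] = field(default_factory=default_human_populations)
    fraction_embryos_without_te: float = 0.13
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ConfigurationError("population list is empty")
        if self.n_embryos < 1:
            raise ConfigurationError("n_embryos must be positive")
        _check_prob("fraction_embryos_without_te", self.fraction_embryos_without_te)
        _check_prob("dropout_rate", self.dropout_rate)


def simulate_human_mixture(
    config: HumanMixtureConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Counts matrix over the 36-marker + TE-marker panel with true labels.

    Embryos flagged TE-less contain no TE-labelled cells; every cell's
    true population and embryo id are recorded in the annotation.
    """
    rng = np.random.default_rng(config.seed)
    genes = HUMAN_PANEL + HUMAN_TE_MARKERS
    gene_pos = {g: j for j, g in enumerate(genes)}
    baseline = rng.uniform(1.0, 4.0, size=len(genes))

    n_no_te = int(round(config.fraction_embryos_without_te * config.n_embryos))
    no_te = np.zeros(config.n_embryos, dtype=bool)
    no_te[rng.choice(config.n_embryos, size=n_no_te, replace=False)] = True

    stages = rng.choice(["E5", "E6", "E7"], size=config.n_embryos)

    rows, labels, embryos, cell_stages = [], [], [], []
    for e in range(config.n_embryos):
        eid = f"hembryo{e + 1:02d}"
        for pop in config.populations:
            if pop.label == "TE" and no_te[e]:
                continue
            shift = np.zeros(len(genes))
            for gene, delta in pop.marker_shift.items():
                if gene in gene_pos:
                    shift[gene_pos[gene]] = delta
            z = baseline + shift + rng.standard_normal((pop.n_per_embryo, len(genes)))
            reads = 2.0 ** z
            counts = np.where(reads < COUNTS_DETECTION_THRESHOLD, 0.0, reads)
            # same expression-dependent dropout model as simulate_regime
            p_drop = config.dropout_rate * 2.0 ** (-np.maximum(z, 0.0))
            counts[rng.random(counts.shape) < p_drop] = 0.0
            rows.append(counts)
            labels += [pop.label] * pop.n_per_embryo
            embryos += [eid] * pop.n_per_embryo
            cell_stages += [stages[e]] * pop.n_per_embryo

    values = np.vstack(rows)
    cell_ids = [f"hcell{i + 1:03d}" for i in range(values.shape[0])]
    matrix = ExpressionMatrix(values=values, mask=np.zeros_like(values, dtype=bool),
                              assay="counts", gene_ids=list(genes), cell_ids=cell_ids)
    ann = pd.DataFrame({
        "cell_id": cell_ids,
        "stage": cell_stages,
        "genotype": "WT",
        "embryo_id": embryos,
        "population": labels,
    })
    logger.info("simulate_human_mixture: %d cells from %d embryos (%d without TE)",
                len(cell_ids), config.n_embryos, n_no_te)
    return matrix, ann


def write_simulation(
    matrix: ExpressionMatrix,
    ann: pd.DataFrame,
    outdir: str | Path,
    prefix: str = "sim",
    seed: int | None = None,
) -> None:
    """Write matrix + annotation TSVs (and log the seed used)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(matrix, outdir / f"{prefix}_matrix.tsv")
    write_annotation(ann, outdir / f"{prefix}_annotation.tsv")
    if seed is not None:
        logger.info("write_simulation: seed=%d -> %s", seed, outdir)
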