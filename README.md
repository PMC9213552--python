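# icmcoord

Expression-coordination analysis of inner-cell-mass (ICM) progenitor and
epiblast cells in preimplantation embryos.

## The problem

Before the blastocyst's ICM resolves into epiblast (Epi) and primitive
endoderm (PrE), its cells express pluripotency genes — *Nanog*, *Sox2*,
*Klf4*, *Prdm14*, *Fgf4*, ... — with strong cell-to-cell variability. Two
different kinds of heterogeneity hide under that variability:

* **primary heterogeneity** — each gene fluctuates independently from cell
  to cell; no lineage has been chosen (unspecified ICM progenitors);
* **coordinated heterogeneity** — pluripotency genes co-vary in the same
  cells, the classic "salt-and-pepper" signature of specified Epi cells.

The two states are indistinguishable gene-by-gene; they differ only in the
*correlation structure* across cells. `icmcoord` implements the pipeline
that separates them, for single-cell RT-qPCR (Biomark-style Ct matrices)
and for single-cell RNA-seq count matrices, in mouse and human.

## The statistic at its core

Given a cells × genes matrix **X** and an anchor gene *a* (*Fgf4* in mouse;
*FGF4* or *NANOG* in human), every expressed gene *g* is screened by
Spearman correlation ρ(a, g) computed pairwise-complete over missing
values, with the two-sided p from t = ρ√((n−2)/(1−ρ²)) on n−2 df. Genes
with |ρ| ≥ ρ\* form the anchor signature (ρ\* = 0.3 at n = 40 cells, 0.345
at n = 33, or by a t-grid for other n). Pairwise correlations among the
signature genes are discretized,

  D(g, h) = 1 if ρ ≥ ρ\*, −1 if ρ ≤ −ρ\*, 0 otherwise,

ordered by hierarchical clustering (Euclidean distance, complete linkage),
and summarized by the **coordination fraction** — the share of off-diagonal
pairs with D ≠ 0. Transferred to another population (e.g. the 16C stage, or
human ICM progenitors) the same gene list scores near the chance level of
the threshold when expression is uncoordinated; the difference between the
two fractions (`cross_regime_delta`) quantifies the random→coordinated
transition that marks Epi specification.

Around this core the package provides: 2^−ΔCt normalization with
housekeeping QC, the Ct > 35 / reads == 0 anchor-positivity rules, EM
probabilistic PCA tolerant of missing values, repeated k-means consensus
clustering with Fisher-exact enrichment of anchor-positive cells, the
nested TE/ICMp/ICMd staging of human blastocyst cells, the nonparametric
group tests used throughout (Wilcoxon–Mann–Whitney, Kruskal–Wallis with
gated pairwise follow-up, Fligner–Killeen), and a synthetic-data generator
producing both regimes with realistic dropout for all of the above.

## Worked example

Simulate a coordinated "32C-like" stage and an independent "16C-like"
stage, then run the mouse workflow:

```python
from icmcoord import (PipelineConfig, RegimeConfig,
                      run_mouse_stage_analysis, simulate_regime)

late, _  = simulate_regime(RegimeConfig(seed=101, regime="coordinated", stage="32C"))
early, _ = simulate_regime(RegimeConfig(seed=102, regime="independent",  stage="16C"))
config = PipelineConfig(assay="counts", anchor="Fgf4", seed=5, rho_mode=0.3)
report = run_mouse_stage_analysis({"16C": early, "32C": late}, config)
```

Printing the headline numbers:

```
signature: 11 Fgf4 correlates at |rho| >= 0.3
coordination fraction 32C: 0.545 (66 pairs)
coordination fraction 16C: 0.076
cross-regime delta: 0.470
Fisher Fgf4+/- vs clusters at 16C: p = 0.186
Fisher Fgf4+/- vs clusters at 32C: p = 0.0003
```

Reading: at the coordinated stage the anchor recovers a signature whose
pairwise correlations are dense (54.5% of pairs significant), while the
same genes transferred onto the independent stage correlate at roughly the
6–8% chance rate of the |ρ| ≥ 0.3 threshold — the coordination fraction
collapses by 0.47. Likewise, k-means clusters of the PCA map align with
*Fgf4* positivity only at the coordinated stage (Fisher p = 3 × 10⁻⁴ vs
0.19). That asymmetry — same genes, same thresholds, different correlation
structure — is the operational definition of Epi specification.

The same analyses are scriptable from the shell:

```bash
icmcoord simulate out/ --kind regime --seed 3
icmcoord signature out/regime_matrix.tsv out/sig --anchor Fgf4 --threshold 0.3
icmcoord cluster out/regime_matrix.tsv out/clusters.tsv --anchor Fgf4 --seed 3
```

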