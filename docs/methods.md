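# Methods

## The coordination model

`icmcoord` treats epiblast specification as a change in the joint
distribution of pluripotency-gene expression across cells, not in the
marginals. In the *independent* (progenitor) state, gene levels vary from
cell to cell without covariation. In the *coordinated* (specified) state,
a binary latent cell state — "Epi-initiated" or not — shifts a set of
signature genes jointly, so their pairwise correlations become strong and
positive while everything else is unchanged. All detection machinery in
the package is rank-based, so it is invariant to monotone transforms of
expression (2^−ΔCt vs Ct, raw vs log counts) and only sensitive to this
joint structure.

### Spearman machinery

Pairwise Spearman ρ is computed from average-ranked data on the
pairwise-complete subset of cells (masked entries dropped per pair; at
least 4 complete pairs required). Two-sided p-values use the t
approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df. Signature selection applies
a single absolute threshold to the signed ρ; no multiple-testing
correction is applied in the anchor scan (an optional BH/Holm path exists
for the group tests and is logged when used). Two threshold conventions
are exposed: the published lookup values (0.3 at n = 40, 0.345 at n = 33)
and a t-grid root (`t_approx`) that returns the smallest 3-decimal ρ with
p ≤ 0.05 — the two disagree in the third decimal (the t grid gives 0.312
at n = 40 and 0.344 at n = 33) and no attempt is made to reconcile them;
callers choose the convention.

The discretization {−1, 0, 1} at the same threshold, the hierarchical
ordering of the discretized matrix (Euclidean distance on rows, complete
linkage, ties broken by input order), and the coordination fraction
(share of off-diagonal pairs with a nonzero discretized value) are as
described in the README. Undefined correlations (constant genes, too few
complete pairs) discretize to 0, which biases the fraction conservatively
toward "no coordination".

## Synthetic data: what it emulates

The generator draws per-gene log2 levels z = μ_g + δ·s_i·[g ∈ S] + ε with
ε ~ N(0, 1), latent state s_i ~ Bernoulli(f) i.i.d. across cells, coupling
δ in noise-SD units applied to the signature set S in the coordinated
regime only. Defaults are the package's study conditions: 40 cells, 36
genes, |S| = 12, δ = 2, f = 0.4.

Baselines encode the two kinds of signature gene seen in embryos:

* the first signature gene is an **induced** marker (the *Fgf4* role):
  baseline μ = −2, i.e. below the detection limit, so it is rarely
  detected in latent-negative cells and usually detected in
  latent-positive ones — this is what makes the anchor-positivity rules
  (Ct > 35, reads == 0) informative;
* the other signature genes are **expressed** pluripotency factors,
  μ ~ U(2, 5): always detected, coordinated only through their levels;
* background genes draw μ ~ U(1, 5) and never couple to the latent state.

Assay boundary. `counts` matrices emit normalized reads 2^z with a
detection threshold: levels below half a read are recorded as exactly 0,
matching the zero-inflated but otherwise continuous look of normalized
scRNA-seq tables. (Integer rounding was considered and rejected: at
read scale ~1 it creates rank ties dense enough to cap attainable
signature recovery below the package's own acceptance contract.) `ct`
matrices use Ct = 34 − z clipped to [10, 40], one qPCR cycle per log2
unit, so the Ct 35 detection boundary sits one cycle below the induced
gene's on-state mode; two housekeeping genes (Ct ≈ 18 ± 0.5) are
appended.

Technical dropout is expression-dependent: an entry drops to
0 / Ct 40 with probability `dropout_rate` at or below the detection
level, halving per log2 unit above it (abundant transcripts essentially
never drop out, as in preamplified qPCR and deep scRNA-seq). Default
rate 0.05. Failed reactions are masked (`missing_rate`, default 0.02)
independently of value. No quantitative noise parameters are published
for 16C-stage embryos; these defaults are this artifact's own choices,
selected once as what a practitioner would call realistic for
preamplified single-cell material, and are documented here for that
reason.

What the generator does **not** emulate: spatial arrangement and
FGF4-mediated neighbour signalling (the in-vivo feedback that converts
neighbours to PrE), embryo-level batch effects (cells are i.i.d.; embryo
ids are bookkeeping), library-size variation, and gene–gene correlation
beyond the single latent state. Passing tests therefore demonstrate that
the pipeline detects or rejects *this* coordination structure at
realistic noise levels — not that real embryo data are this clean.

The human-mixture generator shares the machinery: a panel of 36 marker
orthologues plus 5 TE markers, four populations (TE, ICMp, Epi-like,
PrE-like) shifted +3 log2 units on their lineage markers, ICMp as the
unshifted baseline cloud, 54 embryos with 13% generated without TE cells
(mimicking earlier embryos whose TE/ICM split is unresolved).

## PCA with missing values

`ppca_em` fits probabilistic PCA (x = Wt + μ + ε, isotropic ε) by EM,
conditioning each cell's latent score on its observed genes only — the
analysis-side answer to Ct matrices with failed reactions. Convergence is
declared when the sine of the largest principal angle between successive
loading subspaces and the relative change of the noise variance both fall
below `tol` (default 1e−8); raw parameter change is *not* usable as a
criterion because the likelihood is flat under within-subspace rotations
of W. Non-convergence raises an error carrying the iteration trace.
After convergence W is orthogonalized by SVD, components are ordered by
score variance and signs fixed so the largest-|loading| gene loads
positively. Explained fractions are score variance over total observed
variance; for the mean-impute cross-check (`classical_mean_impute`) they
are the usual eigenvalue ratios. On complete data the two subspaces agree
to principal angles < 1e−6; on masked rank-2 data the model's
reconstruction error of hidden entries is ~30× smaller than per-gene mean
imputation.

## Clustering and enrichment

Repeated k-means (k-means++ per restart, default 100 restarts; 250 for
1-D intensity splits) aligns every restart to the lowest-inertia run by
exact bipartite matching and takes per-cell majority labels; the mean
agreement with the consensus is reported as a stability score. Degenerate
input (all points identical) yields a single cluster with a warning;
k exceeding the number of distinct points is an error.

Anchor enrichment builds the 2 × 2 cluster × anchor± table and applies
the two-sided Fisher exact test (sum of hypergeometric probabilities not
exceeding the observed table's). An empty margin returns p = 1 with a
warning. Note that the exact test's null p-values are discrete and
conservative (super-uniform); calibration checks therefore bound the
ECDF from above rather than demanding exact uniformity.

## Human TE/ICMp/ICMd staging

Stage 1: k-means (k = 4) on the PCA scores (3 components — four
populations are not separable in a 2-D projection). A cluster is TE when
its mean TE-marker score (mean log2(1+x) over the TE markers) exceeds the
all-cell mean by a configurable margin (default 1 all-cell SD; cell-level
statistics are used because the across-cluster SD degenerates when
sub-clusters are homogeneous). The progenitor cluster is the non-TE
cluster whose centroid is nearest the origin of the centered score space
(the unshifted population); remaining clusters are ICMd. Stage 2: k-means
(k = 3) inside the progenitor cluster discards TE-scoring sub-clusters.
Stage 3: progenitor cells from embryos without any TE-labelled cell are
discarded as potential earlier embryos; this step is skipped (and logged)
when no TE cell was identified anywhere, since the inference has no
basis. Every assignment and discard reason is kept in the result's log.

## Group tests

Wilcoxon–Mann–Whitney: exact enumeration when the combined sample has at
most 12 tie-free values, otherwise the tie- and continuity-corrected
normal approximation, with a U statistic exactly at the null center
mapped to p = 1 (the two-sided tail there is everything); the mode used
is recorded. Kruskal–Wallis gates pairwise Wilcoxon follow-ups on the
omnibus p (default α = 0.05; α = 1 forces them); pairwise p-values are
uncorrected by default, with an optional, logged Holm adjustment.
Fligner–Killeen uses normal scores of ranked absolute deviations from
group medians with a χ²(1) p; constant pooled deviations give p = 1 with
a warning. Boxplot summaries use type-7 (linear-interpolation) quartiles
with whiskers at the furthest points within 1.5 IQR — recorded in output
metadata since plotting conventions differ.

## Problem sizes and tolerances in the acceptance surface

The acceptance checks run 100–200 simulation replicates per quantity at
the study conditions above — enough for Monte-Carlo standard errors of a
few parts per thousand on the calibration quantities while keeping the
whole surface in the minutes range on one CPU. Null calibration is judged
against an independent Monte-Carlo oracle of the same marginal model
(3 combined standard errors), because the tie-free analytic null for
Spearman does not hold exactly under zero-inflated marginals. Under the
frozen conditions the signature-recovery margin is intrinsically tight:
even perfectly continuous data at δ = 2, n = 40, |ρ| ≥ 0.3 yields a
per-gene recovery probability of only ≈0.95, and the assay boundary costs
a few further points; measured sensitivity sits near 0.91–0.92 against
the 0.9 contract.

## Known limitations

* The signature screen inherits the per-gene p ≤ 0.05 convention without
  multiplicity control; at 34k-gene scale the selected set contains an
  α-level fraction of false correlates by design.
* The published threshold table and the t-approximation disagree in the
  third decimal; results near the threshold can differ between modes.
* `ppca_em` is a probabilistic-PCA EM, not a numerical replica of any
  particular Bayesian PCA implementation; agreement is at subspace level.
* The TE-cluster margin (1 SD) and the progenitor-cluster rule
  (centroid nearest the origin) are heuristics chosen for separable
  mixtures; strongly imbalanced or weakly separated data may need the
  configurable margin adjusted, and all such decisions are logged.
* Exact Fisher/Wilcoxon p-values are conservative on small discrete
  tables; calibration claims are therefore one-sided.
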