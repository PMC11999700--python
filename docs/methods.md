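# Methods

This package reimplements, as a tested library, a spatial-analysis pipeline
for multiplexed imaging of the human pancreas in type 1 diabetes (T1D): from
a per-cell table to islet instances, an islet pseudotime with insulitis
stage labels, CD8+T sub-states of inflamed islets, cellular neighborhoods
(CNs) with adjacency statistics, and hierarchical linear models (HLMs) of
lobular patterning. Because the imaging data themselves are not required, a
ground-truthed synthetic tissue generator provides the study conditions for
every stage.

## Pipeline stages

### Marker normalisation, cell typing, gating

Marker intensities are z-normalised within each donor (sample standard
deviation, ddof=1). The typing path applies log1p first — the usual
variance-stabilising transform for right-skewed fluorescence. Cells are
Leiden-clustered on a Euclidean kNN graph of the z-scores (defaults: 30
neighbours, resolution 0.5) and each cluster is annotated with the cell type
whose signature row maximises `sum_m signature[type, m] * mean_z[cluster, m]`;
ties break by signature row order and are flagged. Signatures are +1 for a
type's characteristic markers, −1 for markers the type reliably lacks
(immune types: epithelial markers; structural/endocrine types: CD45), and 0
otherwise. Cells annotated as immune are re-clustered on the immune markers
alone, re-standardised within the immune subset where lineage prevalences
are balanced; this second pass resolves immune lineages that a single coarse
clustering merges, the same refinement used for dense immune compartments in
multiplexed imaging. Replacing interactive cluster merging with
signature-based annotation (same-label clusters merge implicitly) removes
the only manual step of the original procedure.

Marker positivity is gated at the 99th percentile (linear interpolation
between order statistics, the "type 7" convention) of a background
distribution pooled from cell types known not to express the marker,
per-donor by default (pooled mode available; which the original analysis
used is not stated). A cell is positive iff its intensity is *strictly*
greater than the threshold. Gating is rank-based and therefore invariant
under any strictly increasing transform applied jointly to background and
query intensities.

### Islet mapping

Each cell's *window* is its 20 nearest spatial neighbours (Euclidean, µm),
excluding the index cell, never crossing donors, with distance ties broken
by cell id so results are reproducible on degenerate geometry. Window
compositions over the vocabulary with alpha/beta/delta merged to "Endocrine"
are clustered by mini-batch k-means (k=200, batch 1024, best of 3 restarts,
fixed seed). The islet region is the union of clusters whose mean endocrine
window fraction exceeds 0.5 — a threshold rule rather than "the single most
endocrine cluster", for robustness to over-clustering. Islets are connected
components of the symmetric 5-NN graph over region cells (edge when either
cell lists the other), dropping components under 10 cells.

The islet boundary is represented non-parametrically: a cell's distance to
an islet is its distance to the nearest member cell. Composition features
are `log1p((inside + band count) / n_endocrine)` for every non-endocrine
type, where the band is 0–20 µm from the boundary, cells of other islets are
excluded, and a cell within reach of several islets counts only for the
nearest one (no double counting). `log1p` keeps zero counts finite; the
original's zero handling is unstated. Swath profiles assign extra-islet
cells to half-open annuli `[0,25) [25,50) [50,100)` µm by the same distance.

### Pseudotime and stage labels

Islet features enter a cosine kNN graph (15 neighbours); Leiden at
resolution 1 gives trajectory clusters; between-cluster connectivity is the
partition-based graph-abstraction statistic (observed inter-cluster edges
over their expectation under random assignment). Pseudotime is diffusion
pseudotime from a root islet — the islet nearest (cosine) to the mean
feature vector of the non-T1D islets, since a graph distance needs a node to
start from — min-max normalised to [0, 1]. Path isolation is supported as an
explicit omit list: omitted islets are removed before the computation and
afterwards assigned their nearest retained neighbour's pseudotime, leaving
retained islets untouched. Disconnected graphs are handled per component
(local roots) with a warning.

Trajectory clusters map to stages by rule: beta-present clusters (median
beta fraction > 0.05) are Normal, or Inflamed when their median immune
enrichment (CD8 + macrophage/DC per endocrine cell) exceeds the 90th
percentile of non-T1D islets; beta-free clusters are Insulin-Depleted.
Within the beta-free islets, those with strictly more than `cd8_thresh` CD8+T
cells and strictly more than `mac_thresh` macrophage/DCs are promoted to
Insulin-Depleted + Immune; the default thresholds are the 95th percentiles of
those counts over Normal islets (2 and 7 in the original data) and require
Normal islets to calibrate, otherwise explicit thresholds must be passed.

### Inflamed sub-states

Per inflamed islet, the fraction of its CD8+T cells (inside + 0–20 µm band,
combined before the frequency is taken) positive for each functional marker
forms the sub-state matrix; islets under a configurable CD8 floor (default
1) are excluded and listed. Columns are z-normalised and rows
Leiden-clustered (15 neighbours); the number of sub-states is not forced.
Enrichment versus the surrounding tissue pools CD8 cells within donor before
taking frequencies, takes islet-minus-swath differences per marker, and
tests them with the two-sided Wilcoxon signed-rank test across donors
(zero differences dropped; exact null for small n; fewer than 3 pairs skips
the test). P-values are reported raw to match the original analysis; a
Benjamini–Hochberg option exists but is off by default.

### Cellular neighborhoods

CN identification over-clusters the same k=20 windows into 200 raw clusters
and names each cluster by the set of cell types present (≥1 cell among the
20 neighbours) in strictly more than 80% of its windows; acinar and
ductal/epithelial cells participate in windows and clustering but never in
names; same-named clusters merge; empty names form one background CN, so
every cell carries a CN for abundance accounting. CN instances are connected
components of the donor-wide symmetric 5-NN graph restricted to the CN's
cells — the graph is built over *all* cells first because tissue distance is
physical; restricting first would connect distant cells. Two instances are
adjacent when any cell of one is a 5-NN contact of any cell of the other
(symmetric at the pair level); the adjacency frequency from CN A to CN B —
the fraction of A's instances adjacent to ≥1 B instance — is directional.
The exact adjacency criterion of the prior method the original cites is not
restated there; this cell-contact rule is a declared, oracle-testable
stand-in. CN abundance per donor is CN cell count over acinar cell count;
the group contrast ranks CNs by T1D/non-T1D fold change with raw two-sided
Mann–Whitney p-values.

### Lobular models

Cells map to lobule polygons by point-in-polygon lookup (ties to the lowest
lobule id); cells outside all polygons get the reserved "edge" label, which
is excluded from modelling. Lobular abundance uses extra-islet cells only:
type count over acinar count within the lobule, z-normalised within donor;
islet pseudotime is z-normalised across the dataset. Lobules without
extra-islet acinar cells are excluded with a warning; lobules without islets
cannot contribute an outcome and are likewise absent from the fits.

Three models are fitted by restricted maximum likelihood (REML):

* intercept-only `pt ~ 1 + (1|lobule)`, giving ICC = τ²/(τ²+σ²);
* per-donor two-level `pt ~ x + (1|lobule)`;
* three-level `pt ~ x + (1 + x|donor) + (1|lobule)` with an unstructured
  donor-level intercept/slope covariance (the literal reading of the random
  term) and lobules nested in donors.

The REML core parametrises variance components on an unconstrained scale
(log standard-deviation ratios; Cholesky factor for the 2×2 donor block), so
components are non-negative and the ICC is in [0, 1] by construction;
boundary estimates (τ² → 0) are reached up to a floor of e⁻¹² and flagged.
Each criterion evaluation uses the Woodbury identity on per-block
cross-products, so cost is O(q³) per top-level group. Optimisation is
bounded L-BFGS-B with 5 dispersed restarts and 10⁻⁸ tolerance on the
criterion. Fixed-effect inference uses Satterthwaite degrees of freedom:
the variance of the coefficient is differentiated numerically with respect
to the variance parameters, the parameter covariance comes from the observed
REML information (numerical Hessian), and df = 2·Var(β̂)²/(gᵀΣg). The
implementation reproduces lme4/lmerTest estimates, standard errors,
Satterthwaite df and p-values to ~4 significant figures on shared datasets
(`tests/test_lobular.py`), and for the lobule-level covariate in balanced
designs the GLS slope coincides with OLS, which the tests check exactly.
ICC fits exclude lobules with fewer than 2 islets (configurable).

## The synthetic tissue

The generator emulates the statistical structure the pipeline assumes, not
pixels: no point-spread, segmentation noise, or image rendering.

* **Lobules** — Voronoi cells of uniform seeds, mirror-clipped to the tissue
  rectangle (space-filling, irregular, exact tiling). Default 9 lobules on
  2000×2000 µm per donor.
* **Islets** — isotropic Gaussian blobs truncated at 3σ (σ = r/3), radius
  lognormal with log-mean log 58 µm (human islets are ~100–150 µm across),
  endocrine core density 0.03 cells/µm², 10 islets per donor, one donor per
  group (nonT1D, AA+, T1D) by default (~6×10⁴ cells, 30 islets).
* **Disease stage** — each islet's stage is `group mean + lobule effect +
  islet effect` with configurable variances τ*² and σ*² (target ICC
  τ*²/(τ*²+σ*²)); the raw (unclipped) stage is kept as ground truth, the
  [0,1]-clipped stage drives composition. Beta fraction and CD8 /
  macrophage-DC loads are piecewise-linear in stage: beta holds at 0.55 then
  falls to 0 by stage 0.7; immune load peaks mid-trajectory (the inflamed
  phase) and decays in depleted islets. 60% of islet-associated immune cells
  sit in the 0–15 µm peri-islet annulus, reflecting that insulitis is
  predominantly peri-insulitis. A `monotone_infiltration` preset (monotone
  immune curves, non-T1D anchored at low stage, 14 large islets) is the
  benchmark for pseudotime ordering.
* **Niches** — per donor, B/CD8 aggregates (r = 40 µm, 50/50 mix) each with
  a touching vasculature patch (the planted *adjacent* CN pair), plus
  neutrophil patches placed ≥300 µm from everything (the planted
  *non-adjacent* control).
* **Markers** — intensity = lognormal background, shifted by +2 log-units
  when positive (right-skewed, like fluorescence; the positive component
  stochastically dominates). Positivity probabilities: 0.98 for a type's
  own lineage markers, 0.2% otherwise (a bleed-compensated panel);
  functional markers follow four CD8 sub-state profiles (all-low /
  CD45RA-high / CD45RO+PD-1-high / LAG-3+GzmB+ICOS+CD57-high) assigned per
  inflamed islet, are at 5% baseline on other immune cells, and 0 on
  structural cells — which is what makes structural types valid gating
  backgrounds. The intensity distribution family is a modelling choice; the
  original work does not state one.

What passing tests therefore show: the pipeline recovers planted structure
under idealised conditions — compact islets on a homogeneous Poisson
background, independent lognormal markers, literal stage-to-composition
maps. They do not certify performance under segmentation errors, spatial
intensity artefacts, marker bleed, or tissue-section geometry, none of which
the generator models.

## Numerical and scale choices

Simulation sizes were chosen to keep the whole suite within a desktop-scale
budget while leaving the statistical checks well-powered: ICC recovery uses
40 lobules × 12 islets × 200 replicates per target ICC; two-level type-I
error uses 20 lobules × 8 islets × 1000 null simulations (Satterthwaite df
≈ J−2 ≈ 18, where miscalibration would show); slope recovery uses 200
replicates; the end-to-end tissue stages run at the default ~6×10⁴-cell
scale. kNN ties are broken by cell id everywhere; k-means uses a fixed seed
with 3 restarts; Leiden is seeded. Degenerate inputs (empty regions, zero
background, single lobules, constant covariates, islets without CD8) raise
or are excluded-with-report as documented on each function.

## Known limitations

* Stage labelling maps *clusters* to stages via medians; a cluster mixing
  beta-present and beta-free islets dilutes the rule. The original work
  merged clusters by inspection; the rule-based mapping is the price of
  automation.
* The adjacency criterion is a declared stand-in for an unspecified prior
  method; frequencies are comparable within this package, not necessarily
  with the original's numbers.
* The three-level HLM assumes lobules nested in donors and ignores
  cross-donor lobule correlation (as does the original formulation).
* Diffusion pseudotime is only defined up to monotone reparametrisation;
  the [0,1] min-max normalisation is a convention, and only rank statements
  are tested.
* The generator's marker independence (given positivity) understates the
  correlated noise of real panels; typing accuracy on real data will be
  lower than on synthetic tissue.
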