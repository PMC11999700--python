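# insulitis

Spatial analysis of multiplexed pancreas imaging in type 1 diabetes: from a
per-cell table (coordinates, cell types, marker intensities) to islet
instances, an islet pseudotime with insulitis stage labels, CD8⁺T-cell
sub-states of inflamed islets, cellular neighborhoods (CNs) with adjacency
and abundance statistics, and hierarchical linear models of how insulitis
patterns across pancreatic lobules. It is written for computational
biologists analysing CODEX-style highly multiplexed imaging of pancreas —
or anyone who wants a tested, scriptable version of this class of islet
analysis without interactive gating steps.

## The methods in brief

* **Islet mapping.** Each cell's *window* is the composition of its 20
  nearest neighbours (α/β/δ merged to "Endocrine"). Windows are
  over-clustered with mini-batch k-means (k = 200); clusters whose mean
  endocrine fraction exceeds 0.5 define the islet region; islets are
  connected components (symmetric 5-NN graph, ≥10 cells). Features per islet
  are `log1p(count_t / n_endocrine)` for each non-endocrine type *t*,
  counting cells inside the islet or within 20 µm of its boundary.
* **Pseudotime.** A cosine 15-NN graph over islet features, Leiden clusters,
  graph-abstraction connectivity, and diffusion pseudotime from the islet
  nearest the non-T1D centroid, scaled to [0, 1]. Clusters map to stages
  Normal / Inflamed / Insulin-Depleted; β-free islets with > cd8 and > mac
  immune counts (95th percentiles of Normal islets) become
  Insulin-Depleted + Immune.
* **Gating and sub-states.** Marker positivity is intensity > the 99th
  percentile of a background distribution pooled from non-expressing cell
  types. Inflamed islets are clustered on the positivity frequencies of
  their CD8⁺T cells (inside + 20 µm band); islet-vs-swath enrichment uses
  donor-pooled frequencies and the exact Wilcoxon signed-rank test.
* **Cellular neighborhoods.** The same windows, k-means k = 200, each raw
  cluster named by the cell types present in > 80% of its windows (acinar /
  epithelial never in names), same-named clusters merged. Instances are
  connected components of the 5-NN graph; CN A → B adjacency frequency is
  the fraction of A instances touching ≥1 B instance; abundance is CN cells
  per acinar cell, contrasted T1D vs non-T1D by Mann–Whitney U.
* **Lobular models.** With islets assigned to lobule polygons, REML fits of
  `pt ~ 1 + (1|lobule)` give the intraclass correlation
  ICC = τ²/(τ²+σ²) — the fraction of pseudotime variance between lobules —
  and `pt ~ x + (1|lobule)` (per donor) plus
  `pt ~ x + (1 + x|donor) + (1|lobule)` (all donors) relate lobular
  cell-type abundance *x* to islet pseudotime, with Satterthwaite degrees of
  freedom for the fixed effects. The mixed-model core is validated against
  lme4/lmerTest in the test suite.

A ground-truthed synthetic tissue generator (`insulitis.synthetic`) plants
islets with a lobule-structured disease stage, four CD8 sub-state profiles,
B/CD8 aggregates adjacent to vasculature patches, and lognormal marker
intensities — so every stage of the pipeline is testable against planted
truth. See `docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import numpy as np
from insulitis import *
from insulitis import pseudotime as ptm, lobular

cfg = SyntheticConfig(rng_seed=7)           # 3 donors, ~66k cells, 30 islets
table, truth = generate_tissue(cfg)

w = compute_windows(table, k=20)
region = detect_islet_region(w, seed=0)
islets_list = extract_islets(table, region)
fm = islet_composition_features(islets_list, table)

traj = build_trajectory(fm, seed=0)
non = [i for i in fm.meta.index if fm.meta.loc[i, "group"] == "nonT1D"]
res = compute_pseudotime(traj, fm, non, seed=0)
stages = ptm.label_stages(res, fm.meta)
print(stages.value_counts().to_string())

for donor, part in truth.partitions.items():
    lob = lobular.islet_lobule_assignment(
        [i for i in islets_list if i.donor_id == donor], part)
    keep = lob[lob != "edge"]
    fit = fit_icc(res.pseudotime[keep.index], keep)
    print(f"{donor}: ICC = {fit.icc:.2f}")
```

prints

```
stage
Normal      20
Inflamed    10
nonT1D_0: ICC = 0.01
AA+_0: ICC = 0.85
T1D_0: ICC = 0.34
```

All 30 planted islets are detected; the non-T1D donor's islets are all
Normal with no lobular grouping (ICC ≈ 0), while in the autoantibody-positive
and T1D donors inflamed islets cluster within lobules (higher ICC) — the
lobular patterning the hierarchical models then quantify.

There is also a thin CLI (`insulitis synth|celltype|islets|pseudotime|
substates|niches|lobules`) that wires these stages through plain
CSV/Parquet/GeoJSON files.

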