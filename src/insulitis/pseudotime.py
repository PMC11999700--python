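"""Islet pseudotime and insulitis stage labels.

Islets are ordered along a trajectory built from their composition features:
a cosine kNN graph (15 neighbours), Leiden clustering at resolution 1, the
graph-abstraction connectivity statistic between clusters, and diffusion
pseudotime from a root islet — the islet whose feature vector lies nearest
(cosine) to the mean feature vector of non-T1D islets — min-max normalised
to [0, 1].  Trajectory clusters are then mapped to the insulitis stages
Normal / Inflamed / InsulinDepleted by beta-cell presence and immune
enrichment, and beta-free islets with more CD8+T cells and macrophage/DCs
than the 95th percentiles of Normal islets are promoted to
InsulinDepleted + Immune.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .islets import IsletFeatureMatrix
from .synthetic import (
    STAGE_DEPLETED,
    STAGE_DEPLETED_IMMUNE,
    STAGE_INFLAMED,
    STAGE_NORMAL,
)

logger = logging.getLogger(__name__)

__all__ = ["Trajectory", "PseudotimeResult", "build_trajectory",
           "compute_pseudotime", "label_stages"]


@dataclass
class Trajectory:
    """kNN graph, Leiden clusters and cluster-connectivity of the islets."""

    islet_ids: list[str]
    adata: "object" = field(repr=False)      # AnnData holding graph + clusters
    clusters: pd.Series = None               # islet_id -> cluster id
    connectivity: pd.DataFrame = None        # cluster x cluster PAGA statistic


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series                    # islet_id -> [0, 1]
    clusters: pd.Series
    connectivity: pd.DataFrame
    root_islet: str
    omitted: list[str] = field(default_factory=list)
    stages: pd.Series | None = None


def _make_adata(features: pd.DataFrame, n_neighbors: int, seed: int):
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=features.to_numpy(dtype=float))
    adata.obs_names = [str(i) for i in features.index]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, metric="cosine",
                        use_rep="X", random_state=seed)
    return adata


def build_trajectory(
    features: IsletFeatureMatrix | pd.DataFrame,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Cosine kNN graph + Leiden clusters + cluster connectivity.

    The connectivity entry for a cluster pair is the observed inter-cluster
    edge count relative to its expectation under random edge assignment (the
    partition-based graph-abstraction statistic).
    """
    import scanpy as sc

    feats = features.features if isinstance(features, IsletFeatureMatrix) else features
    if len(feats) < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} islets, got {len(feats)}")
    adata = _make_adata(feats, n_neighbors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg")
        sc.tl.paga(adata, groups="leiden")
    names = list(adata.obs["leiden"].cat.categories)
    conn = pd.DataFrame(np.asarray(adata.uns["paga"]["connectivities"].todense()),
                        index=names, columns=names)
    clusters = pd.Series(adata.obs["leiden"].astype(int).to_numpy(),
                         index=feats.index, name="cluster")
    return Trajectory(islet_ids=list(feats.index), adata=adata,
                      clusters=clusters, connectivity=conn)


def _cosine_to_centroid(X: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    xn = np.linalg.norm(X, axis=1)
    cn = np.linalg.norm(centroid)
    denom = np.where(xn * cn > 0, xn * cn, 1.0)
    return 1.0 - (X @ centroid) / denom


def compute_pseudotime(
    trajectory: Trajectory,
    features: IsletFeatureMatrix | pd.DataFrame,
    nonT1D_islets: list[str],
    omit_ids: list[str] | None = None,
    seed: int = 0,
) -> PseudotimeResult:
    """Diffusion pseudotime from the root islet, scaled to [0, 1].

    The root is the islet nearest (cosine) to the mean feature vector of the
    non-T1D islets.  ``omit_ids`` are removed before the computation (path
    isolation) and afterwards assigned the pseudotime of their nearest
    retained neighbour; retained islets are unaffected by the omission.
    Disconnected graphs are handled per connected component, each rooted at
    its islet nearest the non-T1D centroid, with a warning.
    """
    feats = features.features if isinstance(features, IsletFeatureMatrix) else features
    nonT1D_islets = [i for i in nonT1D_islets if i in feats.index]
    if not nonT1D_islets:
        raise ValueError("no non-T1D islets available to define the root")
    omit_ids = [str(i) for i in (omit_ids or []) if str(i) in map(str, feats.index)]

    kept = feats.drop(index=[i for i in feats.index if str(i) in omit_ids])
    centroid = feats.loc[[i for i in nonT1D_islets]].to_numpy(dtype=float).mean(axis=0)

    n_neighbors = trajectory.adata.uns["neighbors"]["params"]["n_neighbors"]
    adata = _make_adata(kept, min(n_neighbors, len(kept) - 1), seed)

    conn = sp.csr_matrix(adata.obsp["connectivities"])
    from scipy.sparse.csgraph import connected_components
    n_comp, comp = connected_components(conn, directed=False)
    if n_comp > 1:
        logger.warning("islet graph has %d connected components; pseudotime "
                       "computed per component", n_comp)

    X = kept.to_numpy(dtype=float)
    pt = np.full(len(kept), np.nan)
    root_global: str | None = None
    import scanpy as sc

    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        d = _cosine_to_centroid(X[members], centroid)
        root_local = members[int(np.argmin(d))]
        if n_comp == 1:
            sub = adata
            root_idx = int(root_local)
        else:
            sub = adata[members].copy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.pp.neighbors(sub, n_neighbors=min(n_neighbors, len(members) - 1)
                                if len(members) > 1 else 1,
                                metric="cosine", use_rep="X", random_state=seed)
            root_idx = int(np.flatnonzero(members == root_local)[0])
        if len(members) == 1:
            pt[members] = 0.0
        else:
            sub.uns["iroot"] = root_idx
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.tl.dpt(sub)
            vals = np.asarray(sub.obs["dpt_pseudotime"], dtype=float)
            vals[~np.isfinite(vals)] = np.nanmax(vals[np.isfinite(vals)]) if np.isfinite(vals).any() else 0.0
            pt[members] = vals
    # the reported root is the islet nearest the non-T1D centroid over all
    # kept islets (the local root of its component)
    d_all = _cosine_to_centroid(X, centroid)
    root_global = str(kept.index[int(np.argmin(d_all))])

    if np.nanmax(pt) > np.nanmin(pt):
        pt = (pt - np.nanmin(pt)) / (np.nanmax(pt) - np.nanmin(pt))
    else:
        pt = np.zeros_like(pt)
    series = pd.Series(pt, index=kept.index, name="pseudotime")

    # re-insert omitted islets at their nearest retained neighbour's value
    if omit_ids:
        omitted_feats = feats.loc[[i for i in feats.index if str(i) in omit_ids]]
        Xo = omitted_feats.to_numpy(dtype=float)
        Xk = kept.to_numpy(dtype=float)
        kn = np.linalg.norm(Xk, axis=1)
        on = np.linalg.norm(Xo, axis=1)
        denom = np.outer(on, kn)
        denom[denom == 0] = 1.0
        cos_d = 1.0 - (Xo @ Xk.T) / denom
        nearest = cos_d.argmin(axis=1)
        filled = pd.Series(pt[nearest], index=omitted_feats.index)
        series = pd.concat([series, filled]).loc[feats.index]
        series.name = "pseudotime"

    return PseudotimeResult(
        pseudotime=series,
        clusters=trajectory.clusters,
        connectivity=trajectory.connectivity,
        root_islet=root_global,
        omitted=list(omit_ids),
    )


def label_stages(
    result: PseudotimeResult,
    meta: pd.DataFrame,
    cd8_thresh: float | None = None,
    mac_thresh: float | None = None,
    beta_fraction_threshold: float = 0.05,
    inflamed_quantile: float = 0.90,
    nonT1D_group: str = "nonT1D",
) -> pd.Series:
    """Map trajectory clusters to insulitis stages.

    ``meta`` must carry per-islet ``n_beta``, ``n_endocrine``, ``cd8_count``,
    ``mac_count`` and ``group`` (as produced by the islet feature step).

    Cluster rule: a cluster whose islets have beta cells (median beta
    fraction > threshold) is Normal, or Inflamed when its median immune
    enrichment (CD8 + macrophage/DC per endocrine cell) exceeds the
    ``inflamed_quantile`` quantile of the non-T1D islets; beta-free clusters
    are InsulinDepleted.  Within InsulinDepleted, an islet with strictly
    more than ``cd8_thresh`` CD8+T cells and strictly more than
    ``mac_thresh`` macrophage/DCs becomes InsulinDepleted + Immune; the
    default thresholds are the 95th percentiles of those counts over Normal
    islets and require Normal islets to calibrate.
    """
    meta = meta.loc[result.pseudotime.index]
    beta_frac = meta["n_beta"] / meta["n_endocrine"]
    enrich = (meta["cd8_count"] + meta["mac_count"]) / meta["n_endocrine"]
    non = enrich[meta["group"] == nonT1D_group]
    if len(non) == 0:
        raise ValueError("no non-T1D islets to calibrate immune enrichment")
    cutoff = float(np.quantile(non, inflamed_quantile))

    stages = pd.Series("", index=meta.index, name="stage")
    for cl, idx in result.clusters.groupby(result.clusters).groups.items():
        has_beta = float(beta_frac.loc[idx].median()) > beta_fraction_threshold
        if not has_beta:
            stages.loc[idx] = STAGE_DEPLETED
        elif float(enrich.loc[idx].median()) > cutoff:
            stages.loc[idx] = STAGE_INFLAMED
        else:
            stages.loc[idx] = STAGE_NORMAL

    depleted = stages == STAGE_DEPLETED
    if cd8_thresh is None or mac_thresh is None:
        normal = stages == STAGE_NORMAL
        if not normal.any():
            raise ValueError("no Normal islets to calibrate the immune thresholds; "
                             "pass cd8_thresh and mac_thresh explicitly")
        if cd8_thresh is None:
            cd8_thresh = float(np.percentile(meta.loc[normal, "cd8_count"], 95))
        if mac_thresh is None:
            mac_thresh = float(np.percentile(meta.loc[normal, "mac_count"], 95))
    immune = depleted & (meta["cd8_count"] > cd8_thresh) & (meta["mac_count"] > mac_thresh)
    stages[immune] = STAGE_DEPLETED_IMMUNE
    result.stages = stages
    return stages
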