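"""Cellular neighborhoods (CNs): over-cluster-and-merge identification,
connected instances, adjacency and abundance statistics.

Windows (k=20 nearest neighbours, endocrine types merged) are over-clustered
with mini-batch k-means into 200 raw clusters.  Each raw cluster is named by
the set of cell types present in strictly more than 80% of its windows —
acinar and ductal/epithelial cells participate in the windows and the
clustering but never in names — and same-named clusters are merged into one
CN; clusters with an empty name form a single background CN.  CN instances
are connected components of the symmetric k=5 spatial kNN graph (built over
all cells of a donor, then restricted to the CN's cells).  Two instances
are adjacent when any cell of one is a k=5 spatial neighbour of any cell of
the other; the adjacency frequency from CN A to CN B is the fraction of A's
instances adjacent to at least one B instance.  CN abundance per donor is
the CN's cell count divided by the donor's acinar cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._knn import connected_component_labels, symmetric_knn_graph
from .islets import Windows, window_kmeans
from .synthetic import CellTypeVocabulary, default_vocabulary

__all__ = ["CNModel", "CNInstance", "identify_cns", "extract_cn_instances",
           "adjacency_frequency", "adjacency_matrix", "cn_abundance_and_contrast"]

BACKGROUND_CN = "(background)"


@dataclass
class CNModel:
    """Raw-cluster -> named-CN map and the per-cell CN assignment."""

    k: int
    n_clusters: int
    presence_threshold: float
    cluster_names: dict[int, str]          # raw cluster -> CN name
    cn_names: list[str]                    # unique CN names
    assignments: pd.Series                 # cell_id -> CN name

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "n_clusters": self.n_clusters,
            "presence_threshold": self.presence_threshold,
            "cluster_names": {str(c): n for c, n in self.cluster_names.items()},
            "cn_names": self.cn_names,
        }


def _name_from_presence(presence: pd.Series, threshold: float,
                        excluded: tuple[str, ...]) -> str:
    kept = [t for t, p in presence.items() if p > threshold and t not in excluded]
    if not kept:
        return BACKGROUND_CN
    return "|".join(kept)  # presence.index order = vocabulary order


def identify_cns(
    windows: Windows,
    n_clusters: int = 200,
    presence_threshold: float = 0.8,
    seed: int = 0,
    vocabulary: CellTypeVocabulary | None = None,
) -> CNModel:
    """Name windows' k-means clusters by their characteristic cell types.

    Presence of a type in a window means at least one of the k neighbours is
    of that type; a type makes it into the cluster's name when present in
    strictly more than ``presence_threshold`` of the cluster's windows.
    """
    voc = default_vocabulary() if vocabulary is None else vocabulary
    excluded = (voc.acinar_type, *voc.epithelial_types)
    labels = window_kmeans(windows, n_clusters, seed)
    present = windows.composition > 0                      # window x type
    names: dict[int, str] = {}
    for cl in np.unique(labels):
        presence = present[labels == cl].mean(axis=0)
        names[int(cl)] = _name_from_presence(presence, presence_threshold, excluded)
    assignments = pd.Series([names[int(c)] for c in labels],
                            index=pd.Index(windows.cell_ids, name="cell_id"),
                            name="cn_label")
    cn_names = sorted(set(names.values()))
    return CNModel(k=windows.k, n_clusters=int(n_clusters),
                   presence_threshold=presence_threshold,
                   cluster_names=names, cn_names=cn_names, assignments=assignments)


@dataclass
class CNInstance:
    instance_id: str
    cn_name: str
    donor_id: str
    cell_ids: np.ndarray
    centroid: tuple[float, float]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class DonorGraph:
    """Symmetric k=5 spatial kNN adjacency over all cells of one donor."""

    cell_ids: np.ndarray
    adjacency: sp.csr_matrix = field(repr=False)
    positions: dict = field(repr=False)        # cell_id -> row


def build_donor_graphs(
    table: pd.DataFrame, adjacency_k: int = 5, donor_col: str = "donor_id",
) -> dict[str, DonorGraph]:
    graphs = {}
    for donor, sub in table.groupby(donor_col, observed=True):
        coords = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        k = min(adjacency_k, len(sub) - 1)
        adj = symmetric_knn_graph(coords, k, order_key=ids)
        graphs[str(donor)] = DonorGraph(
            cell_ids=ids, adjacency=adj,
            positions={c: i for i, c in enumerate(ids)})
    return graphs


def extract_cn_instances(
    table: pd.DataFrame,
    assignments: pd.Series,
    adjacency_k: int = 5,
    donor_col: str = "donor_id",
    graphs: dict[str, DonorGraph] | None = None,
) -> list[CNInstance]:
    """CN instances: connected components of the donor-wide symmetric kNN
    graph restricted to each CN's cells."""
    if graphs is None:
        graphs = build_donor_graphs(table, adjacency_k, donor_col)
    cn_of = assignments.reindex(table["cell_id"]).to_numpy()
    instances: list[CNInstance] = []
    for donor, sub in table.groupby(donor_col, observed=True):
        g = graphs[str(donor)]
        loc = table.index.get_indexer(sub.index)
        sub_cn = cn_of[loc]
        rows = np.array([g.positions[c] for c in sub["cell_id"]])
        for cn in pd.unique(sub_cn):
            if cn is None or (isinstance(cn, float) and np.isnan(cn)):
                continue
            members = rows[sub_cn == cn]
            if len(members) == 0:
                continue
            adj = g.adjacency[members][:, members]
            comp = connected_component_labels(adj)
            for c in np.unique(comp):
                m = members[comp == c]
                ids = g.cell_ids[m]
                coords = sub.set_index("cell_id").loc[ids, ["x_um", "y_um"]]
                instances.append(CNInstance(
                    instance_id=f"{donor}/{cn}/{c}",
                    cn_name=str(cn), donor_id=str(donor), cell_ids=ids,
                    centroid=(float(coords["x_um"].mean()), float(coords["y_um"].mean())),
                ))
    return instances


def _instances_adjacent(a: CNInstance, b: CNInstance, graph: DonorGraph) -> bool:
    ra = [graph.positions[c] for c in a.cell_ids]
    rb = [graph.positions[c] for c in b.cell_ids]
    return bool(graph.adjacency[ra][:, rb].count_nonzero() > 0)


def adjacency_frequency(
    instances: list[CNInstance],
    source_cn: str,
    dest_cn: str,
    graphs: dict[str, DonorGraph],
) -> float:
    """Fraction of source-CN instances adjacent to at least one dest-CN
    instance (self-adjacency of an instance excluded)."""
    src = [i for i in instances if i.cn_name == source_cn]
    if not src:
        raise ValueError(f"no instances of source CN {source_cn!r}: frequency undefined")
    dst = [i for i in instances if i.cn_name == dest_cn]
    hit = 0
    for s in src:
        cands = [d for d in dst if d.donor_id == s.donor_id and d.instance_id != s.instance_id]
        if any(_instances_adjacent(s, d, graphs[s.donor_id]) for d in cands):
            hit += 1
    return hit / len(src)


def adjacency_matrix(
    instances: list[CNInstance],
    graphs: dict[str, DonorGraph],
    cns: list[str] | None = None,
) -> pd.DataFrame:
    """Source x dest adjacency frequencies for all CN pairs with source
    instances (rows without instances are dropped)."""
    if cns is None:
        cns = sorted({i.cn_name for i in instances})
    # precompute instance-level adjacency once per donor
    by_donor: dict[str, list[CNInstance]] = {}
    for inst in instances:
        by_donor.setdefault(inst.donor_id, []).append(inst)
    adjacent_to: dict[str, set[str]] = {i.instance_id: set() for i in instances}
    for donor, insts in by_donor.items():
        g = graphs[donor]
        n = len(insts)
        membership = np.full(g.adjacency.shape[0], -1)
        for k, inst in enumerate(insts):
            membership[[g.positions[c] for c in inst.cell_ids]] = k
        coo = sp.triu(g.adjacency, k=1).tocoo()
        mi, mj = membership[coo.row], membership[coo.col]
        mask = (mi >= 0) & (mj >= 0) & (mi != mj)
        for a, b in zip(mi[mask], mj[mask]):
            adjacent_to[insts[a].instance_id].add(insts[b].cn_name)
            adjacent_to[insts[b].instance_id].add(insts[a].cn_name)
    out = pd.DataFrame(np.nan, index=cns, columns=cns)
    for s_cn in cns:
        src = [i for i in instances if i.cn_name == s_cn]
        if not src:
            continue
        for d_cn in cns:
            hits = sum(d_cn in adjacent_to[s.instance_id] for s in src)
            out.loc[s_cn, d_cn] = hits / len(src)
    return out.dropna(how="all")


def cn_abundance_and_contrast(
    table: pd.DataFrame,
    assignments: pd.Series,
    group_a: str = "T1D",
    group_b: str = "nonT1D",
    donor_col: str = "donor_id",
    acinar_type: str = "Acinar",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor CN abundance (CN cells / acinar cells) and the group
    contrast: CNs ranked by fold increase of mean abundance in ``group_a``
    vs ``group_b`` with per-CN two-sided Mann-Whitney U p-values (raw)."""
    cn_of = assignments.reindex(table["cell_id"]).to_numpy()
    rows = []
    for donor, sub in table.groupby(donor_col, observed=True):
        n_acinar = int((sub["cell_type"].astype(str) == acinar_type).sum())
        if n_acinar == 0:
            raise ValueError(f"donor {donor!r} has no acinar cells; abundance undefined")
        loc = table.index.get_indexer(sub.index)
        counts = pd.Series(cn_of[loc]).value_counts()
        group = sub["group"].iloc[0] if "group" in sub.columns else ""
        for cn, cnt in counts.items():
            rows.append({"donor_id": str(donor), "group": group, "cn": cn,
                         "n_cells": int(cnt), "abundance": cnt / n_acinar})
    abundance = pd.DataFrame(rows)

    contrast_rows = []
    for cn, sub in abundance.groupby("cn"):
        a = sub.loc[sub["group"] == group_a, "abundance"]
        b = sub.loc[sub["group"] == group_b, "abundance"]
        # donors without the CN have abundance 0
        n_a = abundance.loc[abundance["group"] == group_a, "donor_id"].nunique()
        n_b = abundance.loc[abundance["group"] == group_b, "donor_id"].nunique()
        av = np.concatenate([a.to_numpy(), np.zeros(n_a - len(a))])
        bv = np.concatenate([b.to_numpy(), np.zeros(n_b - len(b))])
        mean_a = av.mean() if len(av) else np.nan
        mean_b = bv.mean() if len(bv) else np.nan
        fold = mean_a / mean_b if mean_b and mean_b > 0 else np.inf
        if len(av) and len(bv) and (np.ptp(np.concatenate([av, bv])) > 0):
            p = float(mannwhitneyu(av, bv, alternative="two-sided").pvalue)
        else:
            p = 1.0
        contrast_rows.append({"cn": cn, f"mean_{group_a}": mean_a,
                              f"mean_{group_b}": mean_b, "fold_change": fold,
                              "pvalue": p})
    contrast = (pd.DataFrame(contrast_rows)
                .sort_values("fold_change", ascending=False)
                .reset_index(drop=True))
    return abundance, contrast
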