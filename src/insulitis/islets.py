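"""Islet detection from spatial composition windows.

Each cell's window is its 20 nearest spatial neighbours (excluding itself,
never crossing donors); windows are clustered with mini-batch k-means
(k=200) on their cell-type composition with the alpha/beta/delta types
merged into one endocrine class.  Clusters whose mean endocrine window
fraction exceeds a threshold define the islet region; individual islets are
the connected components of a symmetric k=5 kNN graph over region cells,
discarding components below ten cells.  Islet features are
log1p(count / n_endocrine) of every non-endocrine type inside the islet or
within a 20 µm band of its boundary, where the boundary distance of a cell
is its distance to the nearest islet member cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import MiniBatchKMeans

from ._knn import connected_component_labels, knn_indices, symmetric_knn_graph
from .synthetic import CellTypeVocabulary, default_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "Windows",
    "IsletInstance",
    "IsletFeatureMatrix",
    "compute_windows",
    "detect_islet_region",
    "extract_islets",
    "assign_to_nearest_islet",
    "islet_composition_features",
    "swath_composition",
]


@dataclass
class Windows:
    """kNN windows for every cell: neighbour row positions (into the same
    table) and per-window cell-type composition counts (each row sums to k)."""

    cell_ids: np.ndarray
    donor_ids: np.ndarray
    neighbor_pos: np.ndarray        # (n, k) row positions into the originating table
    composition: pd.DataFrame       # index aligned with cell order, columns = (merged) types
    k: int
    merge_endocrine: bool


def compute_windows(
    table: pd.DataFrame,
    k: int = 20,
    merge_endocrine: bool = True,
    vocabulary: CellTypeVocabulary | None = None,
    donor_col: str = "donor_id",
) -> Windows:
    """Window of the k nearest spatial neighbours of every cell.

    Neighbour search is Euclidean in µm, excludes the index cell, never
    crosses donors, and breaks distance ties by cell id.
    """
    voc = default_vocabulary() if vocabulary is None else vocabulary
    type_names = voc.merged_names if merge_endocrine else voc.names
    type_index = {t: i for i, t in enumerate(type_names)}
    types = table["cell_type"].astype(str).to_numpy()
    if merge_endocrine:
        types = np.array([voc.merged(t) for t in types], dtype=object)
    codes = np.array([type_index[t] for t in types])

    n = len(table)
    neighbor_pos = np.empty((n, k), dtype=np.int64)
    for donor, idx in table.groupby(donor_col, observed=True).indices.items():
        if len(idx) <= k:
            raise ValueError(f"donor {donor!r} has {len(idx)} cells; need more than k={k}")
        coords = table.iloc[idx][["x_um", "y_um"]].to_numpy(dtype=float)
        ids = table.iloc[idx]["cell_id"].to_numpy()
        local = knn_indices(coords, k, order_key=ids)
        neighbor_pos[idx] = np.asarray(idx)[local]

    comp = np.zeros((n, len(type_names)), dtype=np.int32)
    rows = np.repeat(np.arange(n), k)
    np.add.at(comp, (rows, codes[neighbor_pos.ravel()]), 1)
    composition = pd.DataFrame(comp, columns=list(type_names))
    return Windows(
        cell_ids=table["cell_id"].to_numpy(),
        donor_ids=table[donor_col].to_numpy(),
        neighbor_pos=neighbor_pos,
        composition=composition,
        k=k,
        merge_endocrine=merge_endocrine,
    )


def window_kmeans(windows: Windows, n_clusters: int, seed: int) -> np.ndarray:
    """Mini-batch k-means labels on window composition counts (batch size
    1024, best of 3 restarts by inertia)."""
    X = windows.composition.to_numpy(dtype=float)
    if n_clusters > len(X):
        raise ValueError(f"n_clusters={n_clusters} exceeds number of cells {len(X)}")
    km = MiniBatchKMeans(n_clusters=n_clusters, batch_size=1024, n_init=3,
                         random_state=seed)
    return km.fit_predict(X)


def detect_islet_region(
    windows: Windows,
    n_clusters: int = 200,
    endocrine_fraction_threshold: float = 0.5,
    seed: int = 0,
    endocrine_label: str = "Endocrine",
) -> np.ndarray:
    """Cell ids of the islet region: union of window-composition clusters
    whose mean endocrine window fraction exceeds the threshold."""
    if not windows.merge_endocrine:
        raise ValueError("islet detection requires endocrine-merged windows")
    labels = window_kmeans(windows, min(n_clusters, len(windows.cell_ids)), seed)
    endo_frac = windows.composition[endocrine_label].to_numpy(dtype=float) / windows.k
    cluster_mean = pd.Series(endo_frac).groupby(labels).mean()
    good = cluster_mean[cluster_mean > endocrine_fraction_threshold].index
    mask = np.isin(labels, good)
    if not mask.any() and endo_frac.sum() > 0:
        logger.warning("no window cluster exceeded the endocrine threshold; empty islet region")
    return windows.cell_ids[mask]


@dataclass
class IsletInstance:
    """A connected set of islet-region cells (one donor)."""

    islet_id: str
    donor_id: str
    cell_ids: np.ndarray
    inside_counts: pd.Series          # per fine cell type
    band_counts: pd.Series | None = None
    centroid: tuple[float, float] = (np.nan, np.nan)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_endocrine(self) -> int:
        return int(self.inside_counts.get("Alpha", 0) + self.inside_counts.get("Beta", 0)
                   + self.inside_counts.get("Delta", 0))

    @property
    def n_beta(self) -> int:
        return int(self.inside_counts.get("Beta", 0))


def extract_islets(
    table: pd.DataFrame,
    region_cell_ids: np.ndarray,
    adjacency_k: int = 5,
    min_cells: int = 10,
    donor_col: str = "donor_id",
) -> list[IsletInstance]:
    """Islets = connected components (>= min_cells) of the symmetric
    adjacency_k-NN graph over islet-region cells, per donor."""
    region = table[table["cell_id"].isin(region_cell_ids)]
    islets: list[IsletInstance] = []
    for donor, sub in region.groupby(donor_col, observed=True):
        n = len(sub)
        if n == 0:
            continue
        coords = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        if n == 1:
            comp = np.zeros(1, dtype=int)
        else:
            k = min(adjacency_k, n - 1)
            adj = symmetric_knn_graph(coords, k, order_key=ids)
            comp = connected_component_labels(adj)
        counter = 0
        for c in np.unique(comp):
            members = np.flatnonzero(comp == c)
            if len(members) < min_cells:
                continue
            mem = sub.iloc[members]
            counts = mem["cell_type"].astype(str).value_counts()
            islets.append(IsletInstance(
                islet_id=f"{donor}-{counter}",
                donor_id=str(donor),
                cell_ids=mem["cell_id"].to_numpy(),
                inside_counts=counts,
                centroid=(float(mem["x_um"].mean()), float(mem["y_um"].mean())),
            ))
            counter += 1
    return islets


def assign_to_nearest_islet(
    table: pd.DataFrame,
    islets: list[IsletInstance],
    donor_col: str = "donor_id",
) -> pd.DataFrame:
    """For every extra-islet cell, its nearest islet and the distance to that
    islet's boundary (distance to the nearest member cell).

    Returns a frame (cell_id, islet_id, distance) for all cells that belong
    to no islet, in donors that have at least one islet.
    """
    member_ids = (np.concatenate([i.cell_ids for i in islets])
                  if islets else np.empty(0, dtype=object))
    is_member = table["cell_id"].isin(member_ids).to_numpy()
    frames = []
    for donor, sub in table.groupby(donor_col, observed=True):
        donor_islets = [i for i in islets if i.donor_id == str(donor)]
        if not donor_islets:
            continue
        loc = table.index.get_indexer(sub.index)
        extra = sub[~is_member[loc]]
        if extra.empty:
            continue
        pts = extra[["x_um", "y_um"]].to_numpy(dtype=float)
        dists = np.full((len(donor_islets), len(extra)), np.inf)
        for r, islet in enumerate(donor_islets):
            mem = sub[sub["cell_id"].isin(islet.cell_ids)][["x_um", "y_um"]].to_numpy(dtype=float)
            dists[r] = cKDTree(mem).query(pts)[0]
        nearest = dists.argmin(axis=0)
        frames.append(pd.DataFrame({
            "cell_id": extra["cell_id"].to_numpy(),
            "islet_id": [donor_islets[r].islet_id for r in nearest],
            "distance": dists[nearest, np.arange(len(extra))],
        }))
    if not frames:
        return pd.DataFrame(columns=["cell_id", "islet_id", "distance"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class IsletFeatureMatrix:
    """log1p((inside + band count) / n_endocrine) per islet and non-endocrine
    cell type, plus per-islet metadata."""

    features: pd.DataFrame   # index = islet_id, columns = non-endocrine types
    meta: pd.DataFrame       # index = islet_id: donor_id, group, n_cells, n_endocrine,
                             # n_beta, cd8_count, mac_count (inside + band)


def islet_composition_features(
    islets: list[IsletInstance],
    table: pd.DataFrame,
    band_um: float = 20.0,
    vocabulary: CellTypeVocabulary | None = None,
) -> IsletFeatureMatrix:
    """Composition features per islet.

    Band cells are extra-islet cells within ``band_um`` of the islet
    boundary; a cell in reach of several islets counts only for its nearest
    one.  Raises if any islet lacks endocrine cells.
    """
    voc = default_vocabulary() if vocabulary is None else vocabulary
    for islet in islets:
        if islet.n_endocrine < 1:
            raise ValueError(f"islet {islet.islet_id} has no endocrine cells")
    non_endo = [t for t in voc.names if t not in voc.endocrine_types]

    nearest = assign_to_nearest_islet(table, islets)
    band = nearest[nearest["distance"] <= band_um]
    type_of = table.set_index("cell_id")["cell_type"].astype(str)
    group_of = (table.set_index("cell_id")["group"]
                if "group" in table.columns else None)

    feat_rows, meta_rows = [], []
    for islet in islets:
        band_ids = band.loc[band["islet_id"] == islet.islet_id, "cell_id"]
        band_counts = type_of.loc[band_ids].value_counts()
        islet.band_counts = band_counts
        total = islet.inside_counts.add(band_counts, fill_value=0)
        feats = {t: np.log1p(total.get(t, 0) / islet.n_endocrine) for t in non_endo}
        feat_rows.append(pd.Series(feats, name=islet.islet_id))
        grp = ""
        if group_of is not None:
            grp = str(group_of.loc[islet.cell_ids[0]])
        meta_rows.append(pd.Series({
            "donor_id": islet.donor_id,
            "group": grp,
            "n_cells": islet.n_cells,
            "n_endocrine": islet.n_endocrine,
            "n_beta": islet.n_beta,
            "cd8_count": int(total.get("CD8 T", 0)),
            "mac_count": int(total.get("Macrophage/DC", 0)),
        }, name=islet.islet_id))
    features = pd.DataFrame(feat_rows)
    meta = pd.DataFrame(meta_rows)
    return IsletFeatureMatrix(features=features, meta=meta)


def swath_composition(
    islets: list[IsletInstance],
    table: pd.DataFrame,
    bands: list[tuple[float, float]] = [(0.0, 25.0), (25.0, 50.0), (50.0, 100.0)],
    vocabulary: CellTypeVocabulary | None = None,
    donor_col: str = "donor_id",
) -> pd.DataFrame:
    """Cell-type fractions in annular swaths around each islet.

    Bands are half-open [lo, hi) distances (µm) from the islet boundary; a
    cell is binned by its distance to the nearest member cell of the islet
    in question.  Only extra-islet cells are counted.  Fractions in each
    non-empty (islet, band) row sum to 1; empty rows are flagged.
    """
    for (lo1, hi1) in bands:
        if hi1 <= lo1:
            raise ValueError(f"invalid band ({lo1}, {hi1})")
    for a, b in zip(bands, bands[1:]):
        if b[0] < a[1] and a[0] < b[1]:
            raise ValueError(f"overlapping bands {a} and {b}")
    voc = default_vocabulary() if vocabulary is None else vocabulary
    member_ids = (np.concatenate([i.cell_ids for i in islets])
                  if islets else np.empty(0, dtype=object))
    is_member = table["cell_id"].isin(member_ids).to_numpy()

    rows = []
    for donor, sub in table.groupby(donor_col, observed=True):
        donor_islets = [i for i in islets if i.donor_id == str(donor)]
        if not donor_islets:
            continue
        loc = table.index.get_indexer(sub.index)
        extra = sub[~is_member[loc]]
        pts = extra[["x_um", "y_um"]].to_numpy(dtype=float)
        extra_types = extra["cell_type"].astype(str).to_numpy()
        for islet in donor_islets:
            mem = sub[sub["cell_id"].isin(islet.cell_ids)][["x_um", "y_um"]].to_numpy(dtype=float)
            d = cKDTree(mem).query(pts)[0] if len(pts) else np.empty(0)
            for lo, hi in bands:
                in_band = (d >= lo) & (d < hi)
                n_band = int(in_band.sum())
                frac = {}
                for t in voc.names:
                    frac[t] = (float((extra_types[in_band] == t).sum()) / n_band
                               if n_band else 0.0)
                rows.append({"islet_id": islet.islet_id, "donor_id": islet.donor_id,
                             "band_lo": lo, "band_hi": hi, "n_cells": n_band,
                             "empty": n_band == 0, **frac})
    return pd.DataFrame(rows)
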