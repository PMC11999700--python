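"""Sub-states of inflamed islets from CD8+T cell marker frequencies.

For each inflamed islet the fraction of its CD8+T cells (inside the islet or
within 20 µm of its boundary) positive for each functional marker is
computed; the islet x marker frequency matrix is column z-normalised and
Leiden-clustered into sub-states.  Islet-vs-swath enrichment pools CD8 cells
within each donor, takes per-marker frequency differences, and tests them
across donors with the two-sided Wilcoxon signed-rank test (no multiplicity
correction by default, with an optional Benjamini-Hochberg adjustment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from ._knn import leiden_cluster
from .islets import IsletInstance, assign_to_nearest_islet
from .synthetic import FUNCTIONAL_MARKERS

logger = logging.getLogger(__name__)

__all__ = ["SubstateMatrix", "cd8_marker_frequencies", "cluster_substates",
           "enrichment_vs_swaths"]


@dataclass
class SubstateMatrix:
    """Inflamed islets x markers CD8 positivity frequencies."""

    frequencies: pd.DataFrame          # index = islet_id, values in [0, 1]
    n_cd8: pd.Series                   # CD8 cells per islet (inside + band)
    donor: pd.Series                   # donor per islet
    excluded: list[str] = field(default_factory=list)  # islets below the CD8 floor
    cd8_cells: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def cd8_marker_frequencies(
    islets: list[IsletInstance],
    table: pd.DataFrame,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    band_um: float = 20.0,
    min_cd8: int = 1,
    cd8_type: str = "CD8 T",
) -> SubstateMatrix:
    """Per-islet marker-positivity frequencies of CD8+T cells.

    CD8 cells inside the islet and within ``band_um`` of its boundary are
    combined before the frequency is measured.  ``table`` must carry the
    gated ``pos_<marker>`` columns.  Islets with fewer than ``min_cd8`` CD8
    cells are excluded and listed.
    """
    if not islets:
        raise ValueError("no islets supplied")
    for m in markers:
        if f"pos_{m}" not in table.columns:
            raise ValueError(f"missing gated column pos_{m}; run gating first")
    indexed = table.set_index("cell_id")
    nearest = assign_to_nearest_islet(table, islets)
    band = nearest[nearest["distance"] <= band_um]

    rows, n_cd8, donors, excluded = [], {}, {}, []
    cd8_cells: dict[str, np.ndarray] = {}
    for islet in islets:
        inside = indexed.loc[islet.cell_ids]
        inside_cd8 = inside[inside["cell_type"].astype(str) == cd8_type]
        band_ids = band.loc[band["islet_id"] == islet.islet_id, "cell_id"]
        band_cells = indexed.loc[band_ids]
        band_cd8 = band_cells[band_cells["cell_type"].astype(str) == cd8_type]
        cd8 = pd.concat([inside_cd8, band_cd8])
        if len(cd8) < min_cd8:
            excluded.append(islet.islet_id)
            continue
        freq = {m: float(cd8[f"pos_{m}"].mean()) for m in markers}
        rows.append(pd.Series(freq, name=islet.islet_id))
        n_cd8[islet.islet_id] = len(cd8)
        donors[islet.islet_id] = islet.donor_id
        cd8_cells[islet.islet_id] = cd8.index.to_numpy()
    freqs = pd.DataFrame(rows, columns=list(markers))
    return SubstateMatrix(
        frequencies=freqs,
        n_cd8=pd.Series(n_cd8, dtype=int),
        donor=pd.Series(donors, dtype=object),
        excluded=excluded,
        cd8_cells=cd8_cells,
    )


def cluster_substates(
    matrix: SubstateMatrix | pd.DataFrame,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Leiden sub-state labels on the column-z-normalised frequency matrix.

    Returns (labels, per-substate mean marker-frequency profiles).  Constant
    columns carry no information and are set to zero after centring.
    """
    freqs = matrix.frequencies if isinstance(matrix, SubstateMatrix) else matrix
    if len(freqs) < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} islets, got {len(freqs)}")
    sd = freqs.std(ddof=1)
    z = (freqs - freqs.mean()).div(sd.where(sd > 0, 1.0))
    labels = leiden_cluster(z.to_numpy(dtype=float), n_neighbors=n_neighbors,
                            resolution=resolution, seed=seed)
    labels = pd.Series(labels, index=freqs.index, name="substate")
    profiles = freqs.groupby(labels).mean()
    return labels, profiles


def _pooled_frequencies(
    table_indexed: pd.DataFrame,
    cell_ids_by_donor: dict[str, np.ndarray],
    markers: tuple[str, ...],
) -> pd.DataFrame:
    rows = {}
    for donor, ids in cell_ids_by_donor.items():
        cells = table_indexed.loc[ids]
        rows[donor] = {m: float(cells[f"pos_{m}"].mean()) if len(cells) else np.nan
                       for m in markers}
    return pd.DataFrame(rows).T


def enrichment_vs_swaths(
    islet_freqs: pd.DataFrame,
    swath_freqs: pd.DataFrame,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    correct: bool = False,
) -> pd.DataFrame:
    """Islet-minus-swath marker frequency differences across paired donors.

    Both inputs are donor x marker frequency tables with CD8 cells pooled
    within each donor before the frequency is taken.  Per marker the paired
    differences are tested with the two-sided Wilcoxon signed-rank test
    (zero differences dropped, exact null distribution for n <= 25).
    P-values are reported raw; ``correct=True`` adds a Benjamini-Hochberg
    column.
    """
    donors = islet_freqs.index.intersection(swath_freqs.index)
    rows = []
    for m in markers:
        d = (islet_freqs.loc[donors, m] - swath_freqs.loc[donors, m]).dropna()
        n = len(d)
        nonzero = d[d != 0]
        if n < 3:
            logger.warning("marker %s: only %d paired donors; test skipped", m, n)
            stat, p = np.nan, np.nan
        elif len(nonzero) == 0:
            stat, p = 0.0, 1.0
        else:
            # method='auto' is exact for small samples without ties/zeros
            res = wilcoxon(d.to_numpy(), zero_method="wilcox",
                           alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"marker": m, "n_donors": n, "mean_difference": float(d.mean()) if n else np.nan,
                     "statistic": stat, "pvalue": p})
    out = pd.DataFrame(rows)
    if correct:
        from statsmodels.stats.multitest import multipletests
        mask = out["pvalue"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(out.loc[mask, "pvalue"], method="fdr_bh")[1]
        out["pvalue_bh"] = adj
    return out


def donor_pooled_cd8_frequencies(
    table: pd.DataFrame,
    islets: list[IsletInstance],
    islet_ids: list[str] | None = None,
    band_um: float = 20.0,
    swath: tuple[float, float] | None = None,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    cd8_type: str = "CD8 T",
) -> pd.DataFrame:
    """Donor x marker CD8 positivity frequencies, pooling cells across the
    selected islets within each donor.

    With ``swath=None`` the islet compartment is used (inside + band_um
    band); with ``swath=(lo, hi)`` the CD8 cells in that half-open distance
    band from the islet boundary are pooled instead.
    """
    indexed = table.set_index("cell_id")
    keep = set(islet_ids) if islet_ids is not None else {i.islet_id for i in islets}
    sel = [i for i in islets if i.islet_id in keep]
    nearest = assign_to_nearest_islet(table, islets)
    pooled: dict[str, list] = {}
    for islet in sel:
        if swath is None:
            inside = indexed.loc[islet.cell_ids]
            ids1 = inside[inside["cell_type"].astype(str) == cd8_type].index.to_numpy()
            near = nearest[(nearest["islet_id"] == islet.islet_id)
                           & (nearest["distance"] <= band_um)]
            cells = indexed.loc[near["cell_id"]]
            ids2 = cells[cells["cell_type"].astype(str) == cd8_type].index.to_numpy()
            ids = np.concatenate([ids1, ids2])
        else:
            lo, hi = swath
            near = nearest[(nearest["islet_id"] == islet.islet_id)
                           & (nearest["distance"] >= lo) & (nearest["distance"] < hi)]
            cells = indexed.loc[near["cell_id"]]
            ids = cells[cells["cell_type"].astype(str) == cd8_type].index.to_numpy()
        pooled.setdefault(islet.donor_id, []).append(ids)
    by_donor = {d: np.concatenate(v) if v else np.empty(0) for d, v in pooled.items()}
    return _pooled_frequencies(indexed, by_donor, markers)
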