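"""Per-donor marker normalisation, unsupervised cell typing with automated
signature-based annotation, and percentile-threshold marker gating.

The typing path is: z-normalise markers within each donor, Leiden-cluster the
cells on a Euclidean kNN graph of the z-scores, then assign each cluster the
cell type whose marker signature best matches the cluster's mean z-profile.
Marker positivity is gated at the 99th percentile of a background
distribution pooled from cell types known not to express the marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._knn import leiden_cluster
from .synthetic import (
    FUNCTIONAL_MARKERS,
    LINEAGE_MARKERS,
    CellTypeVocabulary,
    default_vocabulary,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "GateResult",
    "default_signature_matrix",
    "znormalize_markers",
    "cluster_cell_types",
    "annotate_clusters",
    "type_cells",
    "gate_marker_positivity",
    "gate_all_markers",
]


@dataclass
class SignatureMatrix:
    """Expected marker behaviour per cell type: +1 high, -1 low, 0 uninformative."""

    table: pd.DataFrame  # rows = cell types, columns = markers, entries in {-1, 0, +1}

    def __post_init__(self):
        if self.table.empty:
            raise ValueError("signature matrix is empty")
        bad = ~self.table.isin([-1, 0, 1]).all(axis=None)
        if bad:
            raise ValueError("signature entries must be -1, 0 or +1")
        if (self.table == 1).sum(axis=1).min() < 1:
            raise ValueError("every cell type needs at least one +1 marker")

    @property
    def cell_types(self) -> list[str]:
        return list(self.table.index)

    @property
    def markers(self) -> list[str]:
        return list(self.table.columns)


def default_signature_matrix(vocabulary: CellTypeVocabulary | None = None) -> SignatureMatrix:
    """Signatures from the characteristic lineage markers of the default
    vocabulary, with expected-low entries that anchor the broad lineages:
    immune types are epithelial-marker negative, non-immune types are
    negative for the clean immune lineage markers, and GzmB+CD3- expects
    CD3 low."""
    voc = default_vocabulary() if vocabulary is None else vocabulary
    markers = list(dict.fromkeys(m for ms in LINEAGE_MARKERS.values() for m in ms))
    tab = pd.DataFrame(0, index=list(voc.names), columns=markers, dtype=int)
    immune = set(voc.immune_types)
    epithelial_neg = [m for m in ("Amylase", "Cytokeratin") if m in markers]
    for t in voc.names:
        if t in immune:
            for m in epithelial_neg:
                tab.loc[t, m] = -1
        else:
            # structural and endocrine types are CD45-negative; every type
            # except acinar/ductal is negative for the other's epithelial marker
            if "CD45" in markers:
                tab.loc[t, "CD45"] = -1
            for m in epithelial_neg:
                if m not in LINEAGE_MARKERS.get(t, ()):
                    tab.loc[t, m] = -1
        for m in LINEAGE_MARKERS.get(t, ()):
            tab.loc[t, m] = 1
    if "GzmB+CD3-" in tab.index and "CD3" in tab.columns:
        tab.loc["GzmB+CD3-", "CD3"] = -1
    return SignatureMatrix(tab)


def znormalize_markers(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    donor_col: str = "donor_id",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Z-normalise each marker column within each donor (ddof=1).

    ``log_transform=True`` applies log1p before standardising — the usual
    variance-stabilising step for right-skewed fluorescence intensities,
    used by the cell-typing path.  Returns a copy; raises if any marker is
    constant within a donor, naming the donor and marker.
    """
    if markers is None:
        markers = [c for c in table.columns
                   if c not in ("cell_id", donor_col, "group", "x_um", "y_um", "cell_type")
                   and pd.api.types.is_numeric_dtype(table[c])]
    out = table.copy()
    if log_transform:
        out[markers] = np.log1p(out[markers])
    for donor, idx in out.groupby(donor_col, observed=True).groups.items():
        sub = out.loc[idx, markers]
        if len(idx) < 2:
            raise ValueError(f"donor {donor!r} has fewer than 2 cells")
        sd = sub.std(ddof=1)
        zero = sd[sd == 0]
        if len(zero):
            raise ValueError(
                f"zero-variance marker {zero.index[0]!r} within donor {donor!r}")
        out.loc[idx, markers] = (sub - sub.mean()) / sd
    return out


def cluster_cell_types(
    table: pd.DataFrame,
    markers: list[str],
    n_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden cluster labels on the Euclidean kNN graph of z-scored markers."""
    X = table[markers].to_numpy(dtype=float)
    if len(X) < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} cells, got {len(X)}")
    return leiden_cluster(X, n_neighbors=n_neighbors, resolution=resolution,
                          seed=seed, metric="euclidean")


def annotate_clusters(
    labels: np.ndarray,
    table: pd.DataFrame,
    signatures: SignatureMatrix,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cluster the signature type maximising
    sum_m signature[type, m] * mean_z[cluster, m].

    Ties are broken by signature row order and flagged.  Returns the per-cell
    type series plus a per-cluster report (cluster, cell_type, score, tie).
    """
    labels = np.asarray(labels)
    z = table[signatures.markers].to_numpy(dtype=float)
    sig = signatures.table.to_numpy(dtype=float)
    rows = []
    assignment: dict[int, str] = {}
    for cl in np.unique(labels):
        mean_z = z[labels == cl].mean(axis=0)
        scores = sig @ mean_z
        best = int(np.argmax(scores))  # argmax returns the first maximum: row-order tie-break
        tie = bool(np.sum(scores == scores[best]) > 1)
        assignment[int(cl)] = signatures.cell_types[best]
        rows.append((int(cl), signatures.cell_types[best], float(scores[best]), tie))
    report = pd.DataFrame(rows, columns=["cluster", "cell_type", "score", "tie"])
    per_cell = pd.Series([assignment[int(c)] for c in labels],
                         index=table.index, name="cell_type")
    return per_cell, report


def type_cells(
    table: pd.DataFrame,
    signatures: SignatureMatrix | None = None,
    vocabulary: CellTypeVocabulary | None = None,
    resolution: float = 0.5,
    n_neighbors: int = 30,
    immune_resolution: float = 1.0,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Two-pass unsupervised cell typing.

    First pass: Leiden on donor-z-normalised log intensities of all
    signature markers, annotated against the signature matrix.  Second
    pass: cells annotated as immune types are re-clustered on the immune
    markers alone (re-standardised within the immune subset, where the
    lineages are balanced) and re-annotated against the immune signature
    rows — the same refinement step used for dense immune compartments in
    multiplexed imaging, where a single coarse cluster mixes immune
    lineages.  Returns (cell types, combined per-cluster report).
    """
    voc = default_vocabulary() if vocabulary is None else vocabulary
    sig = default_signature_matrix(voc) if signatures is None else signatures
    z = znormalize_markers(table, sig.markers, log_transform=True)
    labels = cluster_cell_types(z, sig.markers, n_neighbors=n_neighbors,
                                resolution=resolution, seed=seed)
    types, report = annotate_clusters(labels, z, sig)

    immune = set(voc.immune_types)
    imm_mask = types.isin(immune).to_numpy()
    if imm_mask.sum() >= n_neighbors + 1:
        imm_rows = [t for t in sig.cell_types if t in immune]
        imm_markers = sorted(
            {m for t in imm_rows for m, v in sig.table.loc[t].items() if v == 1})
        sub = table.loc[imm_mask]
        # re-standardise within the immune subset: lineage prevalences are
        # balanced there, so positive populations separate cleanly
        sub_z = znormalize_markers(sub, imm_markers, log_transform=True)
        sub_labels = cluster_cell_types(sub_z, imm_markers,
                                        n_neighbors=min(n_neighbors, 15),
                                        resolution=immune_resolution, seed=seed)
        imm_sig = SignatureMatrix(sig.table.loc[imm_rows, imm_markers])
        sub_types, sub_report = annotate_clusters(sub_labels, sub_z, imm_sig)
        types = types.copy()
        types.loc[imm_mask] = sub_types.to_numpy()
        sub_report["cluster"] = [f"immune/{c}" for c in sub_report["cluster"]]
        report = pd.concat([report, sub_report], ignore_index=True)
    return types, report


@dataclass
class GateResult:
    """A 99th-percentile positivity gate for one marker."""

    marker: str
    background_types: list[str]
    thresholds: dict[str, float]          # donor -> threshold (or {"pooled": t})
    positive: pd.Series = field(repr=False)  # per-cell boolean, indexed like the input table

    @property
    def threshold(self) -> float:
        if len(self.thresholds) != 1:
            raise ValueError("multiple per-donor thresholds; inspect .thresholds")
        return next(iter(self.thresholds.values()))

    def to_json_dict(self) -> dict:
        return {"marker": self.marker, "background_types": self.background_types,
                "thresholds": self.thresholds}


def gate_marker_positivity(
    table: pd.DataFrame,
    marker: str,
    background_types: list[str],
    per_donor: bool = True,
    percentile: float = 99.0,
    min_background: int = 100,
    donor_col: str = "donor_id",
) -> GateResult:
    """Gate a marker at the 99th percentile of its background distribution.

    The background pools the intensities of ``background_types`` (cell types
    known not to express the marker), by default within each donor.  A cell
    is positive iff its intensity is strictly greater than the threshold; a
    cell exactly at the threshold is negative.  The percentile uses linear
    interpolation between order statistics.
    """
    if marker not in table.columns:
        raise KeyError(f"marker {marker!r} not in table")
    is_bg = table["cell_type"].isin(background_types).to_numpy()
    if not is_bg.any():
        raise ValueError(f"no background cells for marker {marker!r}")
    positive = pd.Series(False, index=table.index)
    thresholds: dict[str, float] = {}
    if per_donor:
        groups = table.groupby(donor_col, observed=True).groups.items()
    else:
        groups = [("pooled", table.index)]
    for donor, idx in groups:
        loc = table.index.get_indexer(idx)
        bg_vals = table[marker].to_numpy()[loc][is_bg[loc]]
        if len(bg_vals) == 0:
            raise ValueError(f"no background cells for {marker!r} in donor {donor!r}")
        if len(bg_vals) < min_background:
            logger.warning("background for %s in %s has only %d cells (< %d)",
                           marker, donor, len(bg_vals), min_background)
        thr = float(np.percentile(bg_vals, percentile))  # type-7 linear interpolation
        thresholds[str(donor)] = thr
        positive.loc[idx] = table.loc[idx, marker] > thr
    return GateResult(marker=marker, background_types=list(background_types),
                      thresholds=thresholds, positive=positive)


def gate_all_markers(
    table: pd.DataFrame,
    background_types: list[str] | None = None,
    markers: tuple[str, ...] = FUNCTIONAL_MARKERS,
    per_donor: bool = True,
) -> pd.DataFrame:
    """Gate every functional marker; returns a copy of the table with one
    boolean ``pos_<marker>`` column per marker.

    The default background pools the non-immune, non-endocrine structural
    types (acinar, ductal/epithelial, stroma, nerve), which do not express
    T-cell functional markers.
    """
    if background_types is None:
        background_types = ["Acinar", "Ductal/Epithelial", "Stroma", "Nerve"]
    out = table.copy()
    for m in markers:
        res = gate_marker_positivity(table, m, background_types, per_donor=per_donor)
        out[f"pos_{m}"] = res.positive
    return out
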