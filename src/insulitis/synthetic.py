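"""Ground-truthed synthetic pancreas tissue.

Emulates the statistical structure that the downstream stages assume: islets
as dense endocrine blobs whose beta-cell fraction and immune infiltration
follow a planted disease stage, lobules as a Voronoi partition with tunable
between-lobule stage variance (a target intraclass correlation), planted
B-cell/CD8 aggregates adjacent to vasculature-rich patches, and marker
intensities drawn from a right-skewed background plus a shifted positive
component with stage-dependent positivity probabilities.

Every cell, islet, lobule and niche carries ground-truth labels so islet
detection, pseudotime ordering, sub-state clustering, neighborhood naming and
the hierarchical lobular models can all be scored against planted truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.strtree import STRtree

__all__ = [
    "GROUPS",
    "STAGE_NORMAL",
    "STAGE_INFLAMED",
    "STAGE_DEPLETED",
    "STAGE_DEPLETED_IMMUNE",
    "FUNCTIONAL_MARKERS",
    "LINEAGE_MARKERS",
    "CellTypeVocabulary",
    "MarkerParams",
    "SyntheticConfig",
    "LobulePartition",
    "GroundTruth",
    "default_vocabulary",
    "make_lobule_partition",
    "generate_tissue",
    "sample_marker_intensity",
    "sample_islet_stages",
    "sample_substate_matrix",
]

GROUPS = ("nonT1D", "AA+", "T1D")

STAGE_NORMAL = "Normal"
STAGE_INFLAMED = "Inflamed"
STAGE_DEPLETED = "InsulinDepleted"
STAGE_DEPLETED_IMMUNE = "InsulinDepletedImmune"

#: functional markers gated against a background distribution
FUNCTIONAL_MARKERS = (
    "CD45RA", "CD45RO", "PD-1", "LAG-3", "ICOS",
    "Granzyme-B", "CD57", "CD69", "TOX", "CD44",
)

#: characteristic lineage marker(s) per cell type, used both to draw
#: intensities and to build the default annotation signature matrix
LINEAGE_MARKERS: Mapping[str, tuple[str, ...]] = {
    "Acinar": ("Amylase",),
    "Ductal/Epithelial": ("Cytokeratin",),
    "Alpha": ("Glucagon",),
    "Beta": ("Proinsulin",),
    "Delta": ("Somatostatin",),
    "CD8 T": ("CD45", "CD3", "CD8"),
    "CD4 T": ("CD45", "CD3", "CD4"),
    "B": ("CD45", "CD20"),
    "Macrophage/DC": ("CD45", "CD68"),
    "Neutrophil": ("CD45", "MPO"),
    "Vasculature": ("CD31",),
    "Nerve": ("PGP9.5",),
    "GzmB+CD3-": ("CD45", "Granzyme-B"),
    "Stroma": ("Vimentin",),
}

ALL_LINEAGE_MARKERS = tuple(dict.fromkeys(m for ms in LINEAGE_MARKERS.values() for m in ms))
ALL_MARKERS = tuple(dict.fromkeys(ALL_LINEAGE_MARKERS + FUNCTIONAL_MARKERS))


@dataclass(frozen=True)
class CellTypeEntry:
    name: str
    is_endocrine: bool = False
    is_acinar: bool = False
    is_epithelial: bool = False
    is_immune: bool = False


@dataclass(frozen=True)
class CellTypeVocabulary:
    """The cell-type universe plus the endocrine merge used downstream."""

    entries: tuple[CellTypeEntry, ...]
    merge_map: Mapping[str, str]

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("cell type names must be unique")
        if sum(e.is_acinar for e in self.entries) != 1:
            raise ValueError("exactly one acinar type required")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    @property
    def endocrine_types(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.is_endocrine)

    @property
    def acinar_type(self) -> str:
        return next(e.name for e in self.entries if e.is_acinar)

    @property
    def epithelial_types(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.is_epithelial)

    @property
    def immune_types(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries if e.is_immune)

    def merged(self, cell_type: str) -> str:
        return self.merge_map.get(cell_type, cell_type)

    @property
    def merged_names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.merged(n) for n in self.names))


def default_vocabulary() -> CellTypeVocabulary:
    e = CellTypeEntry
    return CellTypeVocabulary(
        entries=(
            e("Acinar", is_acinar=True),
            e("Ductal/Epithelial", is_epithelial=True),
            e("Alpha", is_endocrine=True),
            e("Beta", is_endocrine=True),
            e("Delta", is_endocrine=True),
            e("CD8 T", is_immune=True),
            e("CD4 T", is_immune=True),
            e("B", is_immune=True),
            e("Macrophage/DC", is_immune=True),
            e("Neutrophil", is_immune=True),
            e("Vasculature"),
            e("Nerve"),
            e("GzmB+CD3-", is_immune=True),
            e("Stroma"),
        ),
        merge_map={"Alpha": "Endocrine", "Beta": "Endocrine", "Delta": "Endocrine"},
    )


@dataclass(frozen=True)
class MarkerParams:
    """Lognormal intensity model: ``scale * exp(mu [+ shift] + sigma * Z)``.

    The positive component shifts the log-location by ``pos_shift`` so it
    stochastically dominates the background.  ``bg_scale=0`` degenerates to a
    point mass at zero (useful in tests).
    """

    bg_scale: float = 1.0
    bg_mu: float = 0.0
    bg_sigma: float = 0.5
    pos_shift: float = 2.0


def _default_substate_profiles() -> dict[str, dict[str, float]]:
    base = {m: 0.05 for m in FUNCTIONAL_MARKERS}
    quiescent = dict(base)
    naive = dict(base, **{"CD45RA": 0.8})
    memory = dict(base, **{"CD45RO": 0.8, "PD-1": 0.7, "TOX": 0.3})
    cytotoxic = dict(base, **{"LAG-3": 0.7, "Granzyme-B": 0.75, "ICOS": 0.7, "CD57": 0.6})
    return {
        "quiescent": quiescent,
        "naive-like": naive,
        "memory-exhausted": memory,
        "cytotoxic-activated": cytotoxic,
    }


def _default_background_type_probs() -> dict[str, float]:
    return {
        "Acinar": 0.780,
        "Ductal/Epithelial": 0.080,
        "Stroma": 0.060,
        "Vasculature": 0.040,
        "Nerve": 0.010,
        "CD8 T": 0.005,
        "CD4 T": 0.005,
        "B": 0.003,
        "Macrophage/DC": 0.010,
        "Neutrophil": 0.002,
        "GzmB+CD3-": 0.005,
    }


@dataclass
class SyntheticConfig:
    """Generative parameters; defaults define the standard study conditions."""

    tissue_size: tuple[float, float] = (2000.0, 2000.0)
    n_donors_per_group: int | Mapping[str, int] = 1
    groups: tuple[str, ...] = GROUPS
    n_lobules: int = 9

    # islets
    islets_per_donor: int = 10
    islet_radius_log_mean: float = math.log(58.0)   # human islets: ~100-150 µm diameter
    islet_radius_log_sd: float = 0.20
    islet_cell_density: float = 0.03          # endocrine cells / µm² of core disc
    # fraction of islet-associated immune cells placed in the peri-islet
    # annulus rather than intermixed in the core (insulitis is predominantly
    # peri-insulitis: T cells accumulate at the islet rim)
    band_immune_fraction: float = 0.6

    # disease-stage model (stage_raw = group mean + lobule effect + islet effect)
    group_stage_means: Mapping[str, float] = field(
        default_factory=lambda: {"nonT1D": 0.10, "AA+": 0.30, "T1D": 0.55})
    lobule_stage_var: float = 0.02            # tau*² between lobules
    islet_stage_var: float = 0.02             # sigma*² between islets in a lobule
    normal_stage_max: float = 0.35
    depleted_stage_min: float = 0.70

    # per-stage composition (piecewise-linear in clipped stage)
    beta_fraction_curve: tuple[tuple[float, float], ...] = (
        (0.0, 0.55), (0.5, 0.55), (0.7, 0.0), (1.0, 0.0))
    cd8_per_endocrine_curve: tuple[tuple[float, float], ...] = (
        (0.0, 0.02), (0.35, 0.05), (0.5, 0.30), (0.7, 0.20), (0.85, 0.01), (1.0, 0.01))
    mac_per_endocrine_curve: tuple[tuple[float, float], ...] = (
        (0.0, 0.05), (0.35, 0.10), (0.5, 0.45), (0.7, 0.35), (0.85, 0.03), (1.0, 0.03))
    other_immune_rate: float = 0.02           # CD4 / B per endocrine cell, each
    islet_vasculature_rate: float = 0.03

    # extra-islet background
    background_density: float = 0.004         # cells / µm²
    background_type_probs: Mapping[str, float] = field(
        default_factory=_default_background_type_probs)

    # planted niches
    aggregates_per_donor: int | Mapping[str, int] = 3
    aggregate_radius: float = 40.0
    aggregate_density: float = 0.03
    vasc_patch_radius: float = 35.0
    vasc_patch_density: float = 0.025
    far_patches_per_donor: int = 2
    far_patch_radius: float = 30.0
    far_patch_density: float = 0.025

    # marker model
    marker_defaults: MarkerParams = field(default_factory=MarkerParams)
    marker_overrides: Mapping[str, MarkerParams] = field(default_factory=dict)
    lineage_positive_prob: float = 0.98
    lineage_background_prob: float = 0.002
    functional_background_prob: float = 0.0   # non-immune types
    functional_immune_baseline: float = 0.05  # non-CD8 immune, quiescent CD8
    gzmb_cd3neg_granzyme_prob: float = 0.95
    substate_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_substate_profiles)

    rng_seed: int = 0
    vocabulary: CellTypeVocabulary = field(default_factory=default_vocabulary)

    def validate(self) -> None:
        w, h = self.tissue_size
        if w <= 0 or h <= 0:
            raise ValueError("tissue dimensions must be positive")
        if self.n_lobules < 1:
            raise ValueError("n_lobules must be >= 1")
        if self.lobule_stage_var < 0 or self.islet_stage_var < 0:
            raise ValueError("stage variances must be >= 0")
        for probs in (self.background_type_probs,):
            for t, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"probability out of [0,1] for {t}")
                if t not in self.vocabulary.names:
                    raise ValueError(f"unknown cell type in background probs: {t}")
        for prof in self.substate_profiles.values():
            for m, p in prof.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"substate probability out of [0,1] for {m}")

    def n_donors(self, group: str) -> int:
        if isinstance(self.n_donors_per_group, Mapping):
            return int(self.n_donors_per_group.get(group, 0))
        return int(self.n_donors_per_group)

    def n_aggregates(self, group: str) -> int:
        if isinstance(self.aggregates_per_donor, Mapping):
            return int(self.aggregates_per_donor.get(group, 0))
        return int(self.aggregates_per_donor)

    def marker_params(self, marker: str) -> MarkerParams:
        if marker not in ALL_MARKERS and marker not in self.marker_overrides:
            raise KeyError(f"unknown marker: {marker!r}")
        return self.marker_overrides.get(marker, self.marker_defaults)

    @classmethod
    def monotone_infiltration(cls, **kw) -> "SyntheticConfig":
        """Preset with a monotone infiltration gradient: immune load rises and
        beta fraction falls monotonically with planted stage, non-T1D islets
        sit at the low-stage end (so the non-T1D centroid anchors the
        trajectory start), and islets are few but large so composition
        features carry low counting noise.  The standard benchmark for
        pseudotime ordering."""
        kw.setdefault("beta_fraction_curve", ((0.0, 0.55), (1.0, 0.0)))
        kw.setdefault("cd8_per_endocrine_curve", ((0.0, 0.02), (1.0, 0.45)))
        kw.setdefault("mac_per_endocrine_curve", ((0.0, 0.05), (1.0, 0.60)))
        kw.setdefault("group_stage_means", {"nonT1D": 0.05, "AA+": 0.45, "T1D": 0.85})
        kw.setdefault("lobule_stage_var", 0.01)
        kw.setdefault("islet_stage_var", 0.005)
        kw.setdefault("n_donors_per_group", 2)
        kw.setdefault("islets_per_donor", 7)
        kw.setdefault("islet_radius_log_mean", math.log(75.0))
        return cls(**kw)


# ---------------------------------------------------------------------------
# lobule partition


@dataclass
class LobulePartition:
    """Planar partition of the tissue rectangle into lobule polygons.

    The reserved label ``"edge"`` denotes interlobular space (cells falling on
    no polygon when the partition comes from an external mask)."""

    polygons: list[Polygon]
    lobule_ids: list[int]
    tissue_size: tuple[float, float]

    EDGE_LABEL = "edge"

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": mapping(p), "properties": {"lobule_id": i}}
                for p, i in zip(self.polygons, self.lobule_ids)
            ],
        }

    def save_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict, tissue_size=(0.0, 0.0)) -> "LobulePartition":
        polys, ids = [], []
        for feat in obj["features"]:
            polys.append(shape(feat["geometry"]))
            ids.append(feat["properties"]["lobule_id"])
        return cls(polys, ids, tissue_size)


def make_lobule_partition(config: SyntheticConfig, rng: np.random.Generator) -> LobulePartition:
    """Voronoi tessellation of uniform seed points, clipped to the tissue box.

    Seeds are mirrored across all four edges before the Voronoi construction
    so every clipped cell is finite; the cells tile the rectangle exactly."""
    w, h = config.tissue_size
    n = config.n_lobules
    if w <= 0 or h <= 0 or n < 1:
        raise ValueError("tissue size and n_lobules must be positive")
    rect = box(0.0, 0.0, w, h)
    if n == 1:
        return LobulePartition([rect], [0], (w, h))
    seeds = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    mirrors = [
        seeds * [-1, 1],                      # across x=0
        seeds * [1, -1],                      # across y=0
        np.column_stack([2 * w - seeds[:, 0], seeds[:, 1]]),
        np.column_stack([seeds[:, 0], 2 * h - seeds[:, 1]]),
    ]
    vor = Voronoi(np.vstack([seeds] + mirrors))
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return LobulePartition(polys, list(range(n)), (w, h))


# ---------------------------------------------------------------------------
# stage model


def sample_islet_stages(
    n_lobules: int,
    islets_per_lobule: int,
    tau2: float,
    sigma2: float,
    mu: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Planted stages for a balanced lobule design: stage = mu + b_j + e_ij
    with Var(b)=tau2 between lobules and Var(e)=sigma2 within.  The realized
    intraclass correlation converges to tau2/(tau2+sigma2)."""
    rng = np.random.default_rng() if rng is None else rng
    b = rng.normal(0.0, math.sqrt(tau2), n_lobules)
    rows = []
    for j in range(n_lobules):
        e = rng.normal(0.0, math.sqrt(sigma2), islets_per_lobule)
        for v in e:
            rows.append((j, mu + b[j] + v))
    return pd.DataFrame(rows, columns=["lobule_id", "stage_raw"])


def _curve(points: tuple[tuple[float, float], ...], s: float) -> float:
    xs, ys = zip(*points)
    return float(np.interp(s, xs, ys))


# ---------------------------------------------------------------------------
# marker model


def sample_marker_intensity(
    positive: bool, marker: str, config: SyntheticConfig, rng: np.random.Generator
) -> float:
    """One draw from the marker's background or shifted positive component."""
    p = config.marker_params(marker)
    shift = p.pos_shift if positive else 0.0
    return p.bg_scale * math.exp(p.bg_mu + shift + p.bg_sigma * rng.standard_normal())


def _intensity_column(pos: np.ndarray, marker: str, config: SyntheticConfig,
                      rng: np.random.Generator) -> np.ndarray:
    p = config.marker_params(marker)
    z = rng.standard_normal(len(pos))
    return p.bg_scale * np.exp(p.bg_mu + np.where(pos, p.pos_shift, 0.0) + p.bg_sigma * z)


def _positivity_prob(cell_type: str, marker: str, substate: str,
                     config: SyntheticConfig, voc: CellTypeVocabulary) -> float:
    if marker in FUNCTIONAL_MARKERS:
        if cell_type == "CD8 T":
            prof = config.substate_profiles.get(substate) or config.substate_profiles["quiescent"]
            return prof.get(marker, config.functional_immune_baseline)
        if cell_type == "GzmB+CD3-":
            if marker == "Granzyme-B":
                return config.gzmb_cd3neg_granzyme_prob
            return config.functional_immune_baseline
        if cell_type in voc.immune_types:
            return config.functional_immune_baseline
        return config.functional_background_prob
    # pure lineage markers
    if marker in LINEAGE_MARKERS.get(cell_type, ()):
        return config.lineage_positive_prob
    return config.lineage_background_prob


def substate_profiles(config: SyntheticConfig) -> pd.DataFrame:
    """Per-substate functional-marker positivity probabilities (rows =
    substates, columns = functional markers)."""
    return pd.DataFrame(config.substate_profiles).T.loc[:, list(FUNCTIONAL_MARKERS)]


def sample_substate_matrix(
    n_islets_per_profile: int,
    n_cd8: int,
    config: SyntheticConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Islet x marker CD8 positivity-frequency matrix with planted sub-state
    labels: each islet's per-marker frequency is Binomial(n_cd8, p)/n_cd8 at
    its profile's probability.  Returns (matrix, labels)."""
    config = SyntheticConfig() if config is None else config
    rng = np.random.default_rng() if rng is None else rng
    profiles = substate_profiles(config)
    rows, labels = [], []
    for si, (name, prof) in enumerate(profiles.iterrows()):
        for _ in range(n_islets_per_profile):
            rows.append(rng.binomial(n_cd8, prof.values) / n_cd8)
            labels.append(si)
    mat = pd.DataFrame(rows, columns=profiles.columns)
    return mat, np.asarray(labels)


# ---------------------------------------------------------------------------
# tissue generation


@dataclass
class GroundTruth:
    """Planted truth aligned with the emitted cell table."""

    cells: pd.DataFrame       # cell_id, donor_id, islet_id, peri_islet_id, lobule_id, niche_id, niche_kind, pos_<marker>...
    islets: pd.DataFrame      # donor_id, islet_id, lobule_id, x, y, radius, stage_raw, stage, stage_label, substate, n_core, n_band
    lobules: pd.DataFrame     # donor_id, lobule_id, mean_stage
    components: pd.DataFrame  # donor_id, component, n_cells
    partitions: dict = field(default_factory=dict)


def _place_centers(rng, n, w, h, margin, min_sep, avoid=(), avoid_sep=0.0, tries=20000):
    centers = []
    for _ in range(tries):
        if len(centers) == n:
            break
        c = np.array([rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)])
        ok = all(np.hypot(*(c - o)) >= min_sep for o in centers)
        ok = ok and all(np.hypot(*(c - o)) >= avoid_sep for o in avoid)
        if ok:
            centers.append(c)
    if len(centers) < n:
        raise RuntimeError("could not place components; tissue too small for config")
    return centers


def _truncated_gaussian_disc(rng, n, center, sigma, trunc=3.0):
    """n isotropic Gaussian points truncated at trunc*sigma from center."""
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.normal(0.0, sigma, size=(max(n - got, 8) * 2, 2))
        keep = cand[np.hypot(cand[:, 0], cand[:, 1]) <= trunc * sigma]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out + center


def _uniform_disc(rng, n, center, radius):
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)]) + center


def _uniform_annulus(rng, n, center, r_in, r_out):
    r = np.sqrt(rng.uniform(r_in ** 2, r_out ** 2, n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)]) + center


def generate_tissue(config: SyntheticConfig | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the multi-donor cell table and its ground truth.

    Deterministic given ``config.rng_seed``.
    """
    config = SyntheticConfig() if config is None else config
    config.validate()
    voc = config.vocabulary
    w, h = config.tissue_size
    ss = np.random.SeedSequence(config.rng_seed)

    donor_list = []
    for g in config.groups:
        for i in range(config.n_donors(g)):
            donor_list.append((f"{g}_{i}", g))
    donor_seeds = ss.spawn(len(donor_list))

    tables, gt_cells, gt_islets, gt_lobules, gt_components = [], [], [], [], []
    partitions = {}
    next_cell_id = 0

    for (donor, group), dseed in zip(donor_list, donor_seeds):
        rng = np.random.default_rng(dseed)
        part = make_lobule_partition(config, rng)
        partitions[donor] = part

        lob_means = {
            j: config.group_stage_means[group] + rng.normal(0, math.sqrt(config.lobule_stage_var))
            for j in part.lobule_ids
        }
        for j, m in lob_means.items():
            gt_lobules.append((donor, j, m))

        max_r = math.exp(config.islet_radius_log_mean + 3 * config.islet_radius_log_sd)
        islet_centers = _place_centers(
            rng, config.islets_per_donor, w, h,
            margin=max_r + 25.0, min_sep=2 * max_r + 30.0)
        radii = np.exp(rng.normal(config.islet_radius_log_mean,
                                  config.islet_radius_log_sd, len(islet_centers)))

        # donor-local accumulators
        xs, ys, types = [], [], []
        islet_of, peri_of, niche_of, niche_kind_of, substate_of = [], [], [], [], []

        def emit(pts, cell_types, islet_id="", peri_id="", niche_id="", niche_kind="", substate=""):
            xs.append(pts[:, 0]); ys.append(pts[:, 1])
            types.extend(cell_types)
            n = len(cell_types)
            islet_of.extend([islet_id] * n)
            peri_of.extend([peri_id] * n)
            niche_of.extend([niche_id] * n)
            niche_kind_of.extend([niche_kind] * n)
            substate_of.extend([substate] * n)

        # --- islets
        for j, (c, r) in enumerate(zip(islet_centers, radii)):
            islet_id = f"{donor}-I{j}"
            lob = next((lid for p, lid in zip(part.polygons, part.lobule_ids)
                        if p.covers(Point(c))), part.lobule_ids[0])
            s_raw = lob_means[lob] + rng.normal(0, math.sqrt(config.islet_stage_var))
            s = float(np.clip(s_raw, 0.0, 1.0))

            n_endo = rng.poisson(config.islet_cell_density * math.pi * r ** 2)
            n_endo = max(n_endo, 3)
            beta_frac = _curve(config.beta_fraction_curve, s)
            n_beta = rng.binomial(n_endo, beta_frac)
            n_rest = n_endo - n_beta
            n_alpha = rng.binomial(n_rest, 0.8) if n_rest else 0
            n_delta = n_rest - n_alpha
            endo_types = ["Beta"] * n_beta + ["Alpha"] * n_alpha + ["Delta"] * n_delta

            n_cd8 = rng.poisson(_curve(config.cd8_per_endocrine_curve, s) * n_endo)
            n_mac = rng.poisson(_curve(config.mac_per_endocrine_curve, s) * n_endo)
            n_cd4 = rng.poisson(config.other_immune_rate * n_endo)
            n_b = rng.poisson(config.other_immune_rate * n_endo)
            n_vasc = rng.poisson(config.islet_vasculature_rate * n_endo)
            imm_types = (["CD8 T"] * n_cd8 + ["Macrophage/DC"] * n_mac +
                         ["CD4 T"] * n_cd4 + ["B"] * n_b)

            if s < config.normal_stage_max:
                label = STAGE_NORMAL
            elif s < config.depleted_stage_min:
                label = STAGE_INFLAMED
            else:
                label = STAGE_DEPLETED
                if n_cd8 > 2 and n_mac > 7:
                    label = STAGE_DEPLETED_IMMUNE
            if label == STAGE_INFLAMED:
                names = list(config.substate_profiles)
                substate = names[rng.integers(len(names))]
            else:
                substate = "quiescent"

            core_pts = _truncated_gaussian_disc(rng, n_endo + n_vasc, c, r / 3.0)
            emit(core_pts, endo_types + ["Vasculature"] * n_vasc,
                 islet_id=islet_id, substate=substate)

            n_imm = len(imm_types)
            n_band = rng.binomial(n_imm, config.band_immune_fraction) if n_imm else 0
            perm = rng.permutation(n_imm)
            imm_types = [imm_types[k] for k in perm]
            band_types, core_imm_types = imm_types[:n_band], imm_types[n_band:]
            if core_imm_types:
                pts = _truncated_gaussian_disc(rng, len(core_imm_types), c, r / 3.0)
                emit(pts, core_imm_types, islet_id=islet_id, substate=substate)
            if band_types:
                pts = _uniform_annulus(rng, len(band_types), c, r, r + 15.0)
                emit(pts, band_types, peri_id=islet_id, substate=substate)

            gt_islets.append((donor, islet_id, lob, c[0], c[1], r, s_raw, s, label,
                              substate, n_endo + n_vasc + len(core_imm_types), len(band_types)))
            gt_components.append((donor, islet_id, n_endo + n_vasc + n_imm))

        # --- planted niches: B/CD8 aggregates with adjacent vasculature
        # patches, plus far neutrophil patches as non-adjacent controls
        avoid = list(islet_centers)
        n_agg = config.n_aggregates(group)
        pair_sep = config.aggregate_radius + config.vasc_patch_radius
        agg_centers = _place_centers(
            rng, n_agg, w, h, margin=pair_sep + 40.0,
            min_sep=3 * pair_sep, avoid=avoid, avoid_sep=max_r + pair_sep + 20.0)
        far_avoid = avoid + agg_centers
        far_centers = _place_centers(
            rng, config.far_patches_per_donor, w, h,
            margin=config.far_patch_radius + 20.0,
            min_sep=2 * config.far_patch_radius + 200.0,
            avoid=far_avoid, avoid_sep=300.0) if config.far_patches_per_donor else []

        for a, c in enumerate(agg_centers):
            nid = f"{donor}-A{a}"
            n_cells = rng.poisson(config.aggregate_density * math.pi * config.aggregate_radius ** 2)
            n_cells = max(n_cells, 10)
            t = np.where(rng.uniform(size=n_cells) < 0.5, "B", "CD8 T")
            pts = _uniform_disc(rng, n_cells, c, config.aggregate_radius)
            emit(pts, list(t), niche_id=nid, niche_kind="B-CD8 aggregate")
            gt_components.append((donor, nid, n_cells))
            # adjacent vasculature patch, touching the aggregate
            th = rng.uniform(0, 2 * np.pi)
            vc = c + (pair_sep - 10.0) * np.array([math.cos(th), math.sin(th)])
            vc = np.clip(vc, config.vasc_patch_radius + 5.0,
                         [w - config.vasc_patch_radius - 5.0, h - config.vasc_patch_radius - 5.0])
            vid = f"{donor}-V{a}"
            n_v = max(rng.poisson(config.vasc_patch_density * math.pi * config.vasc_patch_radius ** 2), 10)
            tv = np.where(rng.uniform(size=n_v) < 0.9, "Vasculature", "Stroma")
            pts = _uniform_disc(rng, n_v, vc, config.vasc_patch_radius)
            emit(pts, list(tv), niche_id=vid, niche_kind="vasculature patch")
            gt_components.append((donor, vid, n_v))

        for a, c in enumerate(far_centers):
            nid = f"{donor}-F{a}"
            n_cells = max(rng.poisson(config.far_patch_density * math.pi * config.far_patch_radius ** 2), 10)
            pts = _uniform_disc(rng, n_cells, c, config.far_patch_radius)
            emit(pts, ["Neutrophil"] * n_cells, niche_id=nid, niche_kind="neutrophil patch")
            gt_components.append((donor, nid, n_cells))

        # --- homogeneous Poisson background
        n_bg = rng.poisson(config.background_density * w * h)
        bg_pts = np.column_stack([rng.uniform(0, w, n_bg), rng.uniform(0, h, n_bg)])
        bt_names = list(config.background_type_probs)
        bt_p = np.array([config.background_type_probs[t] for t in bt_names], dtype=float)
        bt_p = bt_p / bt_p.sum()
        bg_types = [bt_names[k] for k in rng.choice(len(bt_names), size=n_bg, p=bt_p)]
        emit(bg_pts, bg_types)
        gt_components.append((donor, "background", n_bg))

        # --- assemble donor table
        x = np.concatenate(xs) if xs else np.empty(0)
        y = np.concatenate(ys) if ys else np.empty(0)
        n_cells = len(types)
        cell_ids = np.arange(next_cell_id, next_cell_id + n_cells)
        next_cell_id += n_cells
        df = pd.DataFrame({
            "cell_id": cell_ids,
            "donor_id": donor,
            "group": group,
            "x_um": x,
            "y_um": y,
            "cell_type": pd.Categorical(types, categories=voc.names),
        })

        # lobule of every cell (planted truth; the analysis re-derives this)
        lob_labels = np.full(n_cells, LobulePartition.EDGE_LABEL, dtype=object)
        tree = STRtree(part.polygons)
        hit_cell, hit_poly = tree.query(shapely.points(x, y), predicate="intersects")
        # lowest lobule id wins when a point sits exactly on a shared border
        order = np.lexsort((hit_poly, hit_cell))[::-1]
        for ci, pj in zip(hit_cell[order], hit_poly[order]):
            lob_labels[ci] = part.lobule_ids[pj]

        # marker positivity + intensities
        type_arr = np.asarray(types, dtype=object)
        sub_arr = np.asarray(substate_of, dtype=object)
        keys = np.where(type_arr == "CD8 T", np.char.add("CD8 T|", sub_arr.astype(str)), type_arr)
        codes, uniq = pd.factorize(keys)
        gt_cell = pd.DataFrame({
            "cell_id": cell_ids, "donor_id": donor,
            "islet_id": islet_of, "peri_islet_id": peri_of,
            "lobule_id": lob_labels,
            "niche_id": niche_of, "niche_kind": niche_kind_of,
        })
        for marker in ALL_MARKERS:
            p_uniq = np.array([
                _positivity_prob(k.split("|")[0], marker, k.split("|")[1] if "|" in k else "",
                                 config, voc)
                for k in uniq
            ])
            pos = rng.uniform(size=n_cells) < p_uniq[codes]
            df[marker] = _intensity_column(pos, marker, config, rng)
            gt_cell[f"pos_{marker}"] = pos
        tables.append(df)
        gt_cells.append(gt_cell)

    table = pd.concat(tables, ignore_index=True)
    gt = GroundTruth(
        cells=pd.concat(gt_cells, ignore_index=True),
        islets=pd.DataFrame(gt_islets, columns=[
            "donor_id", "islet_id", "lobule_id", "x", "y", "radius", "stage_raw",
            "stage", "stage_label", "substate", "n_core", "n_band"]),
        lobules=pd.DataFrame(gt_lobules, columns=["donor_id", "lobule_id", "mean_stage"]),
        components=pd.DataFrame(gt_components, columns=["donor_id", "component", "n_cells"]),
        partitions=partitions,
    )
    return table, gt
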