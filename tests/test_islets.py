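"""Windows, islet-region detection, instance extraction, composition
features and swath profiles, each against small brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from insulitis import islets as isl
from insulitis import synthetic as syn


def _cells(x, y, types, donor="d0", start_id=0):
    return pd.DataFrame({
        "cell_id": np.arange(start_id, start_id + len(x)),
        "donor_id": donor,
        "x_um": np.asarray(x, dtype=float),
        "y_um": np.asarray(y, dtype=float),
        "cell_type": types,
    })


def brute_force_knn(coords, ids, k):
    """Sort every other point by (distance, id); the independent oracle."""
    out = []
    for i in range(len(coords)):
        d = np.hypot(*(coords - coords[i]).T)
        order = sorted((j for j in range(len(coords)) if j != i),
                       key=lambda j: (d[j], ids[j]))
        out.append(order[:k])
    return np.array(out)


class TestWindows:
    def test_forced_21_cell_donor(self):
        rng = np.random.default_rng(0)
        tab = _cells(rng.uniform(0, 100, 21), rng.uniform(0, 100, 21), "Acinar")
        w = isl.compute_windows(tab, k=20)
        for i in range(21):
            assert set(w.neighbor_pos[i]) == set(range(21)) - {i}

    def test_line_of_cells_interior_window(self):
        tab = _cells(np.arange(50.0), np.zeros(50), "Acinar")
        w = isl.compute_windows(tab, k=20)
        interior = 25
        assert set(w.neighbor_pos[interior]) == set(range(15, 36)) - {25}

    def test_matches_brute_force_with_ties(self):
        # grid coordinates force many exact distance ties
        xs, ys = np.meshgrid(np.arange(7.0), np.arange(6.0))
        tab = _cells(xs.ravel(), ys.ravel(), "Acinar")
        w = isl.compute_windows(tab, k=8)
        oracle = brute_force_knn(tab[["x_um", "y_um"]].to_numpy(),
                                 tab["cell_id"].to_numpy(), 8)
        assert np.array_equal(w.neighbor_pos, oracle)

    def test_matches_brute_force_random(self):
        rng = np.random.default_rng(3)
        n = 300
        tab = _cells(rng.uniform(0, 50, n), rng.uniform(0, 50, n), "Acinar")
        w = isl.compute_windows(tab, k=20)
        oracle = brute_force_knn(tab[["x_um", "y_um"]].to_numpy(),
                                 tab["cell_id"].to_numpy(), 20)
        assert np.array_equal(w.neighbor_pos, oracle)

    def test_composition_sums_to_k_and_merges_endocrine(self, small_tissue):
        table, _ = small_tissue
        w = isl.compute_windows(table, k=20)
        assert (w.composition.sum(axis=1) == 20).all()
        assert "Endocrine" in w.composition.columns
        assert not {"Alpha", "Beta", "Delta"} & set(w.composition.columns)

    def test_windows_never_cross_donors(self):
        a = _cells([0, 1, 2, 3], [0, 0, 0, 0], "Acinar", donor="a")
        b = _cells([0.1, 1.1, 2.1, 3.1], [0, 0, 0, 0], "Acinar", donor="b", start_id=4)
        tab = pd.concat([a, b], ignore_index=True)
        w = isl.compute_windows(tab, k=3)
        assert (w.neighbor_pos[:4] < 4).all() and (w.neighbor_pos[4:] >= 4).all()

    def test_too_few_cells_in_donor_raises(self):
        tab = _cells([0, 1, 2], [0, 0, 0], "Acinar")
        with pytest.raises(ValueError, match="d0"):
            isl.compute_windows(tab, k=20)


class TestRegionDetection:
    def test_all_endocrine_everything_in_region(self):
        rng = np.random.default_rng(0)
        tab = _cells(rng.uniform(0, 100, 60), rng.uniform(0, 100, 60), "Beta")
        w = isl.compute_windows(tab, k=10)
        region = isl.detect_islet_region(w, n_clusters=5, seed=0)
        assert set(region) == set(tab["cell_id"])

    def test_no_endocrine_empty_region(self):
        rng = np.random.default_rng(0)
        tab = _cells(rng.uniform(0, 100, 60), rng.uniform(0, 100, 60), "Acinar")
        w = isl.compute_windows(tab, k=10)
        region = isl.detect_islet_region(w, n_clusters=5, seed=0)
        assert len(region) == 0

    def test_default_tissue_recall(self, default_tissue, default_windows):
        table, gt = default_tissue
        region = isl.detect_islet_region(default_windows, seed=0)
        planted = gt.cells[gt.cells["islet_id"] != ""]
        assert planted["cell_id"].isin(region).mean() >= 0.95


class TestExtractIslets:
    def _blob(self, cx, cy, n, spacing=2.0):
        side = int(np.ceil(np.sqrt(n)))
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        return (cx + spacing * xs.ravel()[:n], cy + spacing * ys.ravel()[:n])

    def test_min_cell_filter_boundary(self):
        x9, y9 = self._blob(0, 0, 9)
        x10, y10 = self._blob(1000, 1000, 10)
        tab = _cells(np.r_[x9, x10], np.r_[y9, y10], "Beta")
        out = isl.extract_islets(tab, tab["cell_id"].to_numpy(), min_cells=10)
        assert len(out) == 1
        assert out[0].n_cells == 10
        assert set(out[0].cell_ids) == set(range(9, 19))

    def test_two_distant_blobs_two_islets(self):
        x1, y1 = self._blob(0, 0, 25)
        x2, y2 = self._blob(500, 0, 25)
        tab = _cells(np.r_[x1, x2], np.r_[y1, y2], "Beta")
        out = isl.extract_islets(tab, tab["cell_id"].to_numpy())
        assert len(out) == 2

    def test_empty_region_empty_list(self):
        tab = _cells([0.0], [0.0], "Beta")
        assert isl.extract_islets(tab, np.array([], dtype=int)) == []

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(8)
        n = 180
        tab = _cells(rng.uniform(0, 300, n), rng.uniform(0, 300, n), "Beta")
        out = isl.extract_islets(tab, tab["cell_id"].to_numpy(),
                                 adjacency_k=5, min_cells=1)
        # oracle: same symmetric 5-NN rule, BFS components
        coords = tab[["x_um", "y_um"]].to_numpy()
        nbrs = brute_force_knn(coords, tab["cell_id"].to_numpy(), 5)
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in nbrs[i]:
                adj[i].add(j)
                adj[j].add(i)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        got = {frozenset(islet.cell_ids) for islet in out}
        assert got == set(comps)

    def test_islets_are_disjoint(self, default_islets):
        all_ids = np.concatenate([i.cell_ids for i in default_islets])
        assert len(all_ids) == len(set(all_ids))


class TestCompositionFeatures:
    def _islet_table(self):
        # 10 beta cells in a tight blob + 5 CD8 inside the blob
        x = np.r_[np.linspace(0, 9, 10), np.linspace(1, 8, 5)]
        y = np.r_[np.zeros(10), np.ones(5) * 0.5]
        tab = _cells(x, y, ["Beta"] * 10 + ["CD8 T"] * 5)
        islets = isl.extract_islets(tab, tab["cell_id"].to_numpy(), min_cells=10)
        assert len(islets) == 1
        return tab, islets

    def test_forced_arithmetic(self):
        tab, islets = self._islet_table()
        fm = isl.islet_composition_features(islets, tab)
        assert fm.features.iloc[0]["CD8 T"] == pytest.approx(np.log1p(5 / 10))
        assert fm.features.iloc[0]["B"] == 0.0  # log1p(0)

    def test_band_ring_counted_only_within_band(self):
        tab, islets = self._islet_table()
        # ring cells at 15 µm (inside band) and 30 µm (outside band) below the blob
        ring15 = _cells([4.0], [-15.0], ["B"], start_id=100)
        ring30 = _cells([4.0], [-30.0], ["CD4 T"], start_id=200)
        full = pd.concat([tab, ring15, ring30], ignore_index=True)
        islets2 = isl.extract_islets(full, tab["cell_id"].to_numpy(), min_cells=10)
        fm = isl.islet_composition_features(islets2, full, band_um=20.0)
        assert fm.features.iloc[0]["B"] == pytest.approx(np.log1p(1 / 10))
        assert fm.features.iloc[0]["CD4 T"] == 0.0

    def test_adding_a_cell_strictly_increases_feature(self):
        tab, islets = self._islet_table()
        fm0 = isl.islet_composition_features(islets, tab)
        extra = _cells([4.0], [-10.0], ["B"], start_id=300)
        full = pd.concat([tab, extra], ignore_index=True)
        islets2 = isl.extract_islets(full, tab["cell_id"].to_numpy(), min_cells=10)
        fm1 = isl.islet_composition_features(islets2, full)
        assert fm1.features.iloc[0]["B"] > fm0.features.iloc[0]["B"]

    def test_zero_endocrine_islet_rejected(self):
        tab = _cells(np.linspace(0, 9, 10), np.zeros(10), "CD8 T")
        islets = isl.extract_islets(tab, tab["cell_id"].to_numpy(), min_cells=10)
        with pytest.raises(ValueError):
            isl.islet_composition_features(islets, tab)


class TestSwaths:
    def _setup(self):
        x = np.linspace(0, 9, 10)
        tab = _cells(x, np.zeros(10), "Beta")
        islets = isl.extract_islets(tab, tab["cell_id"].to_numpy(), min_cells=10)
        return tab, islets

    def test_half_open_band_convention(self):
        tab, islets = self._setup()
        cell = _cells([4.0], [-25.0], ["CD8 T"], start_id=50)
        full = pd.concat([tab, cell], ignore_index=True)
        islets = isl.extract_islets(full, tab["cell_id"].to_numpy(), min_cells=10)
        sw = isl.swath_composition(islets, full)
        sw = sw.set_index(["band_lo", "band_hi"])
        assert sw.loc[(0.0, 25.0), "n_cells"] == 0
        assert sw.loc[(25.0, 50.0), "n_cells"] == 1
        assert sw.loc[(25.0, 50.0), "CD8 T"] == 1.0

    def test_fractions_sum_to_one_in_nonempty_bands(self, default_tissue, default_islets):
        table, _ = default_tissue
        donor_islets = [i for i in default_islets if i.donor_id == "T1D_0"][:3]
        sw = isl.swath_composition(donor_islets, table)
        voc = syn.default_vocabulary().names
        nonempty = sw[~sw["empty"]]
        assert len(nonempty) > 0
        assert np.allclose(nonempty[list(voc)].sum(axis=1), 1.0, atol=1e-12)

    def test_planted_ring_appears_in_matching_band(self):
        tab, islets = self._setup()
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 2 * np.pi, 40)
        r = rng.uniform(30, 40, 40)
        ring = _cells(4.5 + r * np.cos(theta), r * np.sin(theta), ["CD8 T"] * 40,
                      start_id=60)
        bgx = rng.uniform(-100, 110, 200)
        bgy = rng.uniform(-100, 110, 200)
        bg = _cells(bgx, bgy, ["Acinar"] * 200, start_id=200)
        full = pd.concat([tab, ring, bg], ignore_index=True)
        islets = isl.extract_islets(full, tab["cell_id"].to_numpy(), min_cells=10)
        sw = isl.swath_composition(islets, full).set_index(["band_lo", "band_hi"])
        mid = sw.loc[(25.0, 50.0), "CD8 T"]
        assert mid > sw.loc[(0.0, 25.0), "CD8 T"]
        assert mid > sw.loc[(50.0, 100.0), "CD8 T"]

    def test_overlapping_bands_rejected(self):
        tab, islets = self._setup()
        with pytest.raises(ValueError):
            isl.swath_composition(islets, tab, bands=[(0.0, 30.0), (25.0, 50.0)])
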