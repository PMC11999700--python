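"""CN naming, instances, adjacency and abundance, with brute-force oracles
for instances and adjacency."""

import numpy as np
import pandas as pd
import pytest

from insulitis import islets as isl
from insulitis import neighborhoods as nb
from insulitis.neighborhoods import BACKGROUND_CN


def _cells(x, y, types, donor="d0", start_id=0):
    return pd.DataFrame({
        "cell_id": np.arange(start_id, start_id + len(x)),
        "donor_id": donor,
        "x_um": np.asarray(x, dtype=float),
        "y_um": np.asarray(y, dtype=float),
        "cell_type": types,
    })


def _windows_with_presence(present: dict[str, int], n=100, k=20):
    """A Windows object whose composition realises exact presence counts."""
    types = list(present) + ["Acinar"]
    comp = pd.DataFrame(0, index=range(n), columns=types)
    for t, cnt in present.items():
        comp.loc[: cnt - 1, t] = 1
    comp["Acinar"] = k - comp.sum(axis=1)
    return isl.Windows(
        cell_ids=np.arange(n), donor_ids=np.array(["d0"] * n),
        neighbor_pos=np.zeros((n, k), dtype=int), composition=comp,
        k=k, merge_endocrine=True)


class TestNaming:
    def test_presence_rule_forced(self):
        w = _windows_with_presence({"B": 90, "CD8 T": 81, "Stroma": 50})
        model = nb.identify_cns(w, n_clusters=1, seed=0)
        assert model.cn_names == ["B|CD8 T"]

    def test_exactly_80_percent_excluded(self):
        w = _windows_with_presence({"B": 90, "CD8 T": 80})
        model = nb.identify_cns(w, n_clusters=1, seed=0)
        assert model.cn_names == ["B"]

    def test_acinar_and_epithelial_never_in_names(self):
        w = _windows_with_presence({"Ductal/Epithelial": 100, "B": 90})
        model = nb.identify_cns(w, n_clusters=1, seed=0)
        assert model.cn_names == ["B"]

    def test_empty_name_becomes_background(self):
        w = _windows_with_presence({"B": 50})
        model = nb.identify_cns(w, n_clusters=1, seed=0)
        assert model.cn_names == [BACKGROUND_CN]

    def test_every_cell_assigned_and_merge_bounded(self, default_windows):
        model = nb.identify_cns(default_windows, seed=0)
        assert model.assignments.notna().all()
        assert len(model.assignments) == len(default_windows.cell_ids)
        assert len(model.cn_names) <= model.n_clusters

    def test_n_clusters_exceeding_cells_rejected(self):
        w = _windows_with_presence({"B": 90}, n=50)
        with pytest.raises(ValueError):
            nb.identify_cns(w, n_clusters=51)


def _grid(cx, cy, n, spacing=2.0):
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    return cx + spacing * xs.ravel()[:n], cy + spacing * ys.ravel()[:n]


class TestInstances:
    def test_two_distant_groups_two_instances(self):
        x1, y1 = _grid(0, 0, 20)
        x2, y2 = _grid(500, 0, 20)
        tab = _cells(np.r_[x1, x2], np.r_[y1, y2], "B")
        asg = pd.Series("B", index=pd.Index(tab["cell_id"], name="cell_id"))
        inst = nb.extract_cn_instances(tab, asg)
        assert len(inst) == 2

    def test_singleton_instance(self):
        x, y = _grid(0, 0, 30)
        tab = _cells(np.r_[x, [300.0]], np.r_[y, [300.0]],
                     ["Acinar"] * 30 + ["B"])
        asg = pd.Series(["(bg)"] * 30 + ["B"],
                        index=pd.Index(tab["cell_id"], name="cell_id"))
        inst = nb.extract_cn_instances(tab, asg)
        b = [i for i in inst if i.cn_name == "B"]
        assert len(b) == 1 and b[0].n_cells == 1

    def test_instances_partition_cells(self, small_tissue, default_windows=None):
        table, _ = small_tissue
        w = isl.compute_windows(table)
        model = nb.identify_cns(w, n_clusters=50, seed=0)
        inst = nb.extract_cn_instances(table, model.assignments)
        counts = {}
        for i in inst:
            counts[i.cn_name] = counts.get(i.cn_name, 0) + i.n_cells
        expected = model.assignments.value_counts().to_dict()
        assert counts == expected
        all_ids = np.concatenate([i.cell_ids for i in inst])
        assert len(all_ids) == len(set(all_ids)) == len(table)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        n = 400
        tab = _cells(rng.uniform(0, 200, n), rng.uniform(0, 200, n), "B")
        labels = rng.choice(["X", "Y", "Z"], n)
        asg = pd.Series(labels, index=pd.Index(tab["cell_id"], name="cell_id"))
        inst = nb.extract_cn_instances(tab, asg)
        # oracle: symmetric 5-NN over ALL cells, BFS within each label
        coords = tab[["x_um", "y_um"]].to_numpy()
        d = np.hypot(coords[:, None, 0] - coords[None, :, 0],
                     coords[:, None, 1] - coords[None, :, 1])
        np.fill_diagonal(d, np.inf)
        knn = np.argsort(d, axis=1)[:, :5]
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in knn[i]:
                adj[i].add(int(j))
                adj[int(j)].add(i)
        comps = set()
        for lab in "XYZ":
            members = set(np.flatnonzero(labels == lab))
            seen = set()
            for s in members:
                if s in seen:
                    continue
                stack, comp = [s], set()
                while stack:
                    u = stack.pop()
                    if u in comp:
                        continue
                    comp.add(u)
                    stack.extend((adj[u] & members) - comp)
                seen |= comp
                comps.add(frozenset(comp))
        got = {frozenset(i.cell_ids) for i in inst}
        assert got == comps


class TestAdjacency:
    def _three_sources_two_adjacent(self):
        # three B groups; two touch a Vasculature patch, one is far away
        parts = []
        for k, cx in enumerate([0, 200, 400]):
            x, y = _grid(cx, 0, 16)
            parts.append(_cells(x, y, "B", start_id=100 * k))
        # patches interleaving with groups 0 and 1 (1 µm from the B grid edge,
        # closer than the 2 µm within-grid spacing, so k=5 contacts form)
        for k, cx in enumerate([7, 207]):
            x, y = _grid(cx, 1, 16)
            parts.append(_cells(x, y, "Vasculature", start_id=1000 + 100 * k))
        tab = pd.concat(parts, ignore_index=True)
        asg = pd.Series(tab["cell_type"].astype(str).to_numpy(),
                        index=pd.Index(tab["cell_id"], name="cell_id"))
        graphs = nb.build_donor_graphs(tab)
        inst = nb.extract_cn_instances(tab, asg, graphs=graphs)
        return tab, asg, graphs, inst

    def test_forced_two_thirds(self):
        tab, asg, graphs, inst = self._three_sources_two_adjacent()
        assert len([i for i in inst if i.cn_name == "B"]) == 3
        f = nb.adjacency_frequency(inst, "B", "Vasculature", graphs)
        assert f == pytest.approx(2 / 3)

    def test_zero_dest_instances_zero_frequency(self):
        tab, asg, graphs, inst = self._three_sources_two_adjacent()
        assert nb.adjacency_frequency(inst, "B", "Nerve", graphs) == 0.0

    def test_zero_source_instances_rejected(self):
        tab, asg, graphs, inst = self._three_sources_two_adjacent()
        with pytest.raises(ValueError):
            nb.adjacency_frequency(inst, "Nerve", "B", graphs)

    def test_matrix_matches_pairwise_and_symmetry(self):
        tab, asg, graphs, inst = self._three_sources_two_adjacent()
        mat = nb.adjacency_matrix(inst, graphs)
        assert mat.loc["B", "Vasculature"] == pytest.approx(2 / 3)
        assert mat.loc["Vasculature", "B"] == pytest.approx(1.0)
        # pair-level symmetry: A touches B iff B touches A
        b = [i for i in inst if i.cn_name == "B"]
        v = [i for i in inst if i.cn_name == "Vasculature"]
        for s in b:
            for d in v:
                fwd = nb._instances_adjacent(s, d, graphs[s.donor_id])
                rev = nb._instances_adjacent(d, s, graphs[s.donor_id])
                assert fwd == rev

    def test_frequencies_bounded(self, small_tissue):
        table, _ = small_tissue
        w = isl.compute_windows(table)
        model = nb.identify_cns(w, n_clusters=50, seed=0)
        graphs = nb.build_donor_graphs(table)
        inst = nb.extract_cn_instances(table, model.assignments, graphs=graphs)
        mat = nb.adjacency_matrix(inst, graphs)
        vals = mat.to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0


class TestAbundance:
    def _table(self, layout):
        """layout: list of (donor, group, acinar count, cn_counts dict)."""
        rows = []
        cid = 0
        for donor, group, acinar, cns in layout:
            for _ in range(acinar):
                rows.append((cid, donor, group, "Acinar", "(background)")); cid += 1
            for cn, cnt in cns.items():
                for _ in range(cnt):
                    rows.append((cid, donor, group, "B", cn)); cid += 1
        tab = pd.DataFrame(rows, columns=["cell_id", "donor_id", "group",
                                          "cell_type", "cn"])
        tab["x_um"] = 0.0
        tab["y_um"] = 0.0
        asg = pd.Series(tab["cn"].to_numpy(),
                        index=pd.Index(tab["cell_id"], name="cell_id"))
        return tab, asg

    def test_forced_arithmetic(self):
        tab, asg = self._table([("d0", "T1D", 100, {"X": 50})])
        ab, _ = nb.cn_abundance_and_contrast(tab, asg)
        row = ab.set_index(["donor_id", "cn"]).loc[("d0", "X")]
        assert row["abundance"] == pytest.approx(0.5)

    def test_zero_acinar_rejected(self):
        tab, asg = self._table([("d0", "T1D", 0, {"X": 5})])
        with pytest.raises(ValueError):
            nb.cn_abundance_and_contrast(tab, asg)

    def test_planted_enrichment_ranks_first(self):
        rng = np.random.default_rng(0)
        layout = []
        for i in range(5):
            layout.append((f"t{i}", "T1D", 100,
                         {"X": 40 + rng.integers(-3, 4), "Y": 20 + rng.integers(-3, 4)}))
        for i in range(5):
            layout.append((f"n{i}", "nonT1D", 100,
                         {"X": 10 + rng.integers(-2, 3), "Y": 20 + rng.integers(-3, 4)}))
        tab, asg = self._table(layout)
        ab, contrast = nb.cn_abundance_and_contrast(tab, asg)
        ranked = contrast[contrast["cn"] != "(background)"]
        assert ranked.iloc[0]["cn"] == "X"
        assert ranked.iloc[0]["fold_change"] == pytest.approx(4.0, rel=0.35)
        assert ranked.iloc[0]["pvalue"] < 0.05

    def test_identical_groups_null(self):
        layout = [(f"t{i}", "T1D", 100, {"X": 30}) for i in range(4)]
        layout += [(f"n{i}", "nonT1D", 100, {"X": 30}) for i in range(4)]
        tab, asg = self._table(layout)
        _, contrast = nb.cn_abundance_and_contrast(tab, asg)
        row = contrast.set_index("cn").loc["X"]
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["pvalue"] == 1.0
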