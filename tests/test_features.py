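"""Hotspot selection, clustering, feature moments, directions and active spaces."""

import numpy as np
import pytest

import pharmvote as pv
from pharmvote.features import ActiveSpace, Hotspot, hotspots_from_map
from pharmvote.receptor import Atom, ReceptorConformation

from conftest import random_grid_map


def grid_with_energies(values_by_index, n=10, spacing=0.5, fill=1.0):
    e = np.full((n + 1, n + 1, n + 1), fill)
    for idx, v in values_by_index.items():
        e[idx] = v
    return pv.GridMap("hydrophobic", np.zeros(3), spacing, (n, n, n), e)


class TestSelectHotspotCells:
    def test_floor_of_percentage(self, rng):
        vals = {-(i + 1) * 1e-3: None for i in range(1000)}
        e = np.full((10, 10, 10), 1.0).ravel()
        e[:1000] = np.linspace(-1.0, -0.001, 1000)
        g = pv.GridMap("hydrophobic", np.zeros(3), 0.5, (9, 9, 9), e.reshape(10, 10, 10))
        assert len(pv.select_hotspot_cells(g, 0.7)) == 7

    def test_lowest_energy_selection(self):
        g = grid_with_energies({(0, 0, 0): -5, (1, 0, 0): -4, (2, 0, 0): -3,
                                (3, 0, 0): -2, (4, 0, 0): -1})
        cells = pv.select_hotspot_cells(g, 40.0)  # floor(0.4*5) = 2
        assert cells == [(0, 0, 0), (1, 0, 0)]

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(100):
            g = random_grid_map(rng, n=8)
            x = float(rng.uniform(1, 60))
            got = pv.select_hotspot_cells(g, x)
            # oracle: full sort of all negative points by (energy, index)
            neg = [(g.energies[i, j, k], (i, j, k))
                   for i in range(9) for j in range(9) for k in range(9)
                   if g.energies[i, j, k] < 0]
            neg.sort()
            k_sel = int(np.floor(x / 100 * len(neg)))
            assert got == [t[1] for t in neg[:k_sel]]

    def test_selection_nested_in_x(self, rng):
        g = random_grid_map(rng, n=8)
        prev = set()
        for x in (5, 10, 25, 60, 100):
            cur = set(pv.select_hotspot_cells(g, x))
            assert prev <= cur
            prev = cur


def union_find_components(cells, adjacency="full_26"):
    """Brute-force union-find over all pairs — the clustering oracle."""
    parent = {c: c for c in cells}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    arr = np.asarray(cells)
    d = np.abs(arr[:, None, :] - arr[None, :, :])
    if adjacency == "full_26":
        adj = (d.max(axis=-1) == 1) | ((d.max(axis=-1) <= 1) & (d.sum(axis=-1) > 0))
    else:
        adj = d.sum(axis=-1) == 1
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if adj[i, j]:
                ri, rj = find(cells[i]), find(cells[j])
                if ri != rj:
                    parent[ri] = rj
    comps = {}
    for c in cells:
        comps.setdefault(find(c), []).append(c)
    return sorted((sorted(v) for v in comps.values()), key=lambda c: (-len(c), c[0]))


class TestClusterCells:
    def test_face_sharing_merges_distant_split(self):
        assert len(pv.cluster_cells([(0, 0, 0), (1, 0, 0)])) == 1
        assert len(pv.cluster_cells([(0, 0, 0), (3, 0, 0)])) == 2

    def test_empty_input(self):
        assert pv.cluster_cells([]) == []

    def test_diagonal_neighbors_depend_on_adjacency(self):
        cells = [(0, 0, 0), (1, 1, 1)]
        assert len(pv.cluster_cells(cells, "full_26")) == 1
        assert len(pv.cluster_cells(cells, "faces_6")) == 2

    @pytest.mark.parametrize("adjacency", ["full_26", "faces_6"])
    def test_matches_union_find_oracle(self, rng, adjacency):
        for _ in range(100):
            n_cells = int(rng.integers(5, 200))
            flat = rng.choice(20**3, size=n_cells, replace=False)
            cells = [tuple(int(v) for v in np.unravel_index(f, (20, 20, 20)))
                     for f in flat]
            cells.sort()
            got = pv.cluster_cells(cells, adjacency)
            assert got == union_find_components(cells, adjacency)

    def test_partition_property(self, rng):
        g = random_grid_map(rng, n=10)
        cells = pv.select_hotspot_cells(g, 30)
        clusters = pv.cluster_cells(cells)
        flat = [c for cl in clusters for c in cl]
        assert sorted(flat) == sorted(cells)
        assert len(set(flat)) == len(flat)


class TestFeatureMoments:
    def test_single_cell_zero_rgyr(self):
        g = grid_with_energies({(2, 4, 6): -2.0})
        h = Hotspot([(2, 4, 6)], np.array([-2.0]), "hydrophobic", "hydrophobic")
        f = pv.feature_from_hotspot(h, g)
        np.testing.assert_allclose(f.center, g.index_coords([(2, 4, 6)])[0])
        assert f.rgyr == 0.0

    def test_two_equal_cells_midpoint(self):
        g = grid_with_energies({(2, 0, 0): -1.0, (3, 0, 0): -1.0}, spacing=0.25)
        h = Hotspot([(2, 0, 0), (3, 0, 0)], np.array([-1.0, -1.0]),
                    "hydrophobic", "hydrophobic")
        f = pv.feature_from_hotspot(h, g)
        mid = g.index_coords([(2.5, 0, 0)])[0]
        np.testing.assert_allclose(f.center, mid)
        assert f.rgyr == pytest.approx(0.125)

    def test_three_to_one_weights(self):
        g = grid_with_energies({(2, 0, 0): -3.0, (3, 0, 0): -1.0}, spacing=0.25)
        h = Hotspot([(2, 0, 0), (3, 0, 0)], np.array([-3.0, -1.0]),
                    "hydrophobic", "hydrophobic")
        f = pv.feature_from_hotspot(h, g)
        heavy = g.index_coords([(2, 0, 0)])[0]
        assert np.linalg.norm(f.center - heavy) == pytest.approx(0.0625)
        assert f.rgyr == pytest.approx(np.sqrt(3) * 0.25 / 4, abs=1e-9)  # ~0.10825

    def test_matches_direct_moment_oracle(self, rng):
        for _ in range(100):
            g = random_grid_map(rng, n=8)
            k = int(rng.integers(1, 12))
            flat = rng.choice(9**3, size=k, replace=False)
            cells = [tuple(int(v) for v in np.unravel_index(f, (9, 9, 9))) for f in flat]
            energies = -rng.uniform(0.1, 5.0, k)
            h = Hotspot(cells, energies, "hydrophobic", "hydrophobic")
            f = pv.feature_from_hotspot(h, g)
            xyz = g.index_coords(np.asarray(cells, float))
            w = np.abs(energies)
            c = sum(wi * x for wi, x in zip(w, xyz)) / w.sum()
            rg = np.sqrt(sum(wi * np.dot(x - c, x - c) for wi, x in zip(w, xyz)) / w.sum())
            np.testing.assert_allclose(f.center, c, atol=1e-9)
            assert f.rgyr == pytest.approx(rg, abs=1e-9)

    def test_rgyr_bounded_by_half_bounding_diagonal(self, rng):
        for _ in range(20):
            g = random_grid_map(rng, n=10)
            spots = hotspots_from_map(g, "hydrophobic")
            for h in spots:
                f = pv.feature_from_hotspot(h, g)
                xyz = g.index_coords(np.asarray(h.cells, float))
                diag = np.linalg.norm(xyz.max(axis=0) - xyz.min(axis=0))
                assert f.rgyr <= diag / 2 + 1e-12
                assert (f.rgyr == 0.0) == (len(h.cells) == 1)

    def test_translation_equivariance(self, rng):
        g1 = random_grid_map(rng, n=6, center=(0, 0, 0))
        shift = np.array([2.0, -1.0, 3.0])
        g2 = pv.GridMap("hydrophobic", shift, g1.spacing, g1.n_intervals,
                        g1.energies.copy())
        for h1, h2 in zip(hotspots_from_map(g1, "hydrophobic"),
                          hotspots_from_map(g2, "hydrophobic")):
            f1 = pv.feature_from_hotspot(h1, g1)
            f2 = pv.feature_from_hotspot(h2, g2)
            np.testing.assert_allclose(f2.center - f1.center, shift, atol=1e-9)
            assert f1.rgyr == pytest.approx(f2.rgyr, abs=1e-12)


def make_receptor(specs):
    """specs: list of (element, atom_name, resname, resnum, coords)."""
    return ReceptorConformation(
        0, [Atom(el, an, rn, num, "A", np.asarray(c, float))
            for el, an, rn, num, c in specs]
    )


class TestDirections:
    def test_donor_points_to_nearest_oxygen(self):
        rec = make_receptor([("O", "O", "ALA", 1, (0, 0, 2)),
                             ("O", "OG", "SER", 2, (0, 0, 4))])
        f = pv.PharmFeature("donor", np.zeros(3), 0.1)
        f = pv.assign_direction(f, rec)
        np.testing.assert_allclose(f.direction, [0, 0, 1])

    def test_nearest_counterpart_wins(self):
        rec = make_receptor([("O", "O", "ALA", 1, (3, 0, 0)),
                             ("O", "O", "ALA", 2, (0, 4, 0))])
        f = pv.assign_direction(pv.PharmFeature("donor", np.zeros(3), 0.1), rec)
        np.testing.assert_allclose(f.direction, [1, 0, 0])

    def test_acceptor_fallback_without_hydrogens(self):
        rec = make_receptor([("N", "N", "ALA", 1, (0, 2, 0)),
                             ("C", "CA", "ALA", 1, (0, 0, 1))])
        f = pv.assign_direction(pv.PharmFeature("acceptor", np.zeros(3), 0.1), rec)
        np.testing.assert_allclose(f.direction, [0, 1, 0])

    def test_no_counterpart_leaves_direction_absent(self):
        rec = make_receptor([("C", "CA", "ALA", 1, (1, 1, 1))])
        f = pv.assign_direction(pv.PharmFeature("donor", np.zeros(3), 0.1), rec)
        assert f.direction is None


class TestIonIonFeatures:
    space = ActiveSpace("s", np.zeros(3), 5.0)

    def test_arginine_cz_inside_space(self):
        rec = make_receptor([("C", "CZ", "ARG", 1, (2, 0, 0))])
        feats = pv.ion_ion_features(rec, self.space, ion_ion_retained=True)
        assert len(feats) == 1
        assert feats[0].ftype == "ion_ion"
        assert feats[0].rgyr == 4.0
        assert feats[0].direction is None

    def test_lysine_nz_outside_space_excluded(self):
        rec = make_receptor([("N", "NZ", "LYS", 1, (6, 0, 0))])
        assert pv.ion_ion_features(rec, self.space, True) == []

    def test_not_retained_gives_empty(self):
        rec = make_receptor([("C", "CZ", "ARG", 1, (2, 0, 0))])
        assert pv.ion_ion_features(rec, self.space, False) == []


class TestActiveSpaceFilter:
    def test_boundary_inclusive(self):
        space = ActiveSpace("s", np.zeros(3), 5.0)
        feats = [pv.PharmFeature("donor", (5.0, 0, 0), 0.2),
                 pv.PharmFeature("donor", (5.001, 0, 0), 0.2)]
        kept = pv.filter_by_active_space(feats, space)
        assert len(kept) == 1

    def test_matches_distance_oracle(self, rng):
        space = ActiveSpace("s", rng.normal(size=3), float(rng.uniform(2, 6)))
        for _ in range(100):
            feats = [pv.PharmFeature("aromatic", rng.normal(0, 4, 3), 0.1)
                     for _ in range(int(rng.integers(1, 20)))]
            kept = pv.filter_by_active_space(feats, space)
            oracle = [f for f in feats
                      if np.linalg.norm(f.center - space.center) <= space.radius]
            assert [id(f) for f in kept] == [id(f) for f in oracle]
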