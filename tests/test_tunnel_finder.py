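"""Clearance grid, PDB parsing and Dijkstra tunnel search."""

import numpy as np
import pytest

from egresslab import (ChannelSpec, build_cage_system, compute_clearance_grid,
                       find_tunnels, read_pdb_atoms, write_structure)
from egresslab.tunnel_finder import AtomSet, ClearanceGrid, atoms_from_spec


def _single_atom_set(radius=1.7):
    return AtomSet(elements=np.array(["C"]), names=np.array(["C1"]),
                   residues=np.array(["UNK"]),
                   positions=np.zeros((1, 3)),
                   vdw_radii=np.array([radius]))


class TestReadPdbAtoms:
    PDB = (
        "HETATM    1 FE   HEM A   1      10.000  12.000   8.000  1.00  0.00"
        "          FE\n"
        "ATOM      2  CA  ALA A   2       1.500   2.500   3.500  1.00  0.00"
        "           C\n"
        "ATOM      3  O   HOH A   3       9.000   9.000   9.000  1.00  0.00"
        "           O\n"
        "END\n")

    def test_parses_and_assigns_bondi_radii(self):
        atoms = read_pdb_atoms(self.PDB)
        assert len(atoms) == 2          # water excluded
        fe = atoms.find_atom("FE", "HEM")
        assert atoms.vdw_radii[fe] == pytest.approx(2.0)
        assert np.allclose(atoms.positions[fe], [10.0, 12.0, 8.0])

    def test_het_exclusion(self):
        atoms = read_pdb_atoms(self.PDB, include_het=False)
        assert len(atoms) == 1
        assert atoms.names[0].strip() == "CA"

    def test_truncated_line_skipped_with_warning(self):
        broken = "ATOM      9  CA  GLY A   9      bad\n" + self.PDB
        with pytest.warns(UserWarning, match="malformed"):
            atoms = read_pdb_atoms(broken)
        assert len(atoms) == 2

    def test_no_records_is_format_error(self):
        with pytest.raises(ValueError, match="no parsable"):
            read_pdb_atoms("TITLE     NOTHING HERE\nEND\n")

    def test_unknown_element_default_radius_warning(self):
        odd = ("HETATM    1  Q1  UNK A   1       0.000   0.000   0.000"
               "  1.00  0.00           Q\nEND\n")
        with pytest.warns(UserWarning, match="unknown element"):
            atoms = read_pdb_atoms(odd)
        assert atoms.vdw_radii[0] == pytest.approx(1.7)

    def test_roundtrip_from_write_structure(self, drilled_cage):
        atoms = read_pdb_atoms(write_structure(drilled_cage))
        assert np.allclose(atoms.positions, drilled_cage.positions, atol=1e-3)


class TestClearanceGrid:
    def test_point_clearance_arithmetic(self):
        """Clearance at any voxel center equals |center| - radius exactly."""
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        for probe in ([5.0, 0.0, 0.0], [0.0, 0.0, 0.0], [-3.0, 2.0, 1.0]):
            idx = grid.point_to_index(probe)
            center = grid.index_to_point(idx)
            expected = np.linalg.norm(center) - 1.7
            assert grid.clearance_at(probe) == pytest.approx(expected,
                                                             abs=1e-5)

    def test_covers_atoms_with_margin(self):
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        span = np.array(grid.shape) * grid.spacing
        assert np.all(span >= 2 * (1.7 + 5.0))

    def test_halving_spacing_lipschitz(self):
        """The clearance field is 1-Lipschitz: re-looking up any coarse
        voxel on a finer grid moves the value by at most half the coarse
        voxel diagonal."""
        atoms = _single_atom_set()
        g1 = compute_clearance_grid(atoms, spacing=0.8)
        g2 = compute_clearance_grid(atoms, spacing=0.4)
        rng = np.random.default_rng(0)
        for _ in range(200):
            idx = tuple(rng.integers(0, s) for s in g1.shape)
            p = g1.index_to_point(idx)
            try:
                c2 = g2.clearance_at(p)
            except ValueError:
                continue
            assert abs(c2 - float(g1.values[idx])) <= 0.8 * np.sqrt(3) / 2

    def test_empty_atomset_rejected(self):
        empty = AtomSet(elements=np.array([]), names=np.array([]),
                        residues=np.array([]), positions=np.empty((0, 3)),
                        vdw_radii=np.empty(0))
        with pytest.raises(ValueError):
            compute_clearance_grid(empty)

    def test_point_outside_grid_rejected(self):
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        with pytest.raises(ValueError, match="outside"):
            grid.point_to_index([100.0, 0.0, 0.0])


class TestFindTunnels:
    def test_open_space_straight_line(self):
        """A single distant atom: the cheapest route to the boundary is
        essentially straight and its bottleneck matches the tightest
        clearance along it."""
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        start = np.array([4.0, 0.0, 0.0])
        tunnels = find_tunnels(grid, start, k=1)
        assert len(tunnels) == 1
        t = tunnels[0]
        assert t.bottleneck_radius == pytest.approx(
            t.clearance_profile.min())
        assert t.bottleneck_radius >= grid.clearance_at(start) - 0.5

    def test_drilled_cage_recovers_geometric_radius(self, drilled_cage):
        """Bottleneck of a 2.5 Å drilled channel recovered within one
        grid spacing; exit within 15 degrees of the channel axis."""
        grid = compute_clearance_grid(atoms_from_spec(drilled_cage),
                                      spacing=0.4)
        tunnels = find_tunnels(grid, np.zeros(3), k=3)
        top = tunnels[0]
        r = drilled_cage.channels[0].geometric_radius
        assert r - 0.4 <= top.bottleneck_radius <= r + 0.4
        axis = drilled_cage.channels[0].axis_array
        cosang = top.exit_point @ axis / np.linalg.norm(top.exit_point)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 15.0

    def test_closed_cage_all_bottlenecks_below_water(self, closed_cage):
        grid = compute_clearance_grid(atoms_from_spec(closed_cage),
                                      spacing=0.4)
        tunnels = find_tunnels(grid, np.zeros(3), k=20)
        assert tunnels                      # paths exist through gaps
        assert all(t.bottleneck_radius < 1.4 for t in tunnels)

    def test_bottleneck_bounded_by_start_clearance(self, drilled_cage):
        grid = compute_clearance_grid(atoms_from_spec(drilled_cage),
                                      spacing=0.5)
        start = np.zeros(3)
        c0 = grid.clearance_at(start)
        for t in find_tunnels(grid, start, k=5):
            assert t.bottleneck_radius <= c0 + 1e-9

    def test_exits_mutually_separated(self, closed_cage):
        grid = compute_clearance_grid(atoms_from_spec(closed_cage),
                                      spacing=0.5)
        tunnels = find_tunnels(grid, np.zeros(3), k=10)
        pts = [t.exit_point for t in tunnels]
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.linalg.norm(pts[i] - pts[j]) > 5.0

    def test_inflating_radii_shrinks_bottlenecks(self):
        """Enlarging every atom radius by delta decreases every reported
        bottleneck by at least delta/2."""
        spec = build_cage_system(
            channels=[ChannelSpec("c", (0.0, 0.0, 1.0), 2.5)], seed=5)
        atoms = atoms_from_spec(spec)
        delta = 0.5
        fat = AtomSet(atoms.elements, atoms.names, atoms.residues,
                      atoms.positions.copy(), atoms.vdw_radii + delta)
        g1 = compute_clearance_grid(atoms, spacing=0.4)
        g2 = compute_clearance_grid(fat, spacing=0.4)
        t1 = find_tunnels(g1, np.zeros(3), k=1)[0]
        t2 = find_tunnels(g2, np.zeros(3), k=1)[0]
        assert t2.bottleneck_radius <= t1.bottleneck_radius - delta / 2

    def test_blocked_start_shifts_with_warning(self):
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        with pytest.warns(UserWarning, match="shifted"):
            tunnels = find_tunnels(grid, np.array([1.0, 0.0, 0.0]), k=1)
        assert tunnels

    def test_start_outside_grid_rejected(self):
        grid = compute_clearance_grid(_single_atom_set(), spacing=0.5)
        with pytest.raises(ValueError, match="outside"):
            find_tunnels(grid, np.array([50.0, 0.0, 0.0]))

    def test_dijkstra_matches_bellman_ford_oracle(self):
        """Path costs equal brute-force Bellman-Ford relaxation on a
        small synthetic clearance field."""
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 3.0, size=(9, 9, 9)).astype(np.float32)
        grid = ClearanceGrid(origin=np.zeros(3), spacing=1.0, values=vals)
        start = np.array([4.0, 4.0, 4.0])
        tunnels = find_tunnels(grid, start, k=1)
        assert tunnels

        # independent oracle: exhaustive edge relaxation
        shape = vals.shape
        w = 1.0 / np.maximum(vals.astype(np.float64), 0.05) ** 2
        nodes = list(np.ndindex(shape))
        dist = {n: np.inf for n in nodes}
        dist[(4, 4, 4)] = 0.0
        offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                   for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
        edges = []
        for n in nodes:
            for off in offsets:
                m = tuple(np.array(n) + off)
                if all(0 <= m[d] < shape[d] for d in range(3)):
                    cost = np.linalg.norm(off) * 0.5 * (w[n] + w[m])
                    edges.append((n, m, cost))
        for _ in range(len(nodes)):
            changed = False
            for n, m, c in edges:
                if dist[n] + c < dist[m] - 1e-12:
                    dist[m] = dist[n] + c
                    changed = True
            if not changed:
                break
        boundary = [n for n in nodes
                    if 0 in n or any(n[d] == shape[d] - 1 for d in range(3))]
        best = min(dist[n] for n in boundary)
        assert tunnels[0].cost == pytest.approx(best, rel=1e-9)
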