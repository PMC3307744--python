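"""Geometric tunnel detection from a buried point to the molecular surface.

The detector voxelizes space around an atom set into a *clearance grid*
(each voxel stores the exact distance from its center to the nearest atom
surface, negative inside an atom) and runs Dijkstra shortest-cost search
from a buried start point to the box boundary over 26-connected voxels.
Edge costs are the metric step length times the mean inverse-square
clearance of the two endpoints, which strongly favors wide passages, so the
cheapest paths follow tunnel centerlines.  Each reported tunnel carries its
clearance profile and bottleneck radius; a bottleneck below 1.4 Å (the
water radius) means the passage is closed to even a water molecule.

PDB input goes through biotite; van der Waals radii come from a bundled
Bondi table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree

from .units import BONDI_RADII, DEFAULT_VDW_RADIUS

__all__ = [
    "AtomSet",
    "ClearanceGrid",
    "Tunnel",
    "read_pdb_atoms",
    "atoms_from_spec",
    "compute_clearance_grid",
    "find_tunnels",
]


@dataclass
class AtomSet:
    """Atoms as parallel arrays: element, name, residue, position, radius."""

    elements: np.ndarray       # (n,) str
    names: np.ndarray          # (n,) str
    residues: np.ndarray       # (n,) str
    positions: np.ndarray      # (n, 3) Å
    vdw_radii: np.ndarray      # (n,) Å

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")
        if np.any(self.vdw_radii <= 0):
            raise ValueError("vdw radii must be > 0")

    def __len__(self) -> int:
        return len(self.vdw_radii)

    def select(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(self.elements[mask], self.names[mask],
                       self.residues[mask], self.positions[mask],
                       self.vdw_radii[mask])

    def find_atom(self, name: str, residue: str | None = None) -> int:
        """Index of the first atom matching name (and residue), e.g. the
        heme iron via ``find_atom("FE", "HEM")``."""
        for i in range(len(self)):
            if self.names[i].strip().upper() == name.upper() and (
                    residue is None
                    or self.residues[i].strip().upper() == residue.upper()):
                return i
        raise KeyError(f"no atom {name!r} (residue {residue!r})")


def _vdw_for_elements(elements) -> np.ndarray:
    radii = np.empty(len(elements))
    unknown = set()
    for i, e in enumerate(elements):
        key = str(e).strip().upper()
        if key in BONDI_RADII:
            radii[i] = BONDI_RADII[key]
        else:
            radii[i] = DEFAULT_VDW_RADIUS
            unknown.add(key)
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}: assigned default vdW "
            f"radius {DEFAULT_VDW_RADIUS} Å", stacklevel=2)
    return radii


def read_pdb_atoms(pdb_text: str, include_het: bool = True) -> AtomSet:
    """Parse ATOM/HETATM records of PDB text into an :class:`AtomSet`.

    Waters and alternate locations other than blank/"A" are excluded;
    malformed coordinate lines are skipped with a warning.  Set
    ``include_het=False`` to drop all HETATM records (ligands, cofactors).
    """
    raw = pdb_text.splitlines()
    kept, skipped = [], 0
    for ln in raw:
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        if len(ln) < 54:
            skipped += 1
            continue
        try:
            float(ln[30:38]); float(ln[38:46]); float(ln[46:54])
        except ValueError:
            skipped += 1
            continue
        altloc = ln[16]
        if altloc not in (" ", "A"):
            continue
        res = ln[17:20].strip().upper()
        if res in ("HOH", "WAT", "DOD"):
            continue
        if not include_het and ln.startswith("HETATM"):
            continue
        kept.append(ln)
    if skipped:
        warnings.warn(f"skipped {skipped} malformed ATOM/HETATM line(s)",
                      stacklevel=2)
    if not kept:
        raise ValueError("no parsable ATOM/HETATM records in PDB text")

    from biotite.structure.io.pdb import PDBFile
    pf = PDBFile.read(io.StringIO("\n".join(kept) + "\nEND\n"))
    arr = pf.get_structure(model=1)
    elements = np.array([str(e) for e in arr.element])
    # biotite may leave the element blank on nonstandard records; fall back
    # to the first letter of the atom name
    for i, e in enumerate(elements):
        if not e.strip():
            elements[i] = "".join(c for c in str(arr.atom_name[i]) if c.isalpha())[:1]
    return AtomSet(
        elements=elements,
        names=np.array([str(n) for n in arr.atom_name]),
        residues=np.array([str(r) for r in arr.res_name]),
        positions=np.asarray(arr.coord, dtype=float),
        vdw_radii=_vdw_for_elements(elements),
    )


def atoms_from_spec(spec) -> AtomSet:
    """View a :class:`~egresslab.synthetic_system.ToySystemSpec` as atoms,
    using the spec's own bead radii (receptor/gate beads only, so tunnels
    are searched through the empty interior)."""
    mask = np.array([r != "ligand" for r in spec.roles])
    n = int(mask.sum())
    return AtomSet(
        elements=np.array(["X"] * n),
        names=np.array([f"B{i}" for i in range(n)]),
        residues=np.array(["CAG"] * n),
        positions=spec.positions[mask],
        vdw_radii=spec.vdw_radii[mask],
    )


@dataclass
class ClearanceGrid:
    """Regular 3-D grid of distances to the nearest atom surface (Å)."""

    origin: np.ndarray          # (3,) world position of voxel (0,0,0)
    spacing: float
    values: np.ndarray          # (nx, ny, nz)

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def point_to_index(self, point) -> tuple[int, int, int]:
        idx = np.round((np.asarray(point, dtype=float) - self.origin)
                       / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise ValueError(f"point {point} outside the grid")
        return tuple(int(i) for i in idx)

    def index_to_point(self, idx) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    def clearance_at(self, point) -> float:
        return float(self.values[self.point_to_index(point)])


def compute_clearance_grid(atoms: AtomSet, spacing: float = 0.4,
                           margin: float = 5.0, chunk: int = 200_000
                           ) -> ClearanceGrid:
    """Exact nearest-surface distance field on a regular grid.

    ``clearance(v) = min_i (|v − c_i| − r_i)``; the grid covers all atoms
    plus ``margin`` (≥ 5 Å).  The minimizing atom is found among the
    nearest centers by k-d tree lookup (k = 48 neighbours, ample because
    vdW radii vary by under 1.2 Å).
    """
    if len(atoms) == 0:
        raise ValueError("empty AtomSet")
    margin = max(margin, 5.0)
    rmax = float(atoms.vdw_radii.max())
    lo = atoms.positions.min(axis=0) - rmax - margin
    hi = atoms.positions.max(axis=0) + rmax + margin
    dims = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[d] + spacing * np.arange(dims[d]) for d in range(3)]
    tree = cKDTree(atoms.positions)
    k = min(48, len(atoms))
    values = np.empty(dims, dtype=np.float32)
    # evaluate in flat chunks to bound memory
    pts_idx = np.indices(dims).reshape(3, -1).T
    total = pts_idx.shape[0]
    flat = values.reshape(-1)
    for s in range(0, total, chunk):
        sl = pts_idx[s:s + chunk]
        pts = lo + spacing * sl
        d, j = tree.query(pts, k=k)
        if k == 1:
            d = d[:, None]; j = j[:, None]
        flat[s:s + chunk] = (d - atoms.vdw_radii[j]).min(axis=1)
    return ClearanceGrid(origin=lo, spacing=spacing, values=values)


@dataclass
class Tunnel:
    """A path from the start point to the surface with its clearance profile."""

    path: np.ndarray              # (m, 3) voxel centers, start → exit
    clearance_profile: np.ndarray  # (m,) Å
    bottleneck_radius: float       # min of the profile, Å
    length: float                  # Å
    cost: float                    # Dijkstra path cost (dimensionless·Å)

    @property
    def exit_point(self) -> np.ndarray:
        return self.path[-1]


_OFFSETS = np.array([(dx, dy, dz)
                     for dx in (-1, 0, 1)
                     for dy in (-1, 0, 1)
                     for dz in (-1, 0, 1)
                     if (dx, dy, dz) > (0, 0, 0)], dtype=int)


def find_tunnels(grid: ClearanceGrid, start, k: int = 20,
                 min_clearance: float = 0.0, clearance_floor: float = 0.05,
                 exit_separation: float = 5.0) -> list[Tunnel]:
    """Up to ``k`` lowest-cost tunnels from ``start`` to the grid boundary.

    Paths run over 26-connected voxels with clearance > ``min_clearance``;
    an edge (u, v) costs ``step_length · ½ (w(u) + w(v))`` with
    ``w = 1 / max(clearance, clearance_floor)²``.  Exits are selected
    greedily by ascending path cost with mutual separation
    > ``exit_separation`` Å.  Returns an empty list when no open path
    exists (a fully buried start point).
    """
    vals = grid.values.astype(float)
    shape = vals.shape
    start_idx = grid.point_to_index(start)      # raises if outside

    if vals[start_idx] <= min_clearance:
        # shift to the nearest open voxel within 2 Å
        r_vox = int(np.ceil(2.0 / grid.spacing))
        best, best_d = None, None
        for off in np.ndindex(2 * r_vox + 1, 2 * r_vox + 1, 2 * r_vox + 1):
            idx = tuple(np.array(start_idx) + np.array(off) - r_vox)
            if any(i < 0 or i >= s for i, s in zip(idx, shape)):
                continue
            if vals[idx] > min_clearance:
                d = np.linalg.norm((np.array(idx) - np.array(start_idx))
                                   * grid.spacing)
                if d <= 2.0 and (best_d is None or d < best_d):
                    best, best_d = idx, d
        if best is None:
            raise ValueError(
                "start voxel is blocked and no open voxel lies within 2 Å")
        warnings.warn(
            f"start voxel blocked (clearance {vals[start_idx]:.2f} Å); "
            f"shifted {best_d:.2f} Å to the nearest open voxel", stacklevel=2)
        start_idx = best

    open_mask = vals > min_clearance
    node_id = -np.ones(shape, dtype=np.int64)
    node_id[open_mask] = np.arange(int(open_mask.sum()))
    n_nodes = int(open_mask.sum())
    w_field = 1.0 / np.maximum(vals, clearance_floor) ** 2

    rows, cols, data = [], [], []
    for off in _OFFSETS:
        sl_a = tuple(slice(max(0, -o), s - max(0, o))
                     for o, s in zip(off, shape))
        sl_b = tuple(slice(max(0, o), s - max(0, -o))
                     for o, s in zip(off, shape))
        ok = open_mask[sl_a] & open_mask[sl_b]
        if not ok.any():
            continue
        ia = node_id[sl_a][ok]
        ib = node_id[sl_b][ok]
        step = grid.spacing * float(np.linalg.norm(off))
        wgt = step * 0.5 * (w_field[sl_a][ok] + w_field[sl_b][ok])
        rows.append(ia)
        cols.append(ib)
        data.append(wgt)
    if not rows:
        return []
    graph = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_nodes, n_nodes)).tocsr()
    s_node = int(node_id[start_idx])
    dist, pred = _csgraph_dijkstra(graph, directed=False, indices=s_node,
                                   return_predecessors=True)

    boundary = np.zeros(shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    cand_nodes = node_id[boundary & open_mask]
    cand_nodes = cand_nodes[cand_nodes >= 0]
    cand_nodes = cand_nodes[np.isfinite(dist[cand_nodes])]
    if cand_nodes.size == 0:
        return []
    order = cand_nodes[np.argsort(dist[cand_nodes], kind="stable")]

    # node → grid index lookup
    open_idx = np.argwhere(open_mask)

    chosen: list[int] = []
    chosen_pts: list[np.ndarray] = []
    for node in order:
        pt = grid.index_to_point(open_idx[node])
        if all(np.linalg.norm(pt - q) > exit_separation for q in chosen_pts):
            chosen.append(int(node))
            chosen_pts.append(pt)
            if len(chosen) >= k:
                break

    tunnels = []
    for node in chosen:
        chain = []
        cur = node
        while cur != -9999 and cur >= 0:
            chain.append(cur)
            if cur == s_node:
                break
            cur = int(pred[cur])
        chain.reverse()
        pts = np.array([grid.index_to_point(open_idx[c]) for c in chain])
        prof = np.array([vals[tuple(open_idx[c])] for c in chain])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        tunnels.append(Tunnel(
            path=pts,
            clearance_profile=prof,
            bottleneck_radius=float(prof.min()),
            length=float(seg.sum()),
            cost=float(dist[node]),
        ))
    return tunnels
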