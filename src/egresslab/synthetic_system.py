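"""Seeded coarse-grained receptor–ligand systems with a buried binding site.

The generator builds a "cage": a quasi-uniform shell of repulsive beads on a
sphere, enclosing a single-bead ligand held at the center by an attractive
binding well.  Exit channels are drilled through the shell as cylindrical
openings of configurable radius; a channel may be *gated* by a short
four-bead side-chain whose terminal bead occludes the channel mouth and can
swing out of the way by rotating about a dihedral — a coarse abstraction of
an aromatic side-chain acting as a revolving door over a buried active site.

All systems are pure functions of their arguments (including the seed): the
shell is a Fibonacci sphere lattice rotated by a seeded random rotation, so
two calls with identical arguments produce bit-identical bead positions.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .units import KB  # noqa: F401  (re-exported unit context for docs)

__all__ = [
    "ChannelSpec",
    "GateSpec",
    "ToySystemSpec",
    "ConfigurationError",
    "build_cage_system",
    "write_structure",
    "fibonacci_sphere",
]

#: probe radius used by the closed-cage porosity check (water radius, Å)
WATER_RADIUS = 1.4

# package defaults (coarse stand-ins; see docs/methods.md)
LIGAND_MASS = 118.0      # g/mol, indazole-like
LIGAND_RADIUS = 2.0      # Å
RECEPTOR_RADIUS = 1.7    # Å
RECEPTOR_MASS = 100.0    # g/mol
GATE_RADIUS = 1.7        # Å
GATE_MASS = 78.0         # g/mol, phenyl-like
ANCHOR_K = 30.0          # kcal/mol/Å², receptor-bead tether
GATE_ANCHOR_K = 50.0     # kcal/mol/Å², gate-hinge tether
GATE_BOND_K = 50.0       # kcal/mol/Å², gate bond springs
WELL_WIDTH = 1.5         # Å, Gaussian binding-well width


class ConfigurationError(ValueError):
    """Raised when a requested system geometry is internally inconsistent."""


@dataclass(frozen=True)
class ChannelSpec:
    """One exit channel: a cylindrical opening through the cage shell.

    Parameters
    ----------
    label : str
        Channel name, unique within a system (the field uses names such as
        "2a", "2c" for cytochrome P450 channels).
    axis : (3,) array_like
        Unit vector from the cage center through the channel mouth.
    geometric_radius : float
        Radius of the drilled opening, Å.  The construction places a collar
        of beads so the clearance bottleneck of the opening equals this
        radius up to grid discretization.
    gated : bool
        Whether a gate side-chain occludes the mouth.
    """

    label: str
    axis: tuple[float, float, float]
    geometric_radius: float
    gated: bool = False

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (3,):
            raise ConfigurationError("channel axis must be a 3-vector")
        n = float(np.linalg.norm(ax))
        if abs(n - 1.0) > 1e-9:
            raise ConfigurationError(
                f"channel {self.label!r}: axis norm {n} != 1 (tolerance 1e-9)"
            )
        if self.geometric_radius <= 0:
            raise ConfigurationError(
                f"channel {self.label!r}: geometric_radius must be > 0"
            )
        object.__setattr__(self, "axis", tuple(float(x) for x in ax))

    @property
    def axis_array(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)


@dataclass(frozen=True)
class GateSpec:
    """A rotatable side-chain occluding one channel mouth.

    ``beads`` are the four bead indices (hinge → terminal) defining the gate
    dihedral; they are assigned by :func:`build_cage_system` and may be left
    ``None`` when requesting a gate.  ``barrier_height`` is the full
    rotational barrier of the dihedral term (the terminal bead must cross it
    to revolve past the mouth); ``closed_angle`` is the dihedral at which the
    terminal bead sits over the mouth center, ``open_angle`` a representative
    unobstructed pose.
    """

    channel_label: str
    beads: tuple[int, int, int, int] | None = None
    barrier_height: float = 2.0       # kcal/mol
    closed_angle: float = 0.0         # degrees
    open_angle: float = 120.0         # degrees

    def __post_init__(self):
        if self.barrier_height < 0:
            raise ConfigurationError("gate barrier_height must be >= 0")
        if self.beads is not None:
            b = tuple(int(i) for i in self.beads)
            if len(b) != 4 or len(set(b)) != 4:
                raise ConfigurationError("gate beads must be 4 distinct indices")
            object.__setattr__(self, "beads", b)


@dataclass
class ToySystemSpec:
    """Complete description of a coarse-grained receptor–ligand system.

    Bead arrays are index-aligned: ``roles[i]``, ``positions[i]``,
    ``vdw_radii[i]``, ``masses[i]`` describe bead ``i``.  Roles are
    ``receptor`` (shell/collar), ``gate``, ``ligand`` (exactly one) and
    ``anchor`` (receptor beads designated as positional-restraint sites for
    pulling simulations).

    ``bonds`` are harmonic springs ``(i, j, k, r0)`` with
    ``U = ½ k (r − r0)²``; ``dihedrals`` are ``(i, j, k, l, k_dih, n, phase)``
    with ``U = k_dih (1 + cos(n φ − phase))`` (phase in degrees);
    ``anchors`` are positional tethers ``(i, site, k)`` with
    ``U = ½ k |r − site|²``; ``exclusions`` lists bead pairs whose pairwise
    repulsion is skipped (bonded neighbours).  The binding well is an
    attractive Gaussian acting on the ligand only.
    """

    roles: list[str]
    positions: np.ndarray          # (n, 3) Å
    vdw_radii: np.ndarray          # (n,) Å
    masses: np.ndarray             # (n,) g/mol
    bonds: list[tuple[int, int, float, float]]
    dihedrals: list[tuple[int, int, int, int, float, int, float]]
    anchors: list[tuple[int, np.ndarray, float]]
    exclusions: list[tuple[int, int]]
    channels: list[ChannelSpec]
    gates: list[GateSpec]
    binding_well: tuple[np.ndarray, float, float]   # (center, depth, width)
    cage_radius: float
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.roles)
        if self.positions.shape != (n, 3):
            raise ConfigurationError("positions shape mismatch with roles")
        if not np.all(np.isfinite(self.positions)):
            raise ConfigurationError("non-finite bead positions")
        if np.any(self.masses <= 0):
            raise ConfigurationError("all masses must be > 0")
        if np.any(self.vdw_radii <= 0):
            raise ConfigurationError("all vdw radii must be > 0")
        lig = [i for i, r in enumerate(self.roles) if r == "ligand"]
        if len(lig) != 1:
            raise ConfigurationError(
                f"exactly one ligand bead required, found {len(lig)}"
            )
        center = np.asarray(self.binding_well[0], dtype=float)
        if np.linalg.norm(self.positions[lig[0]] - center) >= self.cage_radius:
            raise ConfigurationError("ligand initial position outside the cage")
        labels = [c.label for c in self.channels]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("channel labels must be unique")

    # ------------------------------------------------------------------ #

    @property
    def n_beads(self) -> int:
        return len(self.roles)

    @property
    def ligand_index(self) -> int:
        return self.roles.index("ligand")

    @property
    def ligand_mass(self) -> float:
        return float(self.masses[self.ligand_index])

    @property
    def anchor_indices(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == "anchor"]

    @property
    def well_center(self) -> np.ndarray:
        return np.asarray(self.binding_well[0], dtype=float)

    # ------------------------- serialization -------------------------- #

    def to_dict(self) -> dict:
        return {
            "roles": list(self.roles),
            "positions": self.positions.tolist(),
            "vdw_radii": self.vdw_radii.tolist(),
            "masses": self.masses.tolist(),
            "bonds": [list(b) for b in self.bonds],
            "dihedrals": [list(d) for d in self.dihedrals],
            "anchors": [[i, np.asarray(s).tolist(), k] for i, s, k in self.anchors],
            "exclusions": [list(p) for p in self.exclusions],
            "channels": [
                {
                    "label": c.label,
                    "axis": list(c.axis),
                    "geometric_radius": c.geometric_radius,
                    "gated": c.gated,
                }
                for c in self.channels
            ],
            "gates": [
                {
                    "channel_label": g.channel_label,
                    "beads": list(g.beads) if g.beads is not None else None,
                    "barrier_height": g.barrier_height,
                    "closed_angle": g.closed_angle,
                    "open_angle": g.open_angle,
                }
                for g in self.gates
            ],
            "binding_well": [
                np.asarray(self.binding_well[0]).tolist(),
                float(self.binding_well[1]),
                float(self.binding_well[2]),
            ],
            "cage_radius": self.cage_radius,
            "temperature": self.temperature,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToySystemSpec":
        return cls(
            roles=list(d["roles"]),
            positions=np.asarray(d["positions"], dtype=float),
            vdw_radii=np.asarray(d["vdw_radii"], dtype=float),
            masses=np.asarray(d["masses"], dtype=float),
            bonds=[tuple(b) for b in d["bonds"]],
            dihedrals=[tuple(x) for x in d["dihedrals"]],
            anchors=[(int(i), np.asarray(s, dtype=float), float(k))
                     for i, s, k in d["anchors"]],
            exclusions=[tuple(p) for p in d["exclusions"]],
            channels=[ChannelSpec(**c) for c in d["channels"]],
            gates=[
                GateSpec(
                    channel_label=g["channel_label"],
                    beads=tuple(g["beads"]) if g["beads"] is not None else None,
                    barrier_height=g["barrier_height"],
                    closed_angle=g["closed_angle"],
                    open_angle=g["open_angle"],
                )
                for g in d["gates"]
            ],
            binding_well=(
                np.asarray(d["binding_well"][0], dtype=float),
                float(d["binding_well"][1]),
                float(d["binding_well"][2]),
            ),
            cage_radius=float(d["cage_radius"]),
            temperature=float(d["temperature"]),
            seed=int(d["seed"]),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ToySystemSpec":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------- #
#                            construction                                #
# ---------------------------------------------------------------------- #

def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _seeded_rotation(seed: int) -> np.ndarray:
    """Uniform random rotation matrix, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    # quaternion method
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _angular_halfwidth(radius: float, bead_radius: float, cage_radius: float) -> float:
    s = min(1.0, (radius + bead_radius) / cage_radius)
    return float(np.arcsin(s))


def _tangent_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal tangents completing ``u`` to a right-handed frame."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def _slide_on_sphere(shell: np.ndarray, obstacles: np.ndarray,
                     min_sep: float, radius: float,
                     mutual_sep: float | None = None,
                     n_iter: int = 30) -> np.ndarray:
    """Relax shell beads on the sphere away from fixed obstacles.

    Beads are pushed tangentially until they are ``min_sep`` from every
    obstacle and ``mutual_sep`` from each other (sliding rather than
    deleting keeps the shell watertight around channel collars and gate
    hardware).  Deterministic fixed-point iteration.
    """
    shell = shell.copy()
    if mutual_sep is None:
        mutual_sep = min_sep - 0.2

    def _tangent_away(s, o):
        shat = s / np.linalg.norm(s)
        away = (s - o) - ((s - o) @ shat) * shat
        na = np.linalg.norm(away)
        if na < 1e-9:
            away = np.cross(shat, [0.0, 0.0, 1.0])
            if np.linalg.norm(away) < 1e-9:
                away = np.cross(shat, [1.0, 0.0, 0.0])
            na = np.linalg.norm(away)
        return away / na

    for _ in range(n_iter):
        moved = False
        d = np.linalg.norm(shell[:, None, :] - obstacles[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        dmin = d[np.arange(len(shell)), nearest]
        for i in np.flatnonzero(dmin < min_sep):
            step = (min_sep - dmin[i]) + 0.05
            s_new = shell[i] + step * _tangent_away(shell[i], obstacles[nearest[i]])
            shell[i] = s_new / np.linalg.norm(s_new) * radius
            moved = True
        dd = np.linalg.norm(shell[:, None, :] - shell[None, :, :], axis=2)
        np.fill_diagonal(dd, np.inf)
        ii, jj = np.where(np.triu(dd < mutual_sep))
        for i, j in zip(ii, jj):
            gap = np.linalg.norm(shell[i] - shell[j])
            if gap >= mutual_sep:
                continue
            step = 0.5 * (mutual_sep - gap) + 0.02
            for a, b in ((i, j), (j, i)):
                s_new = shell[a] + step * _tangent_away(shell[a], shell[b])
                shell[a] = s_new / np.linalg.norm(s_new) * radius
            moved = True
        if not moved:
            break
    return shell


def _check_porosity(positions: np.ndarray, radii: np.ndarray,
                    cage_radius: float, n_probe: int) -> float:
    """Max clearance (Å) over probe directions on the shell sphere."""
    probes = fibonacci_sphere(n_probe) * cage_radius
    # clearance = distance from probe point to nearest bead surface
    d = np.linalg.norm(probes[:, None, :] - positions[None, :, :], axis=2)
    clear = (d - radii[None, :]).min(axis=1)
    return float(clear.max())


def build_cage_system(
    cage_radius: float = 12.0,
    n_shell_beads: int = 150,
    channels: list[ChannelSpec] | None = None,
    gates: list[GateSpec] | None = None,
    well_depth: float = 4.0,
    seed: int = 0,
    *,
    receptor_radius: float = RECEPTOR_RADIUS,
    ligand_radius: float = LIGAND_RADIUS,
    ligand_mass: float = LIGAND_MASS,
    temperature: float = 300.0,
) -> ToySystemSpec:
    """Generate a closed cage with optional drilled (and gated) channels.

    The shell is a Fibonacci lattice of ``n_shell_beads`` receptor beads on a
    sphere of ``cage_radius``, rotated by a seeded random rotation.  For each
    channel, shell beads intruding into the cylindrical opening are removed
    and a collar ring of beads is laid at perpendicular distance
    ``geometric_radius + receptor_radius`` from the axis, so the opening's
    clearance bottleneck equals ``geometric_radius``.  Gated channels get a
    four-bead side-chain hinged at the rim whose terminal bead covers the
    mouth center in the closed dihedral state.

    Raises
    ------
    ConfigurationError
        If a closed cage (no channels) is porous to a 1.4 Å water probe, or
        if two channel openings overlap on the shell.
    """
    channels = list(channels or [])
    gates = list(gates or [])

    for g in gates:
        if g.channel_label not in {c.label for c in channels}:
            raise ConfigurationError(
                f"gate references unknown channel {g.channel_label!r}"
            )

    # pairwise channel separation: openings must not overlap
    for a in range(len(channels)):
        for b in range(a + 1, len(channels)):
            ca, cb = channels[a], channels[b]
            ang = np.arccos(np.clip(np.dot(ca.axis_array, cb.axis_array), -1, 1))
            wa = _angular_halfwidth(ca.geometric_radius, receptor_radius, cage_radius)
            wb = _angular_halfwidth(cb.geometric_radius, receptor_radius, cage_radius)
            if ang <= 2.0 * max(wa, wb):
                raise ConfigurationError(
                    f"channels {ca.label!r} and {cb.label!r} overlap: "
                    f"axis separation {np.degrees(ang):.1f}° <= "
                    f"2 x angular width {np.degrees(2 * max(wa, wb)):.1f}°"
                )

    rot = _seeded_rotation(seed)
    shell = fibonacci_sphere(n_shell_beads) @ rot.T * cage_radius

    # drill channels: drop shell beads whose surface intrudes into the opening
    keep = np.ones(len(shell), dtype=bool)
    for c in channels:
        u = c.axis_array
        axial = shell @ u
        perp = np.linalg.norm(shell - np.outer(axial, u), axis=1)
        intrudes = (perp < c.geometric_radius + receptor_radius) & (axial > 0)
        keep &= ~intrudes
    shell = shell[keep]

    # collar rings: put the rim at exactly geometric_radius + receptor_radius
    collar_rings = []
    for c in channels:
        u = c.axis_array
        t1, t2 = _tangent_frame(u)
        rho = c.geometric_radius + receptor_radius
        if rho < cage_radius:
            z = np.sqrt(cage_radius**2 - rho**2)
        else:
            z = 0.0
        n_ring = max(6, int(np.ceil(2 * np.pi * rho / (1.8 * receptor_radius))))
        th = 2 * np.pi * np.arange(n_ring) / n_ring
        ring = (
            rho * np.cos(th)[:, None] * t1[None, :]
            + rho * np.sin(th)[:, None] * t2[None, :]
            + z * u[None, :]
        )
        collar_rings.append(ring)

    if collar_rings:
        collar = np.vstack(collar_rings)
        # slide clashing shell beads along the sphere away from the collar
        # (removal would open a weak annulus just outside the rim)
        shell = _slide_on_sphere(shell, collar, 2.0 * receptor_radius - 0.4,
                                 cage_radius)
        pos = np.vstack([shell, collar])
    else:
        pos = shell
    roles = ["receptor"] * len(pos)

    # gates: 4-bead revolving door per gated channel
    bonds: list[tuple[int, int, float, float]] = []
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = []
    exclusions: list[tuple[int, int]] = []
    gate_specs: list[GateSpec] = []
    gate_rows: list[np.ndarray] = []
    gate_anchor_rows: list[tuple[int, np.ndarray, float]] = []

    n_fixed = len(pos)
    gate_offset = n_fixed
    for g in gates:
        c = next(ch for ch in channels if ch.label == g.channel_label)
        if not c.gated:
            c = dataclasses.replace(c, gated=True)
            channels[[ch.label for ch in channels].index(g.channel_label)] = c
        u = c.axis_array
        t1, t2 = _tangent_frame(u)
        mouth = cage_radius * u
        rim = mouth + (c.geometric_radius + GATE_RADIUS) * t1
        L = c.geometric_radius + GATE_RADIUS      # hinge-to-terminal reach
        b1 = rim - 1.8 * t2 - 1.8 * t1
        b2 = rim - 1.8 * t2
        b3 = rim
        # closed state: terminal bead over the mouth center, rotated by
        # closed_angle about the hinge axis t2 from the -t1 (cis) reference
        phi0 = np.radians(g.closed_angle)
        b4 = b3 + L * (-np.cos(phi0) * t1 + np.sin(phi0) * u)
        i1, i2, i3, i4 = (gate_offset, gate_offset + 1,
                          gate_offset + 2, gate_offset + 3)
        gate_offset += 4
        gate_rows.append(np.array([b1, b2, b3, b4]))
        roles += ["gate"] * 4
        # hinge beads tethered; terminal bead held by two bonds (distance to
        # b3 and to b2), leaving rotation about the b2-b3 axis as the soft mode
        for idx, site in ((i1, b1), (i2, b2), (i3, b3)):
            gate_anchor_rows.append((idx, site, GATE_ANCHOR_K))
        bonds.append((i3, i4, GATE_BOND_K, float(L)))
        bonds.append((i2, i4, GATE_BOND_K, float(np.linalg.norm(b4 - b2))))
        k_dih = g.barrier_height / 2.0
        phase = 180.0 + g.closed_angle
        dihedrals.append((i1, i2, i3, i4, k_dih, 1, phase))
        gate_specs.append(dataclasses.replace(g, beads=(i1, i2, i3, i4)))
        for a_ in (i1, i2, i3, i4):
            for b_ in (i1, i2, i3, i4):
                if a_ < b_:
                    exclusions.append((a_, b_))

    if gate_rows:
        # wall beads essentially replaced by the anchored hinge are dropped;
        # the rest are slid along the sphere so no weak annulus opens
        gpos = np.vstack(gate_rows)
        d = np.linalg.norm(pos[:n_fixed, None, :] - gpos[None, :, :], axis=2)
        clash = d.min(axis=1) < (receptor_radius + GATE_RADIUS - 1.2)
        keep_fixed = _slide_on_sphere(pos[:n_fixed][~clash], gpos,
                                      receptor_radius + GATE_RADIUS - 0.4,
                                      cage_radius)
        n_keep = len(keep_fixed)
        remap = -np.ones(n_fixed + len(gpos), dtype=int)
        remap[np.flatnonzero(~clash)] = np.arange(n_keep)
        remap[n_fixed:] = np.arange(n_keep, n_keep + len(gpos))
        pos = np.vstack([keep_fixed, gpos])
        roles = [r for i, r in enumerate(roles[:n_fixed]) if not clash[i]] \
            + roles[n_fixed:]
        bonds = [(int(remap[i]), int(remap[j]), k, r0) for i, j, k, r0 in bonds]
        dihedrals = [
            (int(remap[i]), int(remap[j]), int(remap[k]), int(remap[l]), kd, n, ph)
            for i, j, k, l, kd, n, ph in dihedrals
        ]
        exclusions = [(int(remap[i]), int(remap[j])) for i, j in exclusions]
        gate_anchor_rows = [(int(remap[i]), s, k) for i, s, k in gate_anchor_rows]
        gate_specs = [
            dataclasses.replace(g, beads=tuple(int(remap[b]) for b in g.beads))
            for g in gate_specs
        ]

    # ligand at well center (= cage center)
    center = np.zeros(3)
    lig_idx = len(pos)
    pos = np.vstack([pos, center[None, :]])
    roles.append("ligand")

    n = len(pos)
    radii = np.empty(n)
    masses = np.empty(n)
    for i, r in enumerate(roles):
        if r == "ligand":
            radii[i], masses[i] = ligand_radius, ligand_mass
        elif r == "gate":
            radii[i], masses[i] = GATE_RADIUS, GATE_MASS
        else:
            radii[i], masses[i] = receptor_radius, RECEPTOR_MASS

    # anchors: every receptor bead tethered to its generated site
    anchors: list[tuple[int, np.ndarray, float]] = [
        (i, pos[i].copy(), ANCHOR_K) for i, r in enumerate(roles) if r == "receptor"
    ]
    anchors += gate_anchor_rows

    # designate 3 pulling-restraint anchor beads on the far side of the
    # first channel (or arbitrary spaced beads for a closed cage)
    ref_axis = channels[0].axis_array if channels else np.array([0.0, 0.0, 1.0])
    receptor_idx = [i for i, r in enumerate(roles) if r == "receptor"]
    proj = pos[receptor_idx] @ ref_axis
    far = np.argsort(proj)[:3]
    for j in far:
        roles[receptor_idx[j]] = "anchor"

    spec = ToySystemSpec(
        roles=roles,
        positions=pos,
        vdw_radii=radii,
        masses=masses,
        bonds=bonds,
        dihedrals=dihedrals,
        anchors=anchors,
        exclusions=exclusions,
        channels=channels,
        gates=gate_specs,
        binding_well=(center, float(well_depth), WELL_WIDTH),
        cage_radius=float(cage_radius),
        temperature=float(temperature),
        seed=int(seed),
    )

    if not channels:
        shell_mask = np.array([r in ("receptor", "anchor") for r in roles])
        gap = _check_porosity(
            pos[shell_mask], radii[shell_mask], cage_radius,
            n_probe=max(2000, 10 * n_shell_beads),
        )
        if gap >= WATER_RADIUS:
            raise ConfigurationError(
                f"closed cage is porous: max surface clearance {gap:.2f} Å >= "
                f"{WATER_RADIUS} Å; increase n_shell_beads"
            )
    return spec


# ---------------------------------------------------------------------- #
#                              PDB output                                #
# ---------------------------------------------------------------------- #

_ROLE_PDB = {
    "receptor": ("C", "CAG"),
    "anchor": ("N", "ANC"),
    "gate": ("S", "GAT"),
    "ligand": ("P", "LIG"),
}


def write_structure(spec: ToySystemSpec, state=None) -> str:
    """Render a system (optionally at a simulation state) as PDB text.

    Beads are written as HETATM records with role-specific element symbols
    and residue names; the single ligand bead gets residue name ``LIG``.
    Coordinates round-trip through :func:`egresslab.tunnel_finder.read_pdb_atoms`
    to PDB precision (1e-3 Å).
    """
    if state is None:
        coords = spec.positions
    else:
        coords = np.asarray(state.positions, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("empty state: no coordinates to write")
    if coords.shape[0] != spec.n_beads:
        raise ValueError(
            f"state has {coords.shape[0]} beads, spec has {spec.n_beads}"
        )
    lines = []
    for i, (role, xyz) in enumerate(zip(spec.roles, coords)):
        elem, res = _ROLE_PDB[role]
        name = f"{elem}{(i % 99) + 1}"
        lines.append(
            f"HETATM{i + 1:>5d} {name:<4s}{res:>4s} A{(i % 9999) + 1:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {elem:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_structure_file(spec: ToySystemSpec, path, state=None) -> None:
    with open(path, "w") as fh:
        fh.write(write_structure(spec, state))


def _warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
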