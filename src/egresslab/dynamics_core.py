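"""Forces and Langevin (BAOAB) / velocity-Verlet dynamics for toy systems.

The force field is deliberately minimal: a steep pairwise repulsion
(``U = ε (σij/r)¹²`` truncated and shifted at a cutoff, ``σij`` the sum of
the two bead vdW radii), harmonic bonds and positional tethers
(``U = ½ k Δ²``), cosine dihedral terms, and one attractive Gaussian
binding well acting on the ligand bead.  There are no electrostatics, no
solvent and no periodic box; a reflecting sphere far outside the cage keeps
escaped ligands finite.

The integrator is BAOAB Langevin; with friction 0 the O-step is the
identity and the scheme reduces exactly to velocity Verlet, which the test
suite exploits for energy-conservation checks.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._geometry import dihedral_angle_and_grad
from .synthetic_system import ToySystemSpec
from .units import ACC_CONV, KB

__all__ = [
    "SimState",
    "ForceField",
    "Trajectory",
    "IntegrationError",
    "SingularGeometryError",
    "initial_state",
    "compute_forces",
    "langevin_step",
    "run_md",
    "default_schedule",
    "ForceEvaluator",
]


class SingularGeometryError(ValueError):
    """Two beads coincide; pair forces are undefined."""


class IntegrationError(RuntimeError):
    """Non-finite forces or coordinates encountered during propagation."""


@dataclass
class SimState:
    """Instantaneous state of a simulation: time, coordinates, velocities
    and a reproducible random-generator token."""

    time: float                      # ps
    positions: np.ndarray            # (n, 3) Å
    velocities: np.ndarray           # (n, 3) Å/ps
    rng: np.random.Generator

    def copy(self) -> "SimState":
        return SimState(
            time=self.time,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            rng=copy.deepcopy(self.rng),
        )


def initial_state(spec: ToySystemSpec, seed: int, temperature: float | None = None,
                  thermal_velocities: bool = True) -> SimState:
    """State at the generated coordinates with Maxwell-Boltzmann velocities."""
    rng = np.random.default_rng(seed)
    T = spec.temperature if temperature is None else temperature
    n = spec.n_beads
    if thermal_velocities and T > 0:
        sigma = np.sqrt(ACC_CONV * KB * T / spec.masses)[:, None]
        v = rng.normal(size=(n, 3)) * sigma
    else:
        v = np.zeros((n, 3))
    return SimState(time=0.0, positions=spec.positions.copy(),
                    velocities=v, rng=rng)


@dataclass
class ForceField:
    """Force-field parameters layered on a :class:`ToySystemSpec`.

    ``restraints`` are extra positional tethers ``(bead, site, k)`` beyond
    the spec's built-in anchors (used e.g. for pulling-run restraints).
    """

    eps: float = 5.0                  # kcal/mol, repulsion prefactor
    cutoff: float = 10.0              # Å, nonbonded truncation
    restraints: list[tuple[int, np.ndarray, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class Trajectory:
    """Sampled frames of one run with per-frame energies (kcal/mol)."""

    times: np.ndarray                # (F,) ps, strictly increasing
    positions: np.ndarray            # (F, n, 3) Å
    potential: np.ndarray            # (F,)
    kinetic: np.ndarray              # (F,)

    def __post_init__(self):
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def total_energy(self) -> np.ndarray:
        return self.potential + self.kinetic

    def instantaneous_temperature(self, masses: np.ndarray) -> np.ndarray:
        ndof = 3 * self.positions.shape[1]
        return 2.0 * self.kinetic / (ndof * KB)

    def to_xyz(self, roles: list[str] | None = None) -> str:
        """XYZ text, one block per frame."""
        n = self.positions.shape[1]
        names = (
            [r[:1].upper() for r in roles] if roles is not None else ["X"] * n
        )
        out = []
        for f in range(self.n_frames):
            out.append(str(n))
            out.append(f"t= {self.times[f]:.6f} ps")
            for i in range(n):
                x, y, z = self.positions[f, i]
                out.append(f"{names[i]} {x:.5f} {y:.5f} {z:.5f}")
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------- #
#                           force evaluation                             #
# ---------------------------------------------------------------------- #

class ForceEvaluator:
    """Pre-compiled force routine for one (spec, force-field) pair.

    Precomputes the σij matrix, exclusion mask, bonded-term arrays and
    restraint arrays so the per-step cost is a handful of vectorized numpy
    operations on (n, n) arrays.
    """

    #: Verlet-list skin, Å; the candidate pair list is rebuilt whenever any
    #: bead has moved more than half the skin since the last rebuild.
    SKIN = 2.0

    def __init__(self, spec: ToySystemSpec, ff: ForceField):
        self.spec = spec
        self.ff = ff
        n = spec.n_beads
        self.n = n
        r = spec.vdw_radii
        self.cut2 = ff.cutoff ** 2
        excluded = set()
        for i, j in spec.exclusions:
            excluded.add((min(i, j), max(i, j)))
        for i, j, *_ in spec.bonds:
            excluded.add((min(i, j), max(i, j)))
        ii, jj = np.triu_indices(n, k=1)
        if excluded:
            ex = np.array(sorted(excluded))
            flat = ii * n + jj
            keep = ~np.isin(flat, ex[:, 0] * n + ex[:, 1])
            ii, jj = ii[keep], jj[keep]
        self._pi_all = ii
        self._pj_all = jj
        self._sig12_all = (r[ii] + r[jj]) ** 12
        # truncation shift so U(cutoff) = 0
        self._shift_all = self._sig12_all / self.cut2 ** 6
        self._nl_ref: np.ndarray | None = None
        self._nl_sel: np.ndarray | None = None

        self.bonds = spec.bonds
        self.dihedrals = spec.dihedrals
        tethers = list(spec.anchors) + list(ff.restraints)
        if tethers:
            self.t_idx = np.array([t[0] for t in tethers], dtype=int)
            self.t_site = np.array([np.asarray(t[1], dtype=float) for t in tethers])
            self.t_k = np.array([t[2] for t in tethers], dtype=float)
        else:
            self.t_idx = np.empty(0, dtype=int)
            self.t_site = np.empty((0, 3))
            self.t_k = np.empty(0)
        self.lig = spec.ligand_index
        self.well_center = spec.well_center
        self.well_depth = float(spec.binding_well[1])
        self.well_width = float(spec.binding_well[2])
        self.masses = spec.masses

    def _candidate_pairs(self, x: np.ndarray):
        """Pairs possibly within the cutoff (Verlet list with skin)."""
        if self._pi_all.size == 0:
            return self._pi_all, self._pj_all, self._sig12_all, self._shift_all
        if self._nl_ref is not None:
            disp2 = np.max(np.sum((x - self._nl_ref) ** 2, axis=1))
            if disp2 < (0.5 * self.SKIN) ** 2:
                s = self._nl_sel
                return (self._pi_all[s], self._pj_all[s],
                        self._sig12_all[s], self._shift_all[s])
        d = x[self._pi_all] - x[self._pj_all]
        r2 = np.einsum("ij,ij->i", d, d)
        self._nl_sel = np.flatnonzero(r2 < (self.ff.cutoff + self.SKIN) ** 2)
        self._nl_ref = x.copy()
        s = self._nl_sel
        return (self._pi_all[s], self._pj_all[s],
                self._sig12_all[s], self._shift_all[s])

    def __call__(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        """Forces (kcal·mol⁻¹·Å⁻¹) and potential energy (kcal/mol) at x."""
        n = self.n
        F = np.zeros((n, 3))
        U = 0.0

        # pair repulsion over the neighbor list
        pi, pj, sig12, shift = self._candidate_pairs(x)
        if pi.size:
            d = x[pi] - x[pj]
            r2 = np.einsum("ij,ij->i", d, d)
            act = r2 < self.cut2
            if act.any():
                r2a = r2[act]
                if (r2a < 1e-16).any():
                    b = int(np.flatnonzero(act)[np.argmin(r2a)])
                    raise SingularGeometryError(
                        f"beads {pi[b]} and {pj[b]} coincide")
                inv_r12 = sig12[act] / r2a ** 6
                U += float(np.sum(self.ff.eps * (inv_r12 - shift[act])))
                fac = 12.0 * self.ff.eps * inv_r12 / r2a
                fv = fac[:, None] * d[act]
                pia, pja = pi[act], pj[act]
                for c in range(3):
                    F[:, c] += np.bincount(pia, fv[:, c], minlength=n)
                    F[:, c] -= np.bincount(pja, fv[:, c], minlength=n)

        # harmonic bonds U = ½ k (r - r0)²
        for i, j, k, r0 in self.bonds:
            d = x[i] - x[j]
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                raise SingularGeometryError(f"bonded beads {i} and {j} coincide")
            U += 0.5 * k * (r - r0) ** 2
            fv = -k * (r - r0) / r * d
            F[i] += fv
            F[j] -= fv

        # cosine dihedrals U = k (1 + cos(nφ - phase))
        for i, j, k_, l, kd, mult, phase in self.dihedrals:
            try:
                phi, grads = dihedral_angle_and_grad(x[i], x[j], x[k_], x[l])
            except ValueError:
                raise IntegrationError(
                    f"collinear dihedral {i}-{j}-{k_}-{l}"
                ) from None
            arg = mult * phi - np.radians(phase)
            U += kd * (1.0 + np.cos(arg))
            dU = -kd * mult * np.sin(arg)
            for idx, g in zip((i, j, k_, l), grads):
                F[idx] -= dU * g

        # positional tethers U = ½ k |r - site|²
        if len(self.t_idx):
            d = x[self.t_idx] - self.t_site
            U += 0.5 * float(np.sum(self.t_k * np.einsum("ij,ij->i", d, d)))
            np.add.at(F, self.t_idx, -self.t_k[:, None] * d)

        # Gaussian binding well on the ligand
        if self.well_depth != 0.0:
            d = x[self.lig] - self.well_center
            s = float(d @ d)
            w2 = self.well_width ** 2
            e = self.well_depth * np.exp(-s / (2 * w2))
            U -= e
            F[self.lig] += -e / w2 * d

        return F, U


def compute_forces(state: SimState, spec: ToySystemSpec, ff: ForceField
                   ) -> tuple[np.ndarray, float]:
    """Forces and potential energy at the state's coordinates.

    Forces are the exact negative gradient of the potential terms; pairs
    beyond the cutoff contribute zero force.
    """
    return ForceEvaluator(spec, ff)(state.positions)


# ---------------------------------------------------------------------- #
#                              integration                               #
# ---------------------------------------------------------------------- #

def _baoab(ev: ForceEvaluator, x, v, F, dt, friction, T, rng,
           inv_m, extra_force=None, reflect_radius=None):
    """One BAOAB step operating on raw arrays.  Returns (x, v, F, U)."""
    half = 0.5 * dt
    v = v + half * (F * inv_m) * ACC_CONV
    x = x + half * v
    if friction > 0.0:
        c1 = np.exp(-friction * dt)
        if T > 0.0:
            sig = np.sqrt(ACC_CONV * KB * T * inv_m[:, 0] * (1.0 - c1 * c1))
            v = c1 * v + sig[:, None] * rng.standard_normal(v.shape)
        else:
            v = c1 * v
    x = x + half * v
    if reflect_radius is not None:
        rr = np.linalg.norm(x, axis=1)
        out = rr > reflect_radius
        if out.any():
            unit = x[out] / rr[out, None]
            x = x.copy()
            x[out] = unit * (2.0 * reflect_radius - rr[out])[:, None]
            vr = np.einsum("ij,ij->i", v[out], unit)
            v = v.copy()
            v[out] -= 2.0 * vr[:, None] * unit
    F, U = ev(x)
    if not np.all(np.isfinite(F)):
        bad = int(np.flatnonzero(~np.isfinite(F).all(axis=1))[0])
        raise IntegrationError(f"non-finite force on bead {bad}")
    v = v + half * (F * inv_m) * ACC_CONV
    return x, v, F, U


def langevin_step(state: SimState, spec: ToySystemSpec, ff: ForceField,
                  dt: float, friction: float = 1.0, T: float = 300.0
                  ) -> SimState:
    """Advance one BAOAB Langevin step (velocity Verlet when friction = 0).

    The input state is not modified; the returned state carries an advanced
    copy of the random generator, so stepping is reproducible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if friction < 0 or T < 0:
        raise ValueError("friction and T must be non-negative")
    ev = ForceEvaluator(spec, ff)
    new = state.copy()
    inv_m = (1.0 / spec.masses)[:, None]
    F, _ = ev(new.positions)
    x, v, _, _ = _baoab(ev, new.positions, new.velocities, F, dt, friction, T,
                        new.rng, inv_m,
                        reflect_radius=3.0 * spec.cage_radius)
    new.positions, new.velocities = x, v
    new.time = state.time + dt
    return new


def kinetic_energy(v: np.ndarray, masses: np.ndarray) -> float:
    return float(np.sum(masses[:, None] * v * v) / (2.0 * ACC_CONV))


def default_schedule(T: float = 300.0, heat: float = 10.0, hold: float = 40.0,
                     friction: float = 1.0):
    """Heating then equilibration: linear 0→T over ``heat`` ps, hold ``hold`` ps."""
    return [(heat, (0.0, T), friction), (hold, T, friction)]


def run_md(spec: ToySystemSpec, ff: ForceField,
           schedule=None, dt: float = 0.002, seed: int = 0,
           sample_every: int = 10, start: SimState | None = None
           ) -> tuple[Trajectory, SimState]:
    """Run a thermostatted (or NVE) schedule of segments.

    ``schedule`` is a list of ``(duration_ps, T, friction)``; ``T`` may be a
    ``(T0, T1)`` pair for a linear ramp within the segment.  The default is
    a linear heat 0→300 K followed by a hold at 300 K.  Returns the sampled
    trajectory (frame 0 included) and the final state.  Deterministic for a
    fixed seed.
    """
    if schedule is None:
        schedule = default_schedule(spec.temperature)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    ev = ForceEvaluator(spec, ff)
    st = (start.copy() if start is not None
          else initial_state(spec, seed, thermal_velocities=False))
    rng = st.rng
    x, v = st.positions, st.velocities
    inv_m = (1.0 / spec.masses)[:, None]
    reflect = 3.0 * spec.cage_radius

    F, U = ev(x)
    times = [st.time]
    frames = [x.copy()]
    pot = [U]
    kin = [kinetic_energy(v, spec.masses)]
    t = st.time
    step_count = 0
    for duration, T, friction in schedule:
        n_steps = int(round(duration / dt))
        ramp = isinstance(T, (tuple, list))
        for s in range(n_steps):
            Tcur = (T[0] + (T[1] - T[0]) * (s + 1) / n_steps) if ramp else T
            try:
                x, v, F, U = _baoab(ev, x, v, F, dt, friction, Tcur, rng,
                                    inv_m, reflect_radius=reflect)
            except IntegrationError as e:
                raise IntegrationError(f"{e} at frame {len(times)}") from e
            t += dt
            step_count += 1
            if step_count % sample_every == 0:
                times.append(t)
                frames.append(x.copy())
                pot.append(U)
                kin.append(kinetic_energy(v, spec.masses))
    traj = Trajectory(times=np.array(times), positions=np.array(frames),
                      potential=np.array(pot), kinetic=np.array(kin))
    final = SimState(time=t, positions=x, velocities=v, rng=rng)
    return traj, final
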