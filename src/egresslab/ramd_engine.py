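"""Random acceleration MD: randomly directed expulsion force with redirection.

A constant-magnitude force ``F = a · m_ligand`` (``a`` in kcal·Å⁻¹·g⁻¹, so
``F`` is in kcal·mol⁻¹·Å⁻¹) is applied to the ligand bead along a randomly
chosen unit direction.  Every ``N`` steps the ligand displacement since the
last check is compared to ``r_min``: if the ligand has moved less than
``r_min`` the direction is resampled uniformly on the sphere, otherwise it
is kept.  A run succeeds when the ligand leaves the receptor (center
distance ≥ ``exit_distance``) and fails when the time cutoff is reached,
in which case the trajectory is abandoned for statistics but still returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics_core import (ForceEvaluator, ForceField, IntegrationError,
                            SimState, Trajectory, _baoab, kinetic_energy)
from .synthetic_system import ToySystemSpec

__all__ = [
    "RAMDParams",
    "RAMDResult",
    "random_unit_direction",
    "run_ramd",
    "run_ramd_ensemble",
    "ensemble_summary",
]


@dataclass(frozen=True)
class RAMDParams:
    """Protocol parameters for one random-acceleration run.

    Defaults mirror common practice for buried-ligand egress sampling:
    accelerations of 0.15–0.2 kcal·Å⁻¹·g⁻¹, a 40-step displacement check,
    ``r_min`` of 0.005–0.02 Å and a 3 ns time cutoff.
    """

    acceleration: float = 0.2        # kcal·Å⁻¹·g⁻¹
    N: int = 40                      # steps between displacement checks
    r_min: float = 0.01              # Å
    dt: float = 0.01                 # ps
    time_cutoff: float = 3000.0      # ps
    exit_distance: float | None = None   # Å; default cage_radius + 5
    temperature: float = 300.0       # K
    friction: float = 1.0            # ps⁻¹
    sample_every: int = 20           # trajectory sampling stride (steps)

    def __post_init__(self):
        if self.acceleration < 0:
            raise ValueError("acceleration must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.r_min < 0:
            raise ValueError("r_min must be >= 0")
        if self.time_cutoff <= 0:
            raise ValueError("time_cutoff must be > 0")


@dataclass
class RAMDResult:
    """Outcome of one RAMD trajectory.

    ``exit_vector`` points from the cage center to the ligand position at
    the moment it first crossed the receptor shell (checked every step);
    the later ``exit_distance`` criterion only confirms that the ligand
    truly left rather than grazing the wall.  Classifying at the wall
    crossing matters because after clearing the shell the ligand flies
    ballistically along the current random-force direction, which scrambles
    the apparent exit direction within a few Å.
    """

    success: bool
    egress_time: float | None        # ps
    exit_vector: np.ndarray | None   # cage center → ligand at wall crossing
    channel_label: str | None        # set by trajectory classification
    n_redirections: int
    trajectory: Trajectory
    seed: int
    params: RAMDParams
    snapshot_index: int = 0


def random_unit_direction(rng: np.random.Generator) -> np.ndarray:
    """A direction uniform on the unit sphere; advances ``rng`` reproducibly."""
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:            # pragma: no cover - measure-zero event
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def run_ramd(spec: ToySystemSpec, ff: ForceField, start: SimState,
             params: RAMDParams, seed: int) -> RAMDResult:
    """Run one RAMD trajectory from an (equilibrated) starting state.

    The random force direction stream is driven by ``seed`` (independent of
    the thermostat noise in ``start.rng``, which is reseeded from the same
    value for full determinism).
    """
    rng = np.random.default_rng(seed)
    ev = ForceEvaluator(spec, ff)
    lig = spec.ligand_index
    m_lig = spec.ligand_mass
    fmag = params.acceleration * m_lig           # kcal·mol⁻¹·Å⁻¹
    exit_d = (params.exit_distance if params.exit_distance is not None
              else spec.cage_radius + 5.0)
    center = spec.well_center

    x = start.positions.copy()
    v = start.velocities.copy()
    inv_m = (1.0 / spec.masses)[:, None]
    reflect = 3.0 * spec.cage_radius
    direction = random_unit_direction(rng)

    def forces_with_bias(xx):
        F, U = ev(xx)
        F[lig] += fmag * direction
        return F, U

    n_steps = int(round(params.time_cutoff / params.dt))
    F, U = forces_with_bias(x)
    times = [0.0]
    frames = [x.copy()]
    pot = [U]
    kin = [kinetic_energy(v, spec.masses)]
    n_redirect = 0
    last_check_pos = x[lig].copy()
    success = False
    egress_time = None
    exit_vec = None
    wall_cross = None

    biased_ev = forces_with_bias

    t = 0.0
    for step in range(1, n_steps + 1):
        try:
            x, v, F, U = _baoab(biased_ev, x, v, F, params.dt,
                                params.friction, params.temperature, rng,
                                inv_m, reflect_radius=reflect)
        except IntegrationError as e:
            raise IntegrationError(
                f"{e} at t={t:.3f} ps (partial trajectory of "
                f"{len(times)} frames)") from e
        t = step * params.dt
        if step % params.sample_every == 0:
            times.append(t)
            frames.append(x.copy())
            pot.append(U)
            kin.append(kinetic_energy(v, spec.masses))
        r_lig = np.linalg.norm(x[lig] - center)
        if wall_cross is None and r_lig >= spec.cage_radius:
            wall_cross = x[lig] - center
        if r_lig >= exit_d:
            success = True
            egress_time = t
            exit_vec = wall_cross if wall_cross is not None else x[lig] - center
            if times[-1] < t:
                times.append(t)
                frames.append(x.copy())
                pot.append(U)
                kin.append(kinetic_energy(v, spec.masses))
            break
        if step % params.N == 0:
            moved = np.linalg.norm(x[lig] - last_check_pos)
            if moved < params.r_min:
                direction = random_unit_direction(rng)
                n_redirect += 1
            last_check_pos = x[lig].copy()

    traj = Trajectory(times=np.array(times), positions=np.array(frames),
                      potential=np.array(pot), kinetic=np.array(kin))
    label = None
    if success and spec.channels:
        label = classify_exit_channel_vector(exit_vec, spec.channels)
    res = RAMDResult(success=success, egress_time=egress_time,
                     exit_vector=exit_vec, channel_label=label,
                     n_redirections=n_redirect, trajectory=traj,
                     seed=seed, params=params)
    return res


def classify_exit_channel_vector(exit_vector, channels, max_angle: float = 30.0):
    """Label helper shared with :mod:`egresslab.trajectory_analysis`."""
    v = np.asarray(exit_vector, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        return "other"
    v = v / nv
    best = None
    best_ang = None
    for c in channels:
        ang = float(np.degrees(np.arccos(np.clip(v @ c.axis_array, -1.0, 1.0))))
        if best_ang is None or ang < best_ang - 1e-12:
            best, best_ang = c.label, ang
    return best if best_ang is not None and best_ang <= max_angle else "other"


def derive_seed(base_seed: int, *key: int) -> int:
    """Stable per-replica seed below 2³¹ derived from a base seed and keys."""
    ss = np.random.SeedSequence([int(base_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def run_ramd_ensemble(spec: ToySystemSpec, ff: ForceField,
                      snapshots: list[SimState],
                      params_grid: list[RAMDParams] | RAMDParams,
                      n_per_combo: int, base_seed: int) -> list[RAMDResult]:
    """Launch ``n_per_combo`` runs per (snapshot, parameter) combination.

    Seeds are derived deterministically and without overlap from
    ``base_seed`` and the (snapshot, params, replica) indices; failed runs
    are included in the returned list.
    """
    if not snapshots:
        raise ValueError("snapshots must be non-empty")
    if isinstance(params_grid, RAMDParams):
        params_grid = [params_grid]
    results: list[RAMDResult] = []
    for si, snap in enumerate(snapshots):
        for pi, params in enumerate(params_grid):
            for r in range(n_per_combo):
                seed = derive_seed(base_seed, si, pi, r)
                snap_r = snap.copy()
                snap_r.rng = np.random.default_rng(seed)
                res = run_ramd(spec, ff, snap_r, params, seed)
                res.snapshot_index = si
                results.append(res)
    return results


def ensemble_summary(results: list[RAMDResult]) -> pd.DataFrame:
    """Tabular ensemble summary (one row per trajectory)."""
    rows = []
    for r in results:
        rows.append({
            "snapshot": r.snapshot_index,
            "a": r.params.acceleration,
            "r_min": r.params.r_min,
            "N": r.params.N,
            "seed": r.seed,
            "success": r.success,
            "egress_time_ps": r.egress_time if r.egress_time is not None else "",
            "channel": r.channel_label if r.channel_label is not None else "",
            "n_redirections": r.n_redirections,
        })
    return pd.DataFrame(rows)
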