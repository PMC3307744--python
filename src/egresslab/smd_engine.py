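"""Constant-velocity steered MD: harmonic pulling along a fixed direction.

A virtual spring of constant ``k`` is attached to the ligand's projection
on the pulling direction and its reference end is dragged at constant
velocity ``v``; the instantaneous pulling force is

    F(t) = k · (v·t − x(t))

with ``x(t)`` the ligand displacement along the direction since the start.
The accumulated nonequilibrium work is ``W(t) = ∫ F v dt`` (trapezoidal
rule).  The pull is one-dimensional: transverse ligand motion is
unrestrained.  Designated anchor beads are held by stiff positional
restraints so the receptor does not drift with the pull.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics_core import (ForceEvaluator, ForceField, IntegrationError,
                            SimState, Trajectory, _baoab, kinetic_energy)
from .ramd_engine import derive_seed
from .synthetic_system import ToySystemSpec

__all__ = [
    "SMDParams",
    "WorkSeries",
    "compute_pull_force",
    "accumulate_work",
    "run_smd",
    "run_smd_ensemble",
]

#: positional-restraint force constant on anchor beads, kcal·mol⁻¹·Å⁻²
ANCHOR_RESTRAINT_K = 50.0


@dataclass(frozen=True)
class SMDParams:
    """Constant-velocity pulling parameters.

    ``v * duration`` must equal ``total_displacement`` (enforced to 1e-6);
    the defaults (k = 4 kcal·mol⁻¹·Å⁻², v = 0.01 Å/ps, 30 Å over 3 ns) are
    the package's standard pulling protocol.
    """

    k: float = 4.0                     # kcal·mol⁻¹·Å⁻²
    v: float = 0.01                    # Å/ps
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    total_displacement: float = 30.0   # Å
    duration: float = 3000.0           # ps
    restraint_k: float = ANCHOR_RESTRAINT_K
    dt: float = 0.01                   # ps
    temperature: float = 300.0         # K
    friction: float = 1.0              # ps⁻¹
    sample_interval: float = 0.1       # ps between force/work samples

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("spring constant k must be > 0")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("direction must be a nonzero vector")
            d = d / n
        object.__setattr__(self, "direction", tuple(float(x) for x in d))
        if abs(self.v * self.duration - self.total_displacement) > 1e-6:
            raise ValueError(
                f"v*duration = {self.v * self.duration} must equal "
                f"total_displacement = {self.total_displacement}"
            )

    @property
    def direction_array(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass
class WorkSeries:
    """Force and cumulative work along one pulling trajectory."""

    times: np.ndarray      # ps
    lam: np.ndarray        # reference coordinate v·t, Å
    x_proj: np.ndarray     # ligand displacement along direction, Å
    force: np.ndarray      # kcal·mol⁻¹·Å⁻¹
    work: np.ndarray       # cumulative, kcal/mol
    seed: int = 0

    def __post_init__(self):
        n = len(self.times)
        for a in (self.lam, self.x_proj, self.force, self.work):
            if len(a) != n:
                raise ValueError("all WorkSeries arrays must have equal length")
        if n and abs(self.work[0]) > 1e-12:
            raise ValueError("work must start at 0")
        if n > 1 and not np.all(np.diff(self.lam) > 0):
            raise ValueError("lambda must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ps": self.times, "lambda_A": self.lam,
            "x_proj_A": self.x_proj, "force": self.force,
            "work": self.work, "seed": self.seed,
        })


def compute_pull_force(t: float, x_proj: float, params: SMDParams) -> float:
    """Spring force ``k (v t − x)``; positive pulls the ligand forward."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return params.k * (params.v * t - x_proj)


def accumulate_work(force: np.ndarray, v: float, dt: float) -> np.ndarray:
    """Cumulative work ``W(t) = ∫ F v dt`` over uniform samples (trapezoid).

    ``dt`` is the uniform sample spacing; ``W[0] = 0``.
    """
    force = np.asarray(force, dtype=float)
    if force.ndim != 1 or len(force) < 1:
        raise ValueError("need at least one force sample")
    w = np.zeros(len(force))
    if len(force) > 1:
        w[1:] = np.cumsum(0.5 * (force[1:] + force[:-1]) * v * dt)
    return w


def run_smd(spec: ToySystemSpec, ff: ForceField, start: SimState,
            params: SMDParams, seed: int) -> tuple[WorkSeries, Trajectory]:
    """One constant-velocity pulling run.

    Langevin dynamics with the spring force applied to the ligand along
    ``params.direction`` and stiff positional restraints on the spec's
    designated anchor beads.  Force and work are sampled every
    ``params.sample_interval`` ps; the run stops when the reference has
    moved ``total_displacement`` (equivalently at ``duration``).
    """
    rng = np.random.default_rng(seed)
    u = params.direction_array
    lig = spec.ligand_index

    restraints = [(i, start.positions[i].copy(), params.restraint_k)
                  for i in spec.anchor_indices]
    ff_run = ForceField(eps=ff.eps, cutoff=ff.cutoff,
                        restraints=list(ff.restraints) + restraints)
    ev = ForceEvaluator(spec, ff_run)

    x = start.positions.copy()
    v_ = start.velocities.copy()
    inv_m = (1.0 / spec.masses)[:, None]
    reflect = 3.0 * spec.cage_radius
    x0_proj = float(x[lig] @ u)

    t = 0.0
    cur_force = [0.0]

    def biased(xx):
        F, U = ev(xx)
        xp = float(xx[lig] @ u) - x0_proj
        f = params.k * (params.v * t - xp)
        cur_force[0] = f
        F[lig] += f * u
        return F, U

    n_steps = int(round(params.duration / params.dt))
    stride = max(1, int(round(params.sample_interval / params.dt)))

    F, U = biased(x)
    times = [0.0]
    xps = [0.0]
    forces = [params.k * 0.0]
    traj_times = [0.0]
    frames = [x.copy()]
    pot = [U]
    kin = [kinetic_energy(v_, spec.masses)]

    for step in range(1, n_steps + 1):
        t = step * params.dt
        try:
            x, v_, F, U = _baoab(biased, x, v_, F, params.dt, params.friction,
                                 params.temperature, rng, inv_m,
                                 reflect_radius=reflect)
        except IntegrationError as e:
            raise IntegrationError(f"{e} at t={t:.3f} ps") from e
        if step % stride == 0:
            xp = float(x[lig] @ u) - x0_proj
            times.append(t)
            xps.append(xp)
            forces.append(compute_pull_force(t, xp, params))
            traj_times.append(t)
            frames.append(x.copy())
            pot.append(U)
            kin.append(kinetic_energy(v_, spec.masses))

    times = np.array(times)
    forces = np.array(forces)
    series = WorkSeries(
        times=times,
        lam=params.v * times,
        x_proj=np.array(xps),
        force=forces,
        work=accumulate_work(forces, params.v, float(times[1] - times[0]))
        if len(times) > 1 else np.zeros(1),
        seed=seed,
    )
    traj = Trajectory(times=np.array(traj_times), positions=np.array(frames),
                      potential=np.array(pot), kinetic=np.array(kin))
    return series, traj


def run_smd_ensemble(spec: ToySystemSpec, ff: ForceField, start: SimState,
                     params: SMDParams, n_replicas: int, base_seed: int
                     ) -> list[WorkSeries]:
    """Independent pulling replicas with derived seeds (work series only)."""
    out = []
    for r in range(n_replicas):
        seed = derive_seed(base_seed, 1000, r)
        st = start.copy()
        st.rng = np.random.default_rng(seed)
        series, _ = run_smd(spec, ff, st, params, seed)
        out.append(series)
    return out
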