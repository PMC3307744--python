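# Methods

## Scope and model

`egresslab` studies how a buried ligand leaves a receptor with more than
one gated exit channel.  The full problem — all-atom simulation of a
cytochrome P450 with explicit solvent — needs cluster hardware; this
package instead runs the complete analysis pipeline (tunnel detection →
random-acceleration egress sampling → steered pulling → Jarzynski PMF) on
coarse-grained systems that reproduce the *qualitative* physics: a deeply
buried binding site, channels of different bottleneck radius, aromatic
"revolving door" gates, and thermal motion at 300 K.

### Units

Å, ps, kcal/mol, g/mol, K throughout.  kB = 1.9872041e-3 kcal·mol⁻¹·K⁻¹;
1 kcal·mol⁻¹·Å⁻¹ acting on 1 g/mol accelerates it by 418.4 Å·ps⁻².  These
are the mixed AMBER-style units in which protocol parameters for this kind
of study are conventionally quoted (spring constants in kcal·mol⁻¹·Å⁻²,
random-force accelerations in kcal·Å⁻¹·g⁻¹).

### The cage model

A receptor is a quasi-uniform shell of purely repulsive beads (vdW radius
1.7 Å, mass 100 g/mol) on a sphere, placed by a Fibonacci lattice rotated
by a seeded random rotation — deterministic, and uniform enough that the
default 150 beads on a 12 Å sphere leave no surface gap a 1.4 Å water
probe could pass (checked at build time by a dense directional clearance
probe whenever a sealed cage is requested).  The ligand is a single bead
(2.0 Å, 118 g/mol — an indazole-sized stand-in) held at the center by an
attractive Gaussian well (default depth 4 kcal/mol, width 1.5 Å).

Channels are drilled as cylindrical openings.  Because the lattice is
discrete, the rim of a drilled hole would otherwise sit at an arbitrary
distance from the axis; a collar ring of beads is therefore laid at
perpendicular distance `geometric_radius + 1.7 Å`, which pins the
clearance bottleneck of the opening to `geometric_radius` up to grid
discretization.  Shell beads that would clash with the collar (or with
gate hardware) are *slid* along the sphere, not deleted: deletion was
found to open a weak annulus just outside the rim through which a strongly
forced ligand escapes, which would corrupt every per-channel statistic.

A gated channel carries a four-bead side-chain: three hinge beads tethered
at the rim and a terminal bead that covers the mouth center in the closed
state.  Two bonds (terminal–hinge3 and terminal–hinge2) leave rotation
about the hinge axis as the only soft mode, and a one-minimum cosine
dihedral with full barrier `barrier_height` (default 2 kcal/mol) holds the
door shut.  This is an abstraction of an aromatic gate residue; fidelity
to any particular all-atom rotation mechanism is not claimed.

### Force field and wall stiffness

Pair repulsion is `U = ε (σij/r)¹²` truncated and shifted at 10 Å, with
σij the sum of the bead radii; bonds and positional tethers are harmonic
(`U = ½ k Δ²`, so the thermal variance per coordinate is kBT/k);
dihedrals are `k(1 + cos(nφ − phase))`.  There are no electrostatics, no
solvent and no periodic box; a reflecting sphere of radius 3× the cage
radius keeps escaped ligands finite.

ε and the receptor tether stiffness are not free decorations: the
strongest standard random-force magnitude (a = 0.2 kcal·Å⁻¹·g⁻¹ on a
118 g/mol ligand) presses on the wall with ~23.6 kcal·mol⁻¹·Å⁻¹.  With a
soft wall the ligand shoves shell beads aside and leaves through intact
wall, which makes "closed" cages leak and channel statistics meaningless.
The defaults ε = 5 kcal/mol and tether k = 30 kcal·mol⁻¹·Å⁻² were chosen
so a sealed cage statically withstands that force with margin while the
shell still breathes thermally (~0.15 Å rms per bead).

### Integration

BAOAB Langevin; with friction 0 the scheme reduces exactly to velocity
Verlet, which the energy-conservation tests exploit.  Default dt is 2 fs
to match common practice, but the toy force field is smooth enough that
production-style runs in the tests use 10 fs; the statistics cages stay
comfortably below the stability limit at that step (verified over a
24-seed scan).  Friction defaults to 1 ps⁻¹.  Equilibration follows a
linear 0→300 K heat followed by a hold, and equipartition, Boltzmann
position statistics and NVE drift are asserted by the test suite.

## RAMD

A constant-magnitude force `F = a·m_ligand` is applied to the ligand along
a random direction, redrawn (uniformly, memory-free) whenever the ligand
moved less than `r_min` during the last `N·dt` window (N = 40).  A run
succeeds when the ligand's distance from the cage center reaches
`exit_distance` (default cage radius + 5 Å) and fails at the time cutoff
(default 3 ns).

Two protocol details are committed choices of this package:

* **Stuck threshold.**  The conventional r_min grid (0.005–0.02 Å) is
  tuned to all-atom simulations where a caged ligand barely moves between
  checks.  On the smooth coarse wall a pressed ligand still jitters
  0.1–0.3 Å per 0.4 ps window, so those thresholds essentially never fire
  and trajectories stall pressed against the wall.  Tests and the
  acceptance script therefore run the toy protocol at r_min = 0.5 Å —
  just above the pressed-state jitter — which makes "no progress"
  detectable at toy scale.  The parameter remains fully configurable and
  the grid values remain the documented defaults of `RAMDParams`.

* **Exit classification point.**  A successful ligand leaves the shell at
  up to ~80 Å/ps and then flies ballistically along whatever direction the
  random force last had, so its position at the termination radius no
  longer reflects which channel it used.  `exit_vector` is therefore
  recorded at the per-step crossing of the receptor shell radius, and
  channel labels are assigned from that vector (smallest axis angle,
  threshold 30°, ties to the first listed channel).  Termination still
  requires the full exit distance, so grazing contacts do not count as
  egress.

Ensembles derive one seed per (snapshot, parameter set, replica) from a
base seed via `numpy` seed sequences, so any individual trajectory can be
reproduced in isolation.

## SMD and work

Constant-velocity pulling applies the scalar spring force
`F(t) = k (v·t − x(t))` along a fixed unit direction to the ligand, where
x is the ligand displacement projected on that direction since the start
(transverse motion is unrestrained).  Defaults: k = 4 kcal·mol⁻¹·Å⁻²,
v = 0.01 Å/ps, 30 Å over 3 ns.  Three designated anchor beads on the far
side of the cage are held by k = 50 kcal·mol⁻¹·Å⁻² positional restraints
so the receptor does not drift with the pull.  Force and work are sampled
every 0.1 ps (≥ 250 samples per 0.5 Å PMF window); work is the
trapezoidal integral of F·v dt, and a self-consistency test re-integrates
the stored force samples.

## PMF estimation

Work curves are interpolated onto a λ grid with 0.5 Å windows anchored at
λ = 0.  The direct estimator is Jarzynski's equality evaluated with a
log-sum-exp shift.  Because the exponential average is biased low at
finite sample size, a cumulative-integral style extrapolation is provided:
direct estimates F̂(n) on the first n trajectories of a random permutation
are averaged over 20 permutations and fitted with F̂(n) = F∞ + c/n
(least squares, n ≥ 5); F∞ is reported and labelled `ci` in outputs.
This 1/n surrogate is this package's committed, testable form of the idea;
it is validated against the Gaussian-work closed form
ΔF = μ − σ²/(2kBT), where its mean absolute error is required to be no
worse than the direct estimator's.  Uncertainties come from bootstrap
resampling of whole trajectories (default 200 resamples); profiles are
reported relative to the first bin, where ΔF ≡ 0.

Convergence is reported, not enforced: a profile is considered converged
when adding the last 10% of trajectories changes ΔF by < 0.1 kcal/mol.

## Tunnel detection

Space around an atom set (parsed from PDB text via biotite, radii from a
bundled Bondi table, waters and B+ altLocs excluded) is voxelized at
0.4 Å; each voxel stores the exact distance from its center to the nearest
atom surface.  Tunnels are lowest-cost paths from a buried start voxel to
the box boundary over 26-connected voxels, with edge cost
`step length × ½(w(u)+w(v))`, `w = 1/max(clearance, 0.05)²`.  The inverse
-square weight strongly favors wide passages — qualitatively the same
preference as Voronoi-based channel finders, without their machinery.  Up
to k tunnels are returned whose surface exits are mutually > 5 Å apart
(greedy by ascending cost); each carries its clearance profile and
bottleneck radius, to be read against the 1.4 Å water criterion.  The
Dijkstra search is verified against exhaustive Bellman-Ford relaxation on
small grids.  Channel *naming* (2a, 2c, …) requires structural context and
is left to the user; tunnels are identified by exit coordinates.

## What the synthetic generator does and does not emulate

Emulated: a buried site sealed from solvent; multiple channels with
controlled bottleneck radii; a rotatable gate that occludes a mouth;
thermal breathing of the wall; Langevin dynamics at 300 K.  Not emulated:
amino-acid chemistry, hydrogen bonds and π-stacking, explicit solvent,
electrostatics, secondary-structure mechanics, and the absolute energy
scale of a real unbinding PMF (tens of kcal/mol).  Consequently, passing
tests demonstrate that the *pipeline* — sampling protocol, estimators,
statistics, geometry — behaves correctly on systems whose ground truth is
known, not that any particular protein shows a particular channel ratio
or barrier.

## Numerical choices and degenerate inputs

* Coincident beads raise a singular-geometry error rather than returning
  infinities; non-finite forces abort a run naming the offending bead and
  frame.
* Dihedral angles use the IUPAC sign convention; analytic gradients are
  validated against central finite differences at 1e-5 Å to a relative
  1e-4.
* Collinear dihedral frames in analysis are recorded as missing (NaN)
  rather than fabricated; a "revolving door" event is ≥ 300° of unwrapped
  rotation within any 500-frame window, operationalizing "nearly 360°".
* The clearance floor (0.05 Å) in the tunnel cost keeps weights finite in
  grazing voxels; bottlenecks are reported from the true clearance
  profile, not the floored weights.
* `ci_extrapolate` falls back to the direct estimate (with a warning)
  below 5 trajectories; bootstrap requires ≥ 2 trajectories and ≥ 2
  resamples.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen once: cages of
45–160 beads, RAMD ensembles of 20–50 replicas with 50–150 ps cutoffs
(successful toy egress takes 10–40 ps), pulling at 0.1 Å/ps over ~12 Å
for ensemble properties and 0.004 Å/ps over 4 Å for the quasi-static
oracle comparison, and 0.4 Å tunnel grids (~10⁶ voxels).  The analytic
SMD/Jarzynski checks use the standard protocol values themselves
(k = 4, v = 0.01, 3 ns, 30 Å) since they need no dynamics.

## Known limitations

* One ligand bead: no orientational degrees of freedom, so no π-stacking
  or pose-dependent bottleneck effects.
* The gate's barrier is a single cosine; real aromatic gates couple to
  backbone motion.
* Channel classification assumes channels are straight cones from the
  center; strongly curved exit paths would need path-based assignment.
* The CI surrogate extrapolates in 1/n only; it does not implement block
  averaging of the original cumulative-integral formulation.
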