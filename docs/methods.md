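# Methods

This note records the models implemented in `ensemref`, the choices made
where the design was genuinely open, and what the desk-scale test system
does and does not establish.

## Replica-averaged restraints

Both restraint terms act on ensemble averages over M simultaneously
integrated replicas — the practical maximum-entropy construction: the
prior (the force field) is perturbed minimally, because only the mean
observable is biased while individual copies fluctuate freely.  With
M = 1 both terms reduce exactly to conventional single-structure
restraints, which the tests assert.

**Chemical shifts.**  E = k·(T_ref/T)·Σ_i Δ_i² with
Δ_i = (1/M)Σ_m δ_m,i − δ_exp,i, k = 5.2 kJ mol⁻¹ ppm⁻², T_ref = 304 K.
The penalty is a *sum of squared deviations of the mean* (not a mean of
squares), and it is left unnormalized over the number of shifts; a
`normalize` switch divides by N for users who prefer an intensive
penalty.  Temperature scaling applies to this term only.

**NOEs.**  Within each replica, equivalent protons are pooled with a
*normalized* r⁻⁶ mean — (mean over cross pairs of r⁻⁶)^(−1/6) — so the
effective distance stays commensurate with the experimental bounds
regardless of group multiplicity (a sum would shrink it by the group
size).  Replicas are then pooled the same way.  The flat-bottom form is:
zero inside [lower, upper]; ½k·Δ² outside on both sides; beyond
upper + r_linear (default 0.2 nm) the upper branch continues linearly
with continuous slope, so a badly violated restraint exerts a bounded,
constant force instead of a diverging one.  Phase constants are
1000 / 20 / 125 kJ mol⁻¹ nm⁻² for the 304 K plateau / heating / cooling;
the 454 K plateau is grouped with heating (the weakest restraint at the
highest temperature — the assignment of the high-temperature plateau is
the one point the protocol description leaves open, and it is
configurable).  Distances of exactly zero raise errors rather than being
clamped.

Forces are exact analytic gradients chain-ruled through the predictor and
through the r⁻⁶ pooling; the suite verifies them against central
differences to a relative error below 10⁻⁵.

## Synthetic shift predictor

Real structure-based predictors (CamShift-class) are regression models
over atomic geometry; reimplementing one is out of scope and unnecessary
for testing the restraint machinery.  The built-in predictor is a
deliberately simple geometric surrogate with the properties that matter:

δ_i = ref(nucleus) + w(nucleus) · Σ_j s(|x_i − x_j|),
s(r) = (1 − (r/r_c)²)² / √(r² + a²) for r < r_c, else 0,

a C¹ switched, soft-cored inverse distance (cutoff r_c = 1.0 nm, soft
core a = 0.25 nm).  It is smooth everywhere (continuous restraint
forces), translation/rotation invariant, structure-sensitive (it counts
and weighs the neighbour shell), and its gradient is bounded at contact
so restraint forces cannot diverge on clashing conformations.  Default
couplings are 1.0 (CA) and 2.0 (N) ppm·nm — chosen so that
conformation-dependent shift variation is a few ppm, the scale real
backbone shifts vary by.  Any external predictor can be plugged in behind
the same `(coords, residue_indices, keys, params) → values/gradients`
contract.

Per-nucleus predictor uncertainties default to literature-typical RMS
accuracies of protein shift predictors (CA 1.3, CB 1.2, C′ 1.3, N 2.7,
H 0.5, HA 0.3, methyl-¹³C 1.0, methyl-¹H 0.3 ppm).  They are
configuration values used in the reduced-χ² metric, not physical
constants.

## Toy system and integrator

The sampler is a bead chain in GROMACS-style units (nm, ps, amu,
kJ/mol): harmonic bonds (k = 1000 kJ mol⁻¹ nm⁻², r₀ = 0.38 nm — the
Cα–Cα virtual bond), cosine-harmonic angles
(E = ½k(cosθ − cosθ₀)², k = 2 kJ/mol, θ₀ = 2 rad; the cosine form is
regular at collinear geometries, where the plain harmonic angle force
diverges), and WCA (purely repulsive Lennard-Jones) excluded volume with
σ = 0.33 nm, ε = 2.5 kJ/mol on all pairs except directly bonded ones.
Two numerical guards keep restrained dynamics stable at a 10 fs timestep:
the WCA core is linearized where the pair force would exceed
3000 kJ mol⁻¹ nm⁻¹ (still a conservative potential), and freshly built
self-avoiding-walk chains are relaxed by capped steepest descent before
dynamics.

Integration is BAOAB Langevin (friction 2 ps⁻¹) — a deliberate
replacement for the solvent-scale machinery of production protein MD
(leap-frog, bond constraints, Ewald electrostatics, explicit water),
which is irrelevant to what is under test here: the restraint and
annealing *protocol*.  The protocol schedule is always book-kept in its
own units (the four phases of 100/100/100/300 ps between 304 and 454 K,
i.e. a 0.6 ns cycle); a `time_scale` factor (default 0.01) maps protocol
time onto integrated toy time so one cycle costs 600 steps.  Velocities
carry over between cycles (continuous dynamics); a switch re-randomizes
them per cycle for users who prefer independent cycles.  Frames are
harvested only during phases whose temperature is pinned at 304 K and
only after the burn-in; the burn-in default is 45 cycles, matching the
production protocol the schedule comes from.

## Desk-scale study conditions

The test suite and the worked example run with 8–12 beads, 20–50 frame
reference ensembles, 2–4 replicas and ~30 SA cycles with a ~10–15 cycle
burn-in — sizes chosen so a full refinement takes tens of seconds while
every qualitative feature of the protocol (restraint-driven convergence,
harvest bookkeeping, replica-spread behaviour) is exercised.  Fixture
NOE intervals are centred on the reference ensemble's pooled r⁻⁶
distances with a ±1 Å half-width, the typical width of NOE bound
classes; short-range intervals connect residues 2–4 apart and long-range
partners (separation > 4) are added at roughly one per nine short
intervals, mirroring the composition of a real sparse restraint list
(46 long-range in 455).

What the synthetic generator does *not* emulate: chemical heterogeneity
(all beads are identical), secondary structure, solvent effects, the
nonlinear physics of real shift surfaces, experimental noise structure
(noise is i.i.d. Gaussian), and asymmetric NOE bounds.  Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery — restraint gradients, averaging conventions, protocol
bookkeeping, estimator behaviour — not the accuracy of any force field
or predictor on real proteins.

## Convergence metrics

Clustering for the Jensen–Shannon comparison runs *once* on the pooled
frames of both ensembles (similarity = −RMSD in nm), so the two occupancy
vectors share support.  Affinity propagation is implemented as the
standard responsibility/availability message passing (damping 0.9,
convergence after 50 stable iterations), with the exemplar-refinement
finalization step; the suite checks exact label agreement with an
independent reference implementation on random problems.  Exactly
coincident frames are merged before message passing: fully degenerate
ties can otherwise split identical frames into separate singleton
exemplars, which would make even a self-comparison nonzero.  JS
divergence is reported in nats (maximum ln 2 ≈ 0.693; the 0.1–0.3
"similar" range is calibrated on this scale), with the log base
configurable.

The preference controls cluster granularity and, through it, the JSD's
resolution: the median off-diagonal similarity (the classic default) is a
reasonable choice at a few hundred frames, but over-fragments larger
pools; the CLI accepts either an explicit value (on the −RMSD scale, in
nm) or `median`.  A positive preference of 12, the value quoted with the
ENCORE-style analysis this mirrors, exceeds every −RMSD similarity and is
kept available as a configuration value; its original internal scaling is
not recoverable, so it is treated as an opaque tunable.

RMSIP uses the top 10 eigenvectors of the Cα-coordinate covariance; the
ensemble is superposed first by iterative least-squares alignment to the
evolving mean (Kabsch per frame, converged when the mean moves < 10⁻⁹ nm
RMS).  The alignment reference starts from the raw ensemble mean so that
an already-aligned ensemble is an exact fixed point (idempotence); when
frames carry arbitrary rigid motions the raw mean degenerates and frame 0
seeds the iteration instead.  This least-squares superposition stands in
for maximum-likelihood superposition; the alignment choice affects the
absolute S² and PCA values and is acknowledged as an approximation.

## Order parameters

ACFs use C(t) = ⟨P₂(ê(s)·ê(s+t))⟩ over all time origins (denominator
N − t), on unaligned trajectories so overall tumbling contributes; lag
grids are logarithmically thinned beyond 100 points before fitting.  The
global Lipari–Szabo fit shares one τ_c across bonds with per-bond
(S², τ_e), solved by bounded nonlinear least squares (S² ∈ [0, 1], τ in
log-parameterization) from a fixed, data-derived initialization (τ_c
from the 1/e crossing of the bond-mean ACF, S² from the
tumbling-corrected quarter-lag value, τ_e = τ_c/20), making the fit
deterministic.  No extended model variants are fitted — model selection
among them is a known difficulty and out of scope.  Non-decaying inputs
are flagged, not rejected.  Ensemble S² uses the second-moment tensor
formula on superposed frames and requires ≥ 2 frames.

## Validation conventions

Reduced χ² normalizes squared deviations by the per-type predictor
variance and the number of shifts; ensemble shifts are unweighted frame
means, matching the linear averaging in the restraint.  NOE violations
are reported in Å (bounds data are conventionally printed in Å even
though the internal unit is nm); the census bins 0.5–1 / 1–2 / > 2 Å are
left-closed, and violations below 0.5 Å count toward the total but are
not binned.  By default violations are evaluated on the ensemble-pooled
r⁻⁶ average — the observable the restraint actually controls — with a
per-frame worst-case mode as the alternative.  The side-chain contact
definition (minimum side-chain atom distance < 0.45 nm in ≥ 50 % of
frames, |i − j| > 2) is a documented default; published contact counts
rarely state their criterion, so these numbers are comparable only
within one definition.

## Known limitations

- The toy chain has no attractive nonbonded term, so unrestrained
  ensembles are self-avoiding coils; compactness information enters only
  through the restraints.
- r⁻⁶ pooling over a fluctuating ensemble is dominated by close
  approaches; restraining the instantaneous M-replica average therefore
  biases the *time-pooled* effective distance slightly below it.  With
  realistic (±1 Å) interval widths this bias is absorbed by the flat
  bottom.
- NMR-STAR support covers exactly the assigned-chemical-shift and
  distance-restraint loops, with backbone + Cβ nucleus mapping; methyl
  shift data enter through the TSV dialect.  One shift per
  (residue, nucleus) is enforced, so degenerate methyl pairs need
  distinct rows per group in TSV form.
- Pseudoatom handling expands a small built-in name map; no bound
  corrections are applied.
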