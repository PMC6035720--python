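"""Coarse-grained bead-chain sampler with the replica simulated-annealing
refinement protocol.

The chain is a minimal stand-in for a solvated all-atom system: harmonic
bonds, soft harmonic angles and a purely repulsive (WCA-style)
Lennard-Jones excluded volume, integrated with BAOAB Langevin dynamics.
What is under test is the *protocol*: M replicas co-evolve, restraint
forces act on the instantaneous replica average at every step, each
simulated-annealing cycle runs the four-phase temperature program
(100 ps at 304 K, linear heating to 454 K over 100 ps, 100 ps at 454 K,
linear cooling back over 300 ps — 0.6 ns per cycle in protocol units) and
only frames from the 304 K plateau of post-burn-in cycles are harvested.

Protocol durations are always book-kept in the protocol units above; a
``time_scale`` factor maps them onto the toy chain's intrinsic timescale so
a 0.6 ns-equivalent cycle integrates in a fraction of a second.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nmr_io import Ensemble

__all__ = [
    "KB",
    "ToySystem",
    "SAPhase",
    "SASchedule",
    "default_schedule",
    "temperature_at",
    "LangevinState",
    "langevin_step",
    "build_toy_chain",
    "sample_unrestrained",
    "RefinementConfig",
    "RefinementRun",
    "run_replica_sa",
]

#: Boltzmann constant, kJ mol^-1 K^-1 (GROMACS-style unit system:
#: nm, ps, amu, kJ/mol).
KB = 0.0083144621


# ---------------------------------------------------------------------------
# Toy force field
# ---------------------------------------------------------------------------

@dataclass
class ToySystem:
    """Bead chain: harmonic bonds and angles plus WCA repulsion.

    Units: nm, amu, kJ/mol.  ``forces`` is batched — it accepts coordinates
    of shape (N, 3) or (M, N, 3).
    """

    positions: np.ndarray  # (N, 3) nm, initial conformation
    masses: np.ndarray  # (N,) amu
    atom_names: list
    residue_indices: np.ndarray
    residue_names: list
    bond_k: float = 1000.0  # kJ mol^-1 nm^-2
    bond_r0: float = 0.38  # nm (Calpha-Calpha virtual bond)
    angle_k: float = 2.0  # kJ/mol (cosine-harmonic)
    angle_theta0: float = 2.0  # rad
    epsilon: float = 2.5  # kJ/mol
    sigma_lj: float = 0.33  # nm
    f_cap: float = 3000.0  # kJ mol^-1 nm^-1; repulsion linearized below this

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.positions.shape[0]
        if n < 3:
            raise ValueError("a chain needs at least 3 beads")
        for name in ("bond_k", "bond_r0", "angle_k", "angle_theta0",
                     "epsilon", "sigma_lj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # nonbonded exclusions: directly bonded pairs only (the soft angle
        # term alone cannot keep 1-3 pairs from collapsing)
        iu, ju = np.triu_indices(n, k=2)
        self._nb_i, self._nb_j = iu, ju
        self._rc_wca = self.sigma_lj * 2.0 ** (1.0 / 6.0)
        # radius below which the WCA pair force reaches f_cap; the core is
        # linearized there so clashes cannot inject unbounded energy
        self._r_cap = self._solve_cap_radius()

    def _wca_force_mag(self, r):
        inv2 = (self.sigma_lj / r) ** 2
        inv6 = inv2 ** 3
        return 24.0 * self.epsilon * (2.0 * inv6 * inv6 - inv6) / r

    def _solve_cap_radius(self) -> float:
        lo, hi = 1e-3, self._rc_wca
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if self._wca_force_mag(mid) > self.f_cap:
                lo = mid
            else:
                hi = mid
        return hi

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.n_beads - 1

    @property
    def n_angles(self) -> int:
        return self.n_beads - 2

    def forces(self, coords: np.ndarray) -> np.ndarray:
        """Force field forces (same shape as ``coords``)."""
        X = np.asarray(coords, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        F = np.zeros_like(X)

        # bonds
        d = X[:, 1:] - X[:, :-1]  # (M, N-1, 3)
        r = np.linalg.norm(d, axis=-1)
        f = (self.bond_k * (r - self.bond_r0) / r)[..., None] * d
        F[:, :-1] += f
        F[:, 1:] -= f

        # angles: cosine-harmonic E = 1/2 k (cos theta - cos theta0)^2 on
        # each consecutive triple -- regular at collinear geometries
        if self.n_beads >= 3 and self.angle_k > 0:
            u = X[:, :-2] - X[:, 1:-1]  # j->i
            v = X[:, 2:] - X[:, 1:-1]  # j->k
            nu = np.linalg.norm(u, axis=-1)
            nv = np.linalg.norm(v, axis=-1)
            c = np.einsum("mak,mak->ma", u, v) / (nu * nv)
            dEdc = self.angle_k * (c - math.cos(self.angle_theta0))
            # dc/dx_i = (v_hat - c u_hat)/|u| ; symmetric for x_k
            dci = (v / nv[..., None] - c[..., None] * u / nu[..., None]) \
                / nu[..., None]
            dck = (u / nu[..., None] - c[..., None] * v / nv[..., None]) \
                / nv[..., None]
            F[:, :-2] -= dEdc[..., None] * dci
            F[:, 2:] -= dEdc[..., None] * dck
            F[:, 1:-1] += dEdc[..., None] * (dci + dck)

        # WCA repulsion on non-excluded pairs, force-capped in the core
        d = X[:, self._nb_i] - X[:, self._nb_j]
        r2 = np.einsum("mpk,mpk->mp", d, d)
        within = r2 < self._rc_wca ** 2
        if np.any(within):
            r2s = np.where(within, np.maximum(r2, self._r_cap ** 2), 1.0)
            inv2 = np.where(within, self.sigma_lj ** 2 / r2s, 0.0)
            inv6 = inv2 ** 3
            # dE/dr * 1/r = -24 eps (2 inv12 - inv6) / r^2; inside r_cap the
            # magnitude stays at f_cap (linearized potential)
            r = np.sqrt(np.where(r2 > 0, r2, 1.0))
            mag = np.where(within,
                           24.0 * self.epsilon * (2.0 * inv6 * inv6 - inv6)
                           / np.sqrt(r2s), 0.0)
            fpair = (mag / r)[..., None] * d
            np.add.at(F, (slice(None), self._nb_i), fpair)
            np.add.at(F, (slice(None), self._nb_j), -fpair)

        if not np.all(np.isfinite(F)):
            raise FloatingPointError("non-finite force encountered")
        return F[0] if single else F

    def potential_energy(self, coords: np.ndarray) -> float:
        X = np.asarray(coords, dtype=float)
        d = np.linalg.norm(X[1:] - X[:-1], axis=-1)
        e = 0.5 * self.bond_k * np.sum((d - self.bond_r0) ** 2)
        u = X[:-2] - X[1:-1]
        v = X[2:] - X[1:-1]
        c = np.einsum("ak,ak->a", u, v) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
        e += 0.5 * self.angle_k * np.sum((c - math.cos(self.angle_theta0)) ** 2)
        dd = X[self._nb_i] - X[self._nb_j]
        r2 = np.einsum("pk,pk->p", dd, dd)
        within = r2 < self._rc_wca ** 2
        r = np.sqrt(r2)
        rs = np.where(within, np.maximum(r, self._r_cap), 1.0)
        inv6 = np.where(within, (self.sigma_lj / rs) ** 6, 0.0)
        e += np.sum(np.where(
            within,
            4 * self.epsilon * (inv6 ** 2 - inv6) + self.epsilon
            + self.f_cap * np.maximum(0.0, self._r_cap - r),
            0.0))
        return float(e)


def minimize_positions(system: ToySystem, coords=None, n_steps: int = 500,
                       max_disp: float = 0.005, f_tol: float = 50.0) -> np.ndarray:
    """Capped steepest-descent relaxation (removes steric near-clashes so
    dynamics can start from finite forces).  ``max_disp`` caps the per-bead
    displacement per iteration (nm); stops early when the largest force
    drops below ``f_tol`` kJ mol^-1 nm^-1."""
    X = np.array(system.positions if coords is None else coords, dtype=float)
    for _ in range(n_steps):
        F = system.forces(X)
        fmax = np.abs(F).max()
        if fmax < f_tol:
            break
        X = X + F * min(max_disp / fmax, 1e-4)
    return X


def build_toy_chain(n_beads: int, seed: int = 0, bead_mass: float = 12.0,
                    **system_kwargs) -> ToySystem:
    """Self-avoiding random-walk chain; deterministic for a given seed.

    The builder rejects growth steps that bring any bead pair closer than
    0.8 sigma, then relaxes the raw walk by capped steepest descent so the
    initial conformation carries no extreme steric forces.
    """
    if n_beads < 3:
        raise ValueError("n_beads must be >= 3")
    rng = np.random.default_rng(seed)
    sigma = system_kwargs.get("sigma_lj", 0.33)
    r0 = system_kwargs.get("bond_r0", 0.38)
    min_sep = 0.8 * sigma
    pos = [np.zeros(3)]
    while len(pos) < n_beads:
        for _attempt in range(1000):
            step = rng.standard_normal(3)
            step *= r0 / np.linalg.norm(step)
            cand = pos[-1] + step
            if all(np.linalg.norm(cand - p) > min_sep for p in pos[:-1]):
                pos.append(cand)
                break
        else:
            raise RuntimeError("self-avoiding walk failed to grow")
    positions = np.array(pos)
    system = ToySystem(
        positions=positions,
        masses=np.full(n_beads, bead_mass),
        atom_names=["CA"] * n_beads,
        residue_indices=np.arange(1, n_beads + 1),
        residue_names=["BEA"] * n_beads,
        **system_kwargs,
    )
    system.positions = minimize_positions(system)
    return system


# ---------------------------------------------------------------------------
# Simulated-annealing schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAPhase:
    label: str
    duration: float  # ps, protocol units
    T_start: float  # K
    T_end: float  # K


@dataclass
class SASchedule:
    """Ordered annealing phases; temperatures interpolate linearly within a
    phase and must be continuous across phase boundaries."""

    phases: list

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        for p in self.phases:
            if p.duration <= 0:
                raise ValueError(f"phase {p.label}: duration must be positive")
        for a, b in zip(self.phases, self.phases[1:]):
            if not math.isclose(a.T_end, b.T_start):
                raise ValueError(
                    f"temperature discontinuity between {a.label} and {b.label}")

    @property
    def total_duration(self) -> float:
        """Cycle length in protocol ps."""
        return sum(p.duration for p in self.phases)

    def temperature_at(self, t: float) -> float:
        """Temperature (K) at protocol time t within the cycle."""
        if not (0 <= t < self.total_duration):
            raise ValueError(
                f"t = {t} outside [0, {self.total_duration}) ps")
        start = 0.0
        for p in self.phases:
            if t < start + p.duration:
                frac = (t - start) / p.duration
                return p.T_start + frac * (p.T_end - p.T_start)
            start += p.duration
        raise AssertionError("unreachable")

    def phase_at(self, t: float) -> SAPhase:
        if not (0 <= t < self.total_duration):
            raise ValueError(f"t = {t} outside the cycle")
        start = 0.0
        for p in self.phases:
            if t < start + p.duration:
                return p
            start += p.duration
        raise AssertionError("unreachable")


def default_schedule() -> SASchedule:
    """The four-phase 0.6 ns annealing cycle between 304 and 454 K."""
    return SASchedule([
        SAPhase("low_T", 100.0, 304.0, 304.0),
        SAPhase("heat", 100.0, 304.0, 454.0),
        SAPhase("high_T", 100.0, 454.0, 454.0),
        SAPhase("cool", 300.0, 454.0, 304.0),
    ])


def temperature_at(schedule: SASchedule, t: float) -> float:
    """Module-level convenience wrapper for ``schedule.temperature_at``."""
    return schedule.temperature_at(t)


# ---------------------------------------------------------------------------
# Langevin (BAOAB) integration
# ---------------------------------------------------------------------------

@dataclass
class LangevinState:
    """Positions/velocities of the replica stack, shape (M, N, 3)."""

    positions: np.ndarray
    velocities: np.ndarray


def langevin_step(state: LangevinState, system: ToySystem,
                  restraint_forces, dt: float, T: float, friction: float,
                  rng, forces=None):
    """One BAOAB Langevin step.

    ``restraint_forces`` (same shape as positions, or None) are held fixed
    across the step and recomputed by the caller; the force-field forces are
    re-evaluated after the position update and returned for reuse.  With
    T = 0 and zero total force the velocities decay by exp(-friction dt)
    per step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < 0:
        raise ValueError("temperature must be non-negative")
    x, v = state.positions, state.velocities
    m = system.masses[None, :, None]
    if forces is None:
        forces = system.forces(x)
        if restraint_forces is not None:
            forces = forces + restraint_forces
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force")

    v = v + 0.5 * dt * forces / m
    x = x + 0.5 * dt * v
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * KB * T)
    v = c1 * v + c2 / np.sqrt(m) * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    new_forces = system.forces(x)
    if restraint_forces is not None:
        new_forces = new_forces + restraint_forces
    v = v + 0.5 * dt * new_forces / m
    return LangevinState(x, v), new_forces


def _thermal_velocities(system, M, T, rng):
    scale = np.sqrt(KB * T / system.masses)[None, :, None]
    return scale * rng.standard_normal((M, system.n_beads, 3))


def sample_unrestrained(system: ToySystem, n_frames: int, T: float = 304.0,
                        seed: int = 0, dt: float = 0.01, friction: float = 2.0,
                        burn_in_steps: int = 500, spacing_steps: int = 50) -> Ensemble:
    """Plain Langevin sampling of the toy chain at constant temperature."""
    rng = np.random.default_rng(seed)
    state = LangevinState(system.positions[None].copy(),
                          _thermal_velocities(system, 1, T, rng))
    frames = []
    forces = None
    total = burn_in_steps + n_frames * spacing_steps
    for step in range(total):
        state, forces = langevin_step(state, system, None, dt, T, friction,
                                      rng, forces=forces)
        if step >= burn_in_steps and (step - burn_in_steps) % spacing_steps == 0:
            frames.append(state.positions[0].copy())
            if len(frames) == n_frames:
                break
    return Ensemble(np.array(frames[:n_frames]), system.atom_names,
                    system.residue_indices, system.residue_names,
                    system.masses, provenance=f"unrestrained T={T} seed={seed}")


# ---------------------------------------------------------------------------
# Replica simulated-annealing refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementConfig:
    """Integration and harvesting settings for the SA protocol.

    ``time_scale`` maps protocol ps onto integrated toy ps (default 0.01:
    a 600 ps protocol cycle integrates 6 ps).  ``discard_cycles`` default
    follows the production protocol (45); desk-scale runs override it.
    """

    dt: float = 0.01  # ps (toy timescale)
    friction: float = 2.0  # ps^-1
    time_scale: float = 0.01
    harvest_per_cycle: int = 4  # frames per replica per kept cycle
    discard_cycles: int = 45
    rerandomize_velocities: bool = False  # draw fresh velocities each cycle


@dataclass
class RefinementRun:
    """Result of a replica SA refinement: harvested 304 K frames per
    replica, the pooled ensemble, per-cycle diagnostics and metadata."""

    replica_ensembles: list
    ensemble: Ensemble
    diagnostics: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def run_replica_sa(system: ToySystem, restraint_fn, schedule: SASchedule,
                   M: int, n_cycles: int, seed: int = 0,
                   config: RefinementConfig | None = None,
                   discard_cycles: int | None = None,
                   start_positions=None) -> RefinementRun:
    """Run the replica-averaged simulated-annealing refinement.

    ``restraint_fn(replica_coords, T, phase_label) -> RestraintResult`` (or
    None for an unbiased control run) is evaluated at every integration
    step from the instantaneous replica coordinates.  Each cycle starts
    from the previous cycle's final structures.  Frames are harvested only
    during phases whose temperature is pinned at 304 K, and only after the
    burn-in cycles.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    config = config or RefinementConfig()
    discard = config.discard_cycles if discard_cycles is None else discard_cycles
    if n_cycles <= discard:
        raise ValueError("n_cycles must exceed the discarded burn-in")

    rng = np.random.default_rng(seed)
    if start_positions is None:
        start = np.repeat(system.positions[None], M, axis=0)
    else:
        start = np.asarray(start_positions, dtype=float)
        if start.shape != (M, system.n_beads, 3):
            raise ValueError("start_positions must be (M, n_beads, 3)")
    state = LangevinState(start.copy(),
                          _thermal_velocities(system, M, schedule.phases[0].T_start, rng))

    harvested = [[] for _ in range(M)]
    rows = []
    for cycle in range(n_cycles):
        if config.rerandomize_velocities and cycle > 0:
            state.velocities = _thermal_velocities(
                system, M, schedule.phases[0].T_start, rng)
        forces = None
        cycle_diag = {}
        t0 = 0.0
        for phase in schedule.phases:
            n_steps = max(1, round(phase.duration * config.time_scale / config.dt))
            is_harvest_phase = (phase.T_start == phase.T_end == 304.0)
            harvest_steps = set()
            if is_harvest_phase and cycle >= discard:
                # evenly spaced harvest points within the plateau
                k = min(config.harvest_per_cycle, n_steps)
                harvest_steps = {
                    int((j + 1) * n_steps / k) - 1 for j in range(k)}
            for s in range(n_steps):
                t = t0 + (s + 0.5) / n_steps * phase.duration
                T = schedule.temperature_at(t)
                if restraint_fn is not None:
                    rr = restraint_fn(state.positions, T, phase.label)
                    restraint_forces = rr.forces
                else:
                    rr = None
                    restraint_forces = None
                # restraint forces change every step: do not reuse cached sums
                state, forces = langevin_step(
                    state, system, restraint_forces, config.dt, T,
                    config.friction, rng, forces=None)
                if s in harvest_steps:
                    for m in range(M):
                        harvested[m].append(state.positions[m].copy())
            if phase.label == "low_T" and rr is not None:
                diag = rr.diagnostics
                cycle_diag["restraint_energy"] = rr.energy
                if "cs" in diag:
                    cycle_diag["cs_mean_abs_dev"] = diag["cs"]["mean_abs_deviation"]
                if "noe" in diag:
                    cycle_diag["noe_max_violation"] = diag["noe"]["max_violation"]
            t0 += phase.duration
        rows.append({"cycle": cycle, **cycle_diag})

    def to_ensemble(frames, tag):
        frames = np.array(frames) if frames else np.zeros((0, system.n_beads, 3))
        return Ensemble(frames, system.atom_names,
                        system.residue_indices, system.residue_names,
                        system.masses, provenance=tag)

    replica_ens = [
        to_ensemble(harvested[m], f"replica {m} harvested 304 K frames")
        for m in range(M)
    ]
    pooled = to_ensemble(
        [f for m in range(M) for f in harvested[m]],
        f"pooled harvested ensemble (M={M}, seed={seed})")
    metadata = {
        "M": M,
        "n_cycles": n_cycles,
        "discard_cycles": discard,
        "seed": seed,
        "cycle_duration_ps": schedule.total_duration,
        "cycle_duration_ns": schedule.total_duration / 1000.0,
        "harvest_per_cycle": config.harvest_per_cycle,
        "time_scale": config.time_scale,
    }
    return RefinementRun(replica_ens, pooled, pd.DataFrame(rows), metadata)
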