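"""Replica-averaged experimental restraint energies and forces.

Chemical shifts are restrained with a harmonic penalty on the *replica mean*
(the practical maximum-entropy construction): individual copies fluctuate
freely while the ensemble average is pulled towards experiment.  The force
constant defaults to 5.2 kJ mol^-1 ppm^-2 and is scaled by (304 K / T) at
the elevated annealing temperatures.

NOE distances are first pooled r^-6 over equivalent protons within each
replica and then r^-6 over replicas; the pooled value is held inside the
experimental interval by a flat-bottom potential: zero inside
[lower, upper], half-harmonic outside, with a slope-continuous linear tail
beyond ``upper + r_linear`` (mirroring the GROMACS distance-restraint
shape).  The force constant switches with the annealing phase:
1000 kJ mol^-1 nm^-2 at the 304 K plateau, 20 during heating (and the high-T
plateau), 125 during cooling.

With a single replica both terms reduce exactly to conventional restrained
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .predictors import ShiftPredictorParams, predict_shifts

__all__ = [
    "CSRestraintConfig",
    "NoePhaseConstants",
    "RestraintResult",
    "cs_restraint",
    "noe_restraint",
    "total_restraint_force",
    "resolve_noe_indices",
    "make_restraint_function",
]


@dataclass
class CSRestraintConfig:
    """Chemical-shift restraint settings.

    ``k_cs`` in kJ mol^-1 ppm^-2 (default 5.2); the energy is scaled by
    ``T_ref / T``.  ``normalize`` divides the penalty by the number of
    shifts (off by default: the penalty is an unnormalized sum over shifts).
    """

    k_cs: float = 5.2
    T_ref: float = 304.0
    normalize: bool = False

    def __post_init__(self):
        if self.k_cs < 0:
            raise ValueError("k_cs must be non-negative")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive")


@dataclass
class NoePhaseConstants:
    """Per-phase NOE force constants (kJ mol^-1 nm^-2).

    The low-temperature plateau uses the strong constant, heating (and the
    high-temperature plateau, which shares its weak restraint) the weakest,
    cooling an intermediate one.
    """

    k_low_T: float = 1000.0
    k_heat: float = 20.0
    k_cool: float = 125.0
    r_linear: float = 0.2  # nm beyond the upper bound where the tail turns linear

    def __post_init__(self):
        if min(self.k_low_T, self.k_heat, self.k_cool) < 0:
            raise ValueError("force constants must be non-negative")

    def for_phase(self, phase: str) -> float:
        try:
            return {"low_T": self.k_low_T, "heat": self.k_heat,
                    "high_T": self.k_heat, "cool": self.k_cool}[phase]
        except KeyError:
            raise ValueError(f"unknown phase label {phase!r}") from None


@dataclass
class RestraintResult:
    """Energy (kJ/mol), per-replica per-atom forces (kJ mol^-1 nm^-1, equal
    to minus the energy gradient) and per-restraint diagnostics."""

    energy: float
    forces: np.ndarray  # (M, N, 3)
    diagnostics: dict = field(default_factory=dict)


def cs_restraint(replica_coords, shift_table, predictor_params, config, T,
                 residue_indices=None, predictor=predict_shifts) -> RestraintResult:
    """Harmonic restraint on the replica-mean chemical shifts.

    ``E = k_cs (T_ref/T) sum_i ( (1/M) sum_m delta_mi - delta_exp_i )^2``.
    Forces are chain-ruled through the predictor gradients; each replica
    carries the 1/M averaging factor.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    X = np.asarray(replica_coords, dtype=float)
    if X.ndim == 2:
        X = X[None]
    M, n_atoms = X.shape[0], X.shape[1]
    if residue_indices is None:
        residue_indices = np.arange(1, n_atoms + 1)

    records = list(shift_table)
    keys = [r.key for r in records]
    exp = np.array([r.value for r in records])

    if predictor is predict_shifts:
        from .predictors import predict_shifts_batch
        values, grads, skipped = predict_shifts_batch(
            X, residue_indices, keys, predictor_params, with_gradient=True)
        if skipped:
            raise ValueError(f"unpredictable shifts in table: {skipped}")
    else:  # external predictor plugin: one conformation at a time
        preds = []
        for m in range(M):
            p = predictor(X[m], residue_indices, keys, predictor_params,
                          with_gradient=True)
            if p.skipped:
                raise ValueError(f"unpredictable shifts in table: {p.skipped}")
            preds.append(p)
        values = np.stack([p.values for p in preds])
        grads = np.stack([p.gradients for p in preds])
    mean = values.mean(axis=0)
    dev = mean - exp

    k_T = config.k_cs * (config.T_ref / T)
    norm = len(keys) if (config.normalize and keys) else 1
    energy = k_T * float(np.sum(dev ** 2)) / norm

    coef = 2.0 * k_T * dev / (M * norm)  # dE/d(delta_mi)
    forces = -np.einsum("i,mijk->mjk", coef, grads)
    diag = {
        "keys": keys,
        "deviation": dev,
        "replica_values": values,
        "mean_abs_deviation": float(np.mean(np.abs(dev))) if keys else 0.0,
    }
    return RestraintResult(energy, forces, diag)


def resolve_noe_indices(noe_set, atom_index: dict) -> list:
    """Resolve restraint groups to atom indices via a
    (residue_index, atom_name) -> atom position map.  Raises on atoms
    missing from the system, listing the offending restraint."""
    resolved = []
    for k, r in enumerate(noe_set):
        try:
            ai = np.array([atom_index[key] for key in r.group_i], dtype=int)
            aj = np.array([atom_index[key] for key in r.group_j], dtype=int)
        except KeyError as exc:
            raise ValueError(
                f"restraint {k}: atom {exc.args[0]} not present in system"
            ) from None
        resolved.append((ai, aj))
    return resolved


class _FlatNoeIndex:
    """Flattened (restraint, cross-pair) index arrays so the whole NOE term
    evaluates in a handful of vectorized operations per step."""

    def __init__(self, noe_set, resolved):
        pi, pj, seg = [], [], []
        counts = []
        for k, (ai, aj) in enumerate(resolved):
            n_pairs = 0
            for a in ai:
                for b in aj:
                    pi.append(a)
                    pj.append(b)
                    seg.append(k)
                    n_pairs += 1
            counts.append(n_pairs)
        self.pi = np.array(pi, dtype=int)
        self.pj = np.array(pj, dtype=int)
        self.seg = np.array(seg, dtype=int)
        self.counts = np.array(counts, dtype=int)
        self.n = len(resolved)
        self.lower = np.array([r.lower for r in noe_set])
        self.upper = np.array([r.upper for r in noe_set])


def _flat_bottom(r_eff, lower, upper, k, r_linear):
    """Energy and dE/dr_eff of the flat-bottom interval potential."""
    if r_eff < lower:
        d = lower - r_eff
        return 0.5 * k * d * d, -k * d
    if r_eff <= upper:
        return 0.0, 0.0
    d = r_eff - upper
    if d <= r_linear:
        return 0.5 * k * d * d, k * d
    # slope-continuous linear tail
    return 0.5 * k * r_linear ** 2 + k * r_linear * (d - r_linear), k * r_linear


def noe_restraint(replica_coords, noe_set, phase, constants,
                  resolved_indices=None, atom_index=None) -> RestraintResult:
    """Flat-bottom restraint on the replica-and-group r^-6 mean distance.

    For each restraint, ``r_eff = ((1/M) sum_m r_m^-6)^(-1/6)`` where
    ``r_m`` is the group-pooled effective distance within replica m; this
    equals the r^-6 mean over all (replica, cross-pair) combinations.
    """
    X = np.asarray(replica_coords, dtype=float)
    if X.ndim == 2:
        X = X[None]
    M = X.shape[0]
    k = constants.for_phase(phase)

    if isinstance(resolved_indices, _FlatNoeIndex):
        flat = resolved_indices
    else:
        if resolved_indices is None:
            if atom_index is None:
                raise ValueError("need resolved_indices or atom_index")
            resolved_indices = resolve_noe_indices(noe_set, atom_index)
        flat = _FlatNoeIndex(noe_set, resolved_indices)

    diff = X[:, flat.pi] - X[:, flat.pj]  # (M, P, 3)
    r2 = np.einsum("mpk,mpk->mp", diff, diff)
    if np.any(r2 == 0):
        bad = int(flat.seg[np.argwhere(r2 == 0)[0][1]])
        raise ValueError(f"restraint {bad}: overlapping atoms (r = 0)")
    inv6 = r2 ** -3
    # r^-6 mean over replicas and cross pairs, per restraint
    S = np.bincount(flat.seg, weights=inv6.sum(axis=0), minlength=flat.n) \
        / (M * flat.counts)
    r_eff = S ** (-1.0 / 6.0)

    rl = constants.r_linear
    d_lo = flat.lower - r_eff
    d_up = r_eff - flat.upper
    e_up = np.where(d_up <= rl, 0.5 * k * d_up ** 2,
                    0.5 * k * rl ** 2 + k * rl * (d_up - rl))
    energies = np.where(d_lo > 0, 0.5 * k * d_lo ** 2,
                        np.where(d_up > 0, e_up, 0.0))
    dE_dreff = np.where(d_lo > 0, -k * d_lo,
                        np.where(d_up > 0, k * np.minimum(d_up, rl), 0.0))
    energy = float(energies.sum())
    violations = np.maximum(0.0, np.maximum(d_lo, d_up))

    forces = np.zeros_like(X)
    if np.any(dE_dreff != 0.0):
        # dr_eff/dr_pair = r_eff^7 r_pair^-7 / (M P)
        rpair = np.sqrt(r2)
        per_pair = (dE_dreff * r_eff ** 7 / flat.counts)[flat.seg] / M
        coef = per_pair * rpair ** -7  # (M, P) dE/dr_pair
        grad_pair = (coef / rpair)[..., None] * diff  # dE/dx on the pi side
        np.add.at(forces, (slice(None), flat.pi), -grad_pair)
        np.add.at(forces, (slice(None), flat.pj), grad_pair)
    diag = {"r_eff": r_eff, "violation": violations,
            "max_violation": float(violations.max(initial=0.0))}
    return RestraintResult(energy, forces, diag)


def total_restraint_force(replica_coords, shift_table=None, noe_set=None,
                          predictor_params=None, cs_config=None,
                          noe_constants=None, T=304.0, phase="low_T",
                          residue_indices=None, resolved_indices=None,
                          atom_index=None) -> RestraintResult:
    """Sum of the chemical-shift and NOE restraint terms (energies and
    forces are additive; diagnostics are merged under 'cs'/'noe')."""
    X = np.asarray(replica_coords, dtype=float)
    if X.ndim == 2:
        X = X[None]
    energy = 0.0
    forces = np.zeros_like(X)
    diag = {}
    if shift_table is not None and len(shift_table):
        cs = cs_restraint(X, shift_table, predictor_params or ShiftPredictorParams(),
                          cs_config or CSRestraintConfig(), T,
                          residue_indices=residue_indices)
        energy += cs.energy
        forces += cs.forces
        diag["cs"] = cs.diagnostics
        diag["cs_energy"] = cs.energy
    if noe_set is not None and len(noe_set):
        noe = noe_restraint(X, noe_set, phase, noe_constants or NoePhaseConstants(),
                            resolved_indices=resolved_indices,
                            atom_index=atom_index)
        energy += noe.energy
        forces += noe.forces
        diag["noe"] = noe.diagnostics
        diag["noe_energy"] = noe.energy
    return RestraintResult(energy, forces, diag)


def make_restraint_function(system, shift_table=None, noe_set=None,
                            predictor_params=None, cs_config=None,
                            noe_constants=None):
    """Bind restraint inputs to a system, returning
    ``f(replica_coords, T, phase) -> RestraintResult`` for the sampler.

    Resolves NOE atom groups once up front (raising before any integration
    if atoms are missing).
    """
    predictor_params = predictor_params or ShiftPredictorParams()
    cs_config = cs_config or CSRestraintConfig()
    noe_constants = noe_constants or NoePhaseConstants()
    atom_index = {
        (int(ri), an): k
        for k, (ri, an) in enumerate(zip(system.residue_indices, system.atom_names))
    }
    resolved = (_FlatNoeIndex(noe_set, resolve_noe_indices(noe_set, atom_index))
                if noe_set is not None and len(noe_set) else None)

    def restraint_fn(replica_coords, T, phase):
        return total_restraint_force(
            replica_coords, shift_table=shift_table, noe_set=noe_set,
            predictor_params=predictor_params, cs_config=cs_config,
            noe_constants=noe_constants, T=T, phase=phase,
            residue_indices=system.residue_indices,
            resolved_indices=resolved)

    return restraint_fn
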