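"""Cross-validation metrics for refined ensembles.

Reduced chi^2 against the predictor uncertainty, a census of NOE bound
violations binned by magnitude and sequence-separation class, radius of
gyration, and persistent side-chain contact counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .predictors import effective_distance

__all__ = [
    "ChiSquaredReport",
    "ViolationReport",
    "reduced_chi2",
    "noe_violations",
    "radius_of_gyration",
    "sidechain_contacts",
    "BACKBONE_ATOMS",
]

ANGSTROM_PER_NM = 10.0

#: Atom names regarded as backbone when picking side-chain atoms.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT"})

#: Violation magnitude bins in Å, left-closed/right-open; violations below
#: the first edge count towards the total but are not binned.
VIOLATION_BINS = ((0.5, 1.0), (1.0, 2.0), (2.0, np.inf))


@dataclass
class ChiSquaredReport:
    """Reduced chi^2 per nucleus type and overall.

    ``chi2 = (1/N) sum_i (calc_i - exp_i)^2 / sigma_type(i)^2``; values
    near 1 mean the deviations match the predictor uncertainty.
    """

    per_type: dict  # nucleus -> (chi2_red, n)
    overall: float
    n_total: int
    sigma_used: dict


@dataclass
class ViolationReport:
    """NOE violation census.

    ``bins`` maps (bin_label, range_class) -> count for the magnitude bins
    0.5-1 / 1-2 / >2 Å; ``total`` counts every violated restraint
    (including sub-0.5 Å violations, which are not binned);
    ``per_restraint`` holds each restraint's violation in Å.
    """

    bins: dict
    total: int
    n_binned: int
    per_restraint: np.ndarray
    range_classes: list = field(default_factory=list)

    @staticmethod
    def bin_label(lo, hi):
        return f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"


def reduced_chi2(calc_shifts: dict, exp_shifts, sigma_per_type: dict) -> ChiSquaredReport:
    """Reduced chi^2 between calculated and experimental shifts.

    ``calc_shifts`` maps (residue_index, nucleus) -> ppm (for an ensemble
    these are the frame-averaged predictions); ``exp_shifts`` is a
    ShiftTable or a like-keyed mapping.  Only overlapping keys enter; no
    overlap is an error.
    """
    exp = exp_shifts.by_key() if hasattr(exp_shifts, "by_key") else dict(exp_shifts)
    keys = [k for k in exp if k in calc_shifts]
    if not keys:
        raise ValueError("no overlapping (residue, nucleus) keys")
    per_type: dict = {}
    sq_sum = 0.0
    for k in keys:
        nucleus = k[1]
        sigma = sigma_per_type[nucleus]
        if sigma <= 0:
            raise ValueError(f"sigma for {nucleus} must be positive")
        z2 = ((calc_shifts[k] - exp[k]) / sigma) ** 2
        tot, n = per_type.get(nucleus, (0.0, 0))
        per_type[nucleus] = (tot + z2, n + 1)
        sq_sum += z2
    report_types = {nuc: (tot / n, n) for nuc, (tot, n) in per_type.items()}
    return ChiSquaredReport(per_type=report_types,
                            overall=sq_sum / len(keys),
                            n_total=len(keys),
                            sigma_used={k[1]: sigma_per_type[k[1]] for k in keys})


def noe_violations(ensemble, noe_set, use_replica_average: bool = True) -> ViolationReport:
    """Census of NOE bound violations for an ensemble, reported in Å.

    With ``use_replica_average`` (default) each restraint is evaluated on
    the frame-pooled r^-6 average (the observable the restraint acts on);
    otherwise the worst single-frame violation is reported.  Violation =
    max(0, r_eff - upper, lower - r_eff), binned left-closed into
    0.5-1 / 1-2 / >2 Å per range class.
    """
    atom_index = ensemble.atom_index()
    per = np.zeros(len(noe_set))
    classes = []
    for k, r in enumerate(noe_set):
        try:
            ai = [atom_index[key] for key in r.group_i]
            aj = [atom_index[key] for key in r.group_j]
        except KeyError as exc:
            raise ValueError(f"restraint {k}: atom {exc.args[0]} missing") from None
        r_frames = np.array([
            effective_distance(ensemble.coords[f], ai, aj)
            for f in range(ensemble.n_frames)
        ])
        if use_replica_average:
            r_eff = float(np.mean(r_frames ** -6) ** (-1.0 / 6.0))
            viol = max(0.0, r_eff - r.upper, r.lower - r_eff)
        else:
            viol = float(np.max(np.maximum(0.0, np.maximum(
                r_frames - r.upper, r.lower - r_frames))))
        per[k] = viol * ANGSTROM_PER_NM
        classes.append(r.range_class or "short")

    bins = {}
    for (lo, hi) in VIOLATION_BINS:
        for cls in ("short", "long"):
            bins[(ViolationReport.bin_label(lo, hi), cls)] = 0
    n_binned = 0
    for v, cls in zip(per, classes):
        if v <= 0:
            continue
        for (lo, hi) in VIOLATION_BINS:
            if lo <= v < hi:
                bins[(ViolationReport.bin_label(lo, hi), cls)] += 1
                n_binned += 1
                break
    return ViolationReport(bins=bins, total=int(np.sum(per > 0)),
                           n_binned=n_binned, per_restraint=per,
                           range_classes=classes)


def radius_of_gyration(coords, masses) -> float:
    """Mass-weighted radius of gyration, in the units of ``coords``.

    ``Rg = sqrt( sum_i m_i |r_i - r_cm|^2 / sum_i m_i )``.
    """
    X = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 atoms")
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    cm = (m[:, None] * X).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((X - cm) ** 2).sum(axis=1)).sum() / m.sum()))


def sidechain_contacts(ensemble, cutoff: float = 0.45, persistence: float = 0.5,
                       selection=None) -> int:
    """Count persistent side-chain contacts.

    A residue pair (|i - j| > 2) is in contact in a frame when the minimum
    distance between their selected atoms is below ``cutoff`` (nm); it
    counts when in contact in at least a ``persistence`` fraction of
    frames.  ``selection`` defaults to non-backbone heavy/side-chain atoms
    (names outside :data:`BACKBONE_ATOMS`).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not (0 < persistence <= 1):
        raise ValueError("persistence must lie in (0, 1]")
    if selection is None:
        selection = [k for k, a in enumerate(ensemble.atom_names)
                     if a not in BACKBONE_ATOMS]
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("no side-chain atoms in the ensemble")
    resi = ensemble.residue_indices[selection]
    residues = np.unique(resi)
    count = 0
    for a_pos, ri in enumerate(residues):
        for rj in residues[a_pos + 1:]:
            if abs(int(ri) - int(rj)) <= 2:
                continue
            ai = selection[resi == ri]
            aj = selection[resi == rj]
            diff = ensemble.coords[:, ai][:, :, None, :] \
                - ensemble.coords[:, aj][:, None, :, :]
            dmin = np.sqrt(np.einsum("fpqk,fpqk->fpq", diff, diff)).min(axis=(1, 2))
            if np.mean(dmin < cutoff) >= persistence:
                count += 1
    return count
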