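"""Input/output for NMR observables and structure ensembles.

Chemical-shift tables and NOE distance-interval tables are read from TSV
(column layouts documented below) or from a minimal NMR-STAR subset covering
only the assigned-chemical-shift and distance-restraint loops.  Structure
ensembles are read/written as multimodel PDB (via biotite) or plain XYZ.

Internal units are nm for all distances; Ångström input is converted on read
when the table declares it.  Residue indices are 1-based, atom names follow
PDB v3 conventions.

TSV dialects (comment character ``#``, tab- or whitespace-separated):

* shift table:  ``residue_index  residue_name  nucleus  value_ppm``
* NOE table:    ``resi_i  atoms_i  resi_j  atoms_j  lower  upper  unit``
  where ``atoms_i``/``atoms_j`` are comma-separated atom names (pseudoatoms
  like ``MD1`` are expanded through :data:`PSEUDOATOM_EXPANSIONS`) and
  ``unit`` is ``nm`` or ``A``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "NUCLEI",
    "ShiftRecord",
    "ShiftTable",
    "NoeRestraint",
    "NoeRestraintSet",
    "Ensemble",
    "ParseError",
    "classify_range",
    "read_shift_table",
    "read_noe_table",
    "read_ensemble",
    "write_ensemble",
    "make_synthetic_dataset",
    "PSEUDOATOM_EXPANSIONS",
    "DEFAULT_SHIFT_EXCLUSIONS",
]

#: Closed vocabulary of nucleus labels.
NUCLEI = frozenset({"CA", "CB", "C", "H", "HA", "N", "methyl-C", "methyl-H"})

#: Shifts dropped on read by default: glutamine Cbeta is excluded because
#: structure-based predictors are unreliable for it.
DEFAULT_SHIFT_EXCLUSIONS = frozenset({("GLN", "CB")})

#: Convenience expansion of common methyl/degenerate pseudoatom names into
#: explicit proton groups.  Equivalent protons are otherwise declared
#: explicitly in the NOE table.
PSEUDOATOM_EXPANSIONS = {
    "MB": ("HB1", "HB2", "HB3"),
    "MG": ("HG1", "HG2", "HG3"),
    "MG1": ("HG11", "HG12", "HG13"),
    "MG2": ("HG21", "HG22", "HG23"),
    "MD": ("HD1", "HD2", "HD3"),
    "MD1": ("HD11", "HD12", "HD13"),
    "MD2": ("HD21", "HD22", "HD23"),
    "ME": ("HE1", "HE2", "HE3"),
    "QA": ("HA1", "HA2"),
    "QB": ("HB2", "HB3"),
    "QG": ("HG2", "HG3"),
    "QD": ("HD2", "HD3"),
    "QE": ("HE2", "HE3"),
}

ANGSTROM_PER_NM = 10.0


class ParseError(ValueError):
    """Raised for malformed input tables; names the offending line."""


@dataclass(frozen=True)
class ShiftRecord:
    """A single assigned chemical shift."""

    residue_index: int
    residue_name: str
    nucleus: str
    value: float  # ppm

    def __post_init__(self):
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}; allowed: {sorted(NUCLEI)}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite shift value for residue {self.residue_index}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_index, self.nucleus)


@dataclass
class ShiftTable:
    """List-like collection of :class:`ShiftRecord` with bookkeeping.

    ``n_excluded`` counts records dropped by the exclusion rule on read
    (default: glutamine Cbeta).
    """

    records: list[ShiftRecord] = field(default_factory=list)
    n_excluded: int = 0
    n_unmapped: int = 0  # NMR-STAR rows whose atom id maps to no nucleus

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_key(self) -> dict[tuple[int, str], float]:
        return {r.key: r.value for r in self.records}

    def count(self, nucleus: str) -> int:
        return sum(1 for r in self.records if r.nucleus == nucleus)


@dataclass(frozen=True)
class NoeRestraint:
    """One NOE-derived distance interval between two (possibly degenerate)
    proton groups.  Bounds are in nm; ``range_class`` is ``"long"`` when the
    closest residue pair across the two groups is more than 4 residues apart.
    """

    group_i: tuple[tuple[int, str], ...]
    group_j: tuple[tuple[int, str], ...]
    lower: float  # nm
    upper: float  # nm
    range_class: str = ""

    def __post_init__(self):
        if not self.group_i or not self.group_j:
            raise ValueError("restraint groups must be non-empty")
        if set(self.group_i) & set(self.group_j):
            raise ValueError("restraint groups must be disjoint")
        if not (0 < self.lower <= self.upper):
            raise ValueError(
                f"need 0 < lower <= upper, got lower={self.lower}, upper={self.upper}"
            )


def classify_range(restraint: NoeRestraint) -> str:
    """Sequence-separation class of a restraint.

    ``"long"`` iff every residue pair across the two groups is separated by
    more than 4 residues (equivalently the minimum |i - j| exceeds 4),
    ``"short"`` otherwise (including intra-residue pairs).
    """
    sep = min(
        abs(ri - rj) for ri, _ in restraint.group_i for rj, _ in restraint.group_j
    )
    return "long" if sep > 4 else "short"


@dataclass
class NoeRestraintSet:
    """Collection of NOE restraints with range-class tallies."""

    restraints: list[NoeRestraint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.restraints)

    def __len__(self):
        return len(self.restraints)

    def __getitem__(self, i):
        return self.restraints[i]

    @property
    def n_short(self) -> int:
        return sum(1 for r in self.restraints if r.range_class == "short")

    @property
    def n_long(self) -> int:
        return sum(1 for r in self.restraints if r.range_class == "long")


@dataclass
class Ensemble:
    """A multi-conformation structure: frames sharing one atom table.

    Coordinates are stored as an ``(n_frames, n_atoms, 3)`` array in nm.
    """

    coords: np.ndarray
    atom_names: list[str]
    residue_indices: np.ndarray
    residue_names: list[str]
    masses: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError(f"coords must be (F, N, 3), got {self.coords.shape}")
        n = self.coords.shape[1]
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if not (len(self.atom_names) == len(self.residue_indices)
                == len(self.residue_names) == len(self.masses) == n):
            raise ValueError("atom table lengths inconsistent with coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self) -> dict[tuple[int, str], int]:
        """Map (residue_index, atom_name) -> atom position in the table."""
        return {
            (int(ri), an): k
            for k, (ri, an) in enumerate(zip(self.residue_indices, self.atom_names))
        }

    def select(self, atom_name: str) -> np.ndarray:
        """Indices of atoms with the given name."""
        return np.array([k for k, a in enumerate(self.atom_names) if a == atom_name],
                        dtype=int)

    def subset_frames(self, idx) -> "Ensemble":
        return replace(self, coords=self.coords[idx])


# ---------------------------------------------------------------------------
# Chemical-shift tables
# ---------------------------------------------------------------------------

def _iter_table_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line


def read_shift_table(path, dialect: str = "tsv",
                     exclude=DEFAULT_SHIFT_EXCLUSIONS) -> ShiftTable:
    """Read a chemical-shift table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"tsv"`` (residue_index, residue_name, nucleus, value_ppm) or
        ``"nmrstar-subset"`` (the ``_Atom_chem_shift`` loop only).
    exclude
        Set of ``(residue_name, nucleus)`` pairs dropped and counted;
        defaults to glutamine Cbeta.

    Raises
    ------
    ParseError
        Malformed rows (naming the line) or duplicate (residue, nucleus).
    """
    if dialect == "tsv":
        table = _read_shift_tsv(path, exclude)
    elif dialect == "nmrstar-subset":
        table = _read_shift_star(path, exclude)
    else:
        raise ValueError(f"unknown shift-table dialect {dialect!r}")
    seen: dict[tuple[int, str], int] = {}
    for rec in table.records:
        if rec.key in seen:
            raise ParseError(
                f"{path}: duplicate shift for residue {rec.residue_index} "
                f"nucleus {rec.nucleus}"
            )
        seen[rec.key] = 1
    return table


def _read_shift_tsv(path, exclude) -> ShiftTable:
    records, n_excluded = [], 0
    for lineno, line in _iter_table_lines(path):
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            resi = int(parts[0])
            value = float(parts[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        resn, nucleus = parts[1].upper(), parts[2]
        if nucleus not in NUCLEI:
            raise ParseError(f"{path}:{lineno}: unknown nucleus {nucleus!r}")
        if (resn, nucleus) in exclude:
            n_excluded += 1
            continue
        records.append(ShiftRecord(resi, resn, nucleus, value))
    return ShiftTable(records, n_excluded=n_excluded)


# -- minimal NMR-STAR loop reader -------------------------------------------

def _star_tokens(text: str):
    """Tokenize NMR-STAR, honouring quoted values and comments."""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(";"):  # multi-line values are not needed here
            continue
        i = 0
        while i < len(line):
            if line[i].isspace():
                i += 1
                continue
            if line[i] in "'\"":
                q = line[i]
                j = line.index(q, i + 1)
                yield line[i + 1:j]
                i = j + 1
            else:
                j = i
                while j < len(line) and not line[j].isspace():
                    j += 1
                tok = line[i:j]
                if tok.startswith("#"):
                    break
                yield tok
                i = j
        continue


def _star_loops(path):
    """Yield (tags, rows) for each loop_ in an NMR-STAR file."""
    text = Path(path).read_text()
    toks = list(_star_tokens(text))
    i = 0
    while i < len(toks):
        if toks[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < len(toks) and toks[i].startswith("_"):
            tags.append(toks[i])
            i += 1
        values = []
        while i < len(toks) and toks[i].lower() not in ("stop_", "loop_") \
                and not toks[i].startswith("_") \
                and not toks[i].lower().startswith("save_"):
            values.append(toks[i])
            i += 1
        if i < len(toks) and toks[i].lower() == "stop_":
            i += 1
        if tags and len(values) % len(tags) == 0:
            rows = [values[k:k + len(tags)] for k in range(0, len(values), len(tags))]
            yield tags, rows


_STAR_ATOM_TO_NUCLEUS = {"CA": "CA", "CB": "CB", "C": "C", "H": "H", "HN": "H",
                         "HA": "HA", "N": "N"}


def _read_shift_star(path, exclude) -> ShiftTable:
    records, n_excluded, n_unmapped = [], 0, 0
    found = False
    for tags, rows in _star_loops(path):
        cols = {t.split(".")[-1].lower(): k for k, t in enumerate(tags)}
        if not any(t.lower().startswith("_atom_chem_shift.") for t in tags):
            continue
        found = True
        i_res = cols.get("seq_id", cols.get("comp_index_id"))
        i_resn = cols.get("comp_id")
        i_atom = cols.get("atom_id")
        i_val = cols.get("val")
        if None in (i_res, i_resn, i_atom, i_val):
            raise ParseError(f"{path}: chemical-shift loop lacks required tags")
        for row in rows:
            atom = row[i_atom].upper()
            nucleus = _STAR_ATOM_TO_NUCLEUS.get(atom)
            if nucleus is None:
                n_unmapped += 1
                continue
            resn = row[i_resn].upper()
            if (resn, nucleus) in exclude:
                n_excluded += 1
                continue
            try:
                records.append(
                    ShiftRecord(int(row[i_res]), resn, nucleus, float(row[i_val]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: bad chemical-shift row {row}: {exc}") from None
    if not found:
        raise ParseError(f"{path}: no _Atom_chem_shift loop found")
    return ShiftTable(records, n_excluded=n_excluded, n_unmapped=n_unmapped)


# ---------------------------------------------------------------------------
# NOE tables
# ---------------------------------------------------------------------------

def _expand_group(resi: int, atoms_field: str, path, lineno) -> tuple:
    group = []
    for name in atoms_field.split(","):
        name = name.strip()
        if not name:
            raise ParseError(f"{path}:{lineno}: empty atom name in group")
        for expanded in PSEUDOATOM_EXPANSIONS.get(name.upper(), (name,)):
            group.append((resi, expanded))
    return tuple(group)


def read_noe_table(path, dialect: str = "tsv") -> NoeRestraintSet:
    """Read NOE distance intervals; bounds are converted to nm.

    The TSV layout is ``resi_i atoms_i resi_j atoms_j lower upper unit``
    with ``unit`` in {``nm``, ``A``}.  ``dialect="nmrstar-subset"`` reads the
    ``_Gen_dist_constraint`` loop (bounds in Å per NMR-STAR convention).
    Each restraint's ``range_class`` is filled from :func:`classify_range`.
    """
    if dialect == "tsv":
        restraints = _read_noe_tsv(path)
    elif dialect == "nmrstar-subset":
        restraints = _read_noe_star(path)
    else:
        raise ValueError(f"unknown NOE-table dialect {dialect!r}")
    classified = [replace(r, range_class=classify_range(r)) for r in restraints]
    return NoeRestraintSet(classified)


def _read_noe_tsv(path) -> list[NoeRestraint]:
    restraints = []
    for lineno, line in _iter_table_lines(path):
        parts = line.split()
        if len(parts) != 7:
            raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            resi_i, resi_j = int(parts[0]), int(parts[2])
            lower, upper = float(parts[4]), float(parts[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        unit = parts[6]
        if unit.upper() in ("A", "ANG", "ANGSTROM"):
            lower /= ANGSTROM_PER_NM
            upper /= ANGSTROM_PER_NM
        elif unit.lower() != "nm":
            raise ParseError(f"{path}:{lineno}: unknown unit {unit!r}")
        if lower > upper:
            raise ParseError(f"{path}:{lineno}: lower bound exceeds upper bound")
        gi = _expand_group(resi_i, parts[1], path, lineno)
        gj = _expand_group(resi_j, parts[3], path, lineno)
        try:
            restraints.append(NoeRestraint(gi, gj, lower, upper))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return restraints


def _read_noe_star(path) -> list[NoeRestraint]:
    restraints = []
    found = False
    for tags, rows in _star_loops(path):
        if not any(t.lower().startswith("_gen_dist_constraint.") for t in tags):
            continue
        found = True
        cols = {t.split(".")[-1].lower(): k for k, t in enumerate(tags)}

        def get(row, *names):
            for n in names:
                k = cols.get(n)
                if k is not None:
                    return row[k]
            raise ParseError(f"{path}: distance-restraint loop lacks {names}")

        # NMR-STAR lists one row per atom pair; rows sharing a restraint ID
        # form one degenerate-group restraint.
        by_id: dict[str, dict] = {}
        for row in rows:
            rid = get(row, "id")
            entry = by_id.setdefault(rid, {"gi": [], "gj": [], "lo": None, "up": None})
            ri = int(get(row, "seq_id_1", "comp_index_id_1"))
            rj = int(get(row, "seq_id_2", "comp_index_id_2"))
            ai = get(row, "atom_id_1").upper()
            aj = get(row, "atom_id_2").upper()
            for name in PSEUDOATOM_EXPANSIONS.get(ai, (ai,)):
                if (ri, name) not in entry["gi"]:
                    entry["gi"].append((ri, name))
            for name in PSEUDOATOM_EXPANSIONS.get(aj, (aj,)):
                if (rj, name) not in entry["gj"]:
                    entry["gj"].append((rj, name))
            lo = get(row, "distance_lower_bound_val")
            up = get(row, "distance_upper_bound_val")
            entry["lo"] = None if lo in (".", "?") else float(lo)
            entry["up"] = None if up in (".", "?") else float(up)
        for rid, entry in by_id.items():
            lo = entry["lo"] if entry["lo"] is not None else 0.18 * ANGSTROM_PER_NM
            up = entry["up"]
            if up is None:
                raise ParseError(f"{path}: restraint {rid} has no upper bound")
            if lo > up:
                raise ParseError(f"{path}: restraint {rid}: lower exceeds upper")
            restraints.append(
                NoeRestraint(tuple(entry["gi"]), tuple(entry["gj"]),
                             lo / ANGSTROM_PER_NM, up / ANGSTROM_PER_NM)
            )
    if not found:
        raise ParseError(f"{path}: no _Gen_dist_constraint loop found")
    return restraints


# ---------------------------------------------------------------------------
# Structure ensembles
# ---------------------------------------------------------------------------

def read_ensemble(path, format: str = "pdb-multimodel") -> Ensemble:
    """Read a multimodel PDB (coordinates in Å on file) or XYZ ensemble.

    All models must share one atom table; coordinates are converted to nm.
    """
    if format == "pdb-multimodel":
        return _read_pdb(path)
    if format == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown ensemble format {format!r}")


def write_ensemble(ensemble: Ensemble, path, format: str = "pdb-multimodel") -> None:
    """Write an ensemble; PDB carries 3 decimals in Å (1e-3 Å precision)."""
    if format == "pdb-multimodel":
        _write_pdb(ensemble, path)
    elif format == "xyz":
        _write_xyz(ensemble, path)
    else:
        raise ValueError(f"unknown ensemble format {format!r}")


def _read_pdb(path) -> Ensemble:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    names = [str(a) for a in stack.atom_name]
    resi = np.asarray(stack.res_id, dtype=int)
    resn = [str(r) for r in stack.res_name]
    masses = _guess_masses(names)
    return Ensemble(coords, names, resi, resn, masses, provenance=str(path))


def _write_pdb(ensemble: Ensemble, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = ensemble.coords * ANGSTROM_PER_NM
    stack.atom_name = np.array(ensemble.atom_names)
    stack.res_id = np.array(ensemble.residue_indices)
    stack.res_name = np.array(ensemble.residue_names)
    stack.chain_id = np.array(["A"] * n)
    stack.element = np.array([_element_of(a) for a in ensemble.atom_names])
    stack.hetero = np.zeros(n, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _guess_masses(atom_names) -> np.ndarray:
    return np.array([_ELEMENT_MASS.get(_element_of(a), 12.011) for a in atom_names])


def _read_xyz(path) -> Ensemble:
    """XYZ trajectory: repeated blocks of ``n`` / comment / n atom lines.

    Coordinates on file are in Å (the customary XYZ unit); the atom-name
    column may carry ``NAME:RESI`` to preserve the residue index.
    """
    frames, names, resis = [], None, None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated XYZ frame at line {i + 1}")
        cur_names, cur_resis, coords = [], [], []
        for ln in block:
            parts = ln.split()
            label = parts[0]
            if ":" in label:
                name, resi = label.split(":", 1)
                cur_resis.append(int(resi))
            else:
                name = label
                cur_resis.append(len(cur_names) + 1)
            cur_names.append(name)
            coords.append([float(x) for x in parts[1:4]])
        if names is None:
            names, resis = cur_names, cur_resis
        elif cur_names != names:
            raise ParseError(f"{path}: inconsistent atom table across XYZ frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    coords = np.asarray(frames, dtype=float) / ANGSTROM_PER_NM
    return Ensemble(coords, names, np.array(resis), ["UNK"] * len(names),
                    _guess_masses(names), provenance=str(path))


def _write_xyz(ensemble: Ensemble, path) -> None:
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for k in range(ensemble.n_atoms):
                x, y, z = ensemble.coords[f, k] * ANGSTROM_PER_NM
                label = f"{ensemble.atom_names[k]}:{ensemble.residue_indices[k]}"
                fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

#: Fraction of long-range intervals the generator targets, matching the
#: 46-in-455 proportion of the NCBD restraint list it emulates.
LONG_RANGE_FRACTION = 46 / 409  # long per short restraint

#: Half-width of generated distance intervals (nm); 1 Å is the typical
#: width of NOE-derived bound classes.
NOE_HALF_WIDTH = 0.1


def make_synthetic_dataset(n_beads: int = 20, n_frames: int = 50,
                           noise_level: float = 0.0, seed: int = 0,
                           predictor_params=None):
    """Generate a self-consistent toy dataset (ensemble, shifts, NOEs).

    A reference ensemble is sampled with the coarse-grained chain at 304 K.
    "Experimental" shifts are the frame-averaged synthetic-predictor values;
    NOE intervals are centred on the ensemble r^-6 effective distances, so at
    ``noise_level = 0`` every restraint is satisfied exactly by the reference
    ensemble.  ``noise_level`` adds Gaussian error: in units of the per-type
    predictor sigma for the shifts, and in nm for the interval centres.
    Short-range intervals connect residues 2-4 apart; long-range partners
    (separation > 4) are added at roughly one per nine short intervals.

    Deterministic for a given seed.
    """
    from .predictors import ShiftPredictorParams, predict_shifts, effective_distance
    from .toy_sampler import build_toy_chain, sample_unrestrained

    if n_beads < 5:
        raise ValueError("n_beads must be >= 5")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (averaged observables undefined)")
    params = predictor_params or ShiftPredictorParams()
    rng = np.random.default_rng(seed)

    system = build_toy_chain(n_beads, seed=int(rng.integers(2 ** 31)))
    ensemble = sample_unrestrained(system, n_frames=n_frames, T=304.0,
                                   seed=int(rng.integers(2 ** 31)))
    ensemble.provenance = f"synthetic reference (seed={seed})"

    # --- shifts: frame-mean predicted values (+ optional noise) -----------
    keys = [(i, nuc) for i in range(1, n_beads + 1)
            for nuc in sorted(params.reference_shift)]
    mean_shifts = np.zeros(len(keys))
    for f in range(n_frames):
        pred = predict_shifts(ensemble.coords[f], ensemble.residue_indices,
                              keys, params)
        mean_shifts += pred.values
    mean_shifts /= n_frames
    shift_records = []
    for (resi, nuc), val in zip(keys, mean_shifts):
        val = val + noise_level * params.sigma[nuc] * rng.standard_normal()
        shift_records.append(ShiftRecord(resi, "BEA", nuc, float(val)))
    shifts = ShiftTable(shift_records)

    # --- NOE intervals from ensemble r^-6 distances ------------------------
    short_pairs = [(i, i + s) for s in (2, 3, 4)
                   for i in range(1, n_beads + 1 - s)]
    long_candidates = [(i, j) for i in range(1, n_beads + 1)
                       for j in range(i + 5, n_beads + 1)]
    n_long = int(round(LONG_RANGE_FRACTION * len(short_pairs)))

    def ens_reff(i, j):
        # frame-averaged r^-6 effective distance between beads i and j
        r6 = [effective_distance(ensemble.coords[f], [i - 1], [j - 1]) ** -6
              for f in range(n_frames)]
        return float(np.mean(r6) ** (-1 / 6))

    # rank long-range candidates by ensemble-average proximity: restrain the
    # genuinely close contacts, as NOEs report short distances only
    ranked = sorted(long_candidates, key=lambda p: ens_reff(*p))
    chosen = short_pairs + ranked[:n_long]
    restraints = []
    for (i, j) in chosen:
        c = ens_reff(i, j) + noise_level * rng.standard_normal()
        lower = max(0.05, c - NOE_HALF_WIDTH)
        upper = max(lower, c + NOE_HALF_WIDTH)
        restraints.append(
            NoeRestraint(((i, "CA"),), ((j, "CA"),), lower, upper)
        )
    noes = NoeRestraintSet(
        [replace(r, range_class=classify_range(r)) for r in restraints]
    )
    return ensemble, shifts, noes
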