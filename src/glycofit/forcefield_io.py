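"""Force-field parameter and conformer-dataset I/O.

Handles the AMBER text dialects this toolkit exchanges with the MD
ecosystem: ``frcmod`` parameter modification files (MASS / BOND / ANGLE /
DIHE / NONBON sections), the charge table of ``prep`` residue files, PDB
and XYZ coordinates, and a delimited manifest tying a conformer dataset
together (structure id, coordinate file, reference energy, optional
per-structure charge sets).

Units follow the AMBER convention: Angstrom, kcal/mol, elementary charge,
degrees in files.  Torsion phases are stored in degrees and wrapped to
[0, 360).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .molecule_model import Topology

__all__ = [
    "ParameterSet",
    "Conformer",
    "ConformerSet",
    "read_frcmod",
    "write_frcmod",
    "read_prep_charges",
    "write_prep",
    "read_coordinates",
    "write_xyz",
    "read_manifest",
    "write_manifest",
    "parameters_to_dict",
    "parameters_from_dict",
    "glucose_parameters",
]

BondType = tuple[str, str]
AngleType = tuple[str, str, str]
DihedralType = tuple[str, str, str, str]
FourierTerm = tuple[int, float, float]  # (periodicity n, amplitude V, phase gamma deg)


def _wrap_degrees(x: float) -> float:
    return float(x) % 360.0


@dataclass
class ParameterSet:
    """All constants of the AMBER-form energy function for one molecule.

    ``torsion_terms`` maps a canonical dihedral type to a list of Fourier
    terms ``(n, V, gamma)`` with ``n`` in 1..6, ``V`` in kcal/mol and the
    phase ``gamma`` in degrees.  ``lj_terms`` stores per-atom-type
    ``(Rmin/2, epsilon)``; pairwise A/B coefficients follow from
    Lorentz-Berthelot combination.  ``charges`` are per atom *label*.
    """

    bond_terms: dict[BondType, tuple[float, float]] = field(default_factory=dict)
    angle_terms: dict[AngleType, tuple[float, float]] = field(default_factory=dict)
    torsion_terms: dict[DihedralType, list[FourierTerm]] = field(default_factory=dict)
    lj_terms: dict[str, tuple[float, float]] = field(default_factory=dict)
    charges: dict[str, float] = field(default_factory=dict)
    scee: float = 1.0
    scnb: float = 1.0
    dielectric: float = 1.0
    masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        for t, terms in self.torsion_terms.items():
            cleaned = []
            for n, v, g in terms:
                if not 1 <= int(n) <= 6:
                    raise ValueError(f"torsion periodicity {n} outside 1..6 for {t}")
                cleaned.append((int(n), float(v), _wrap_degrees(g)))
            self.torsion_terms[t] = cleaned

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            bond_terms=dict(self.bond_terms),
            angle_terms=dict(self.angle_terms),
            torsion_terms={k: list(v) for k, v in self.torsion_terms.items()},
            lj_terms=dict(self.lj_terms),
            charges=dict(self.charges),
            scee=self.scee,
            scnb=self.scnb,
            dielectric=self.dielectric,
            masses=dict(self.masses),
        )

    def lj_ab(self, type_i: str, type_j: str) -> tuple[float, float]:
        """Pairwise A12/B6 coefficients by Lorentz-Berthelot combination."""
        ri, ei = self.lj_terms[type_i]
        rj, ej = self.lj_terms[type_j]
        rmin = ri + rj
        eps = math.sqrt(ei * ej)
        if eps == 0.0 or rmin == 0.0:
            return 0.0, 0.0
        return eps * rmin**12, 2.0 * eps * rmin**6

    def validate_against(self, topology: Topology) -> None:
        """Raise KeyError naming the first topology term type not covered."""
        for b in topology.bonds:
            t = topology.bond_type(b)
            if t not in self.bond_terms:
                raise KeyError(f"missing bond parameters for type {'-'.join(t)}")
        for a in topology.angles:
            t = topology.angle_type(a)
            if t not in self.angle_terms:
                raise KeyError(f"missing angle parameters for type {'-'.join(t)}")
        for d in topology.dihedrals:
            t = topology.dihedral_type(d)
            if t not in self.torsion_terms:
                raise KeyError(f"missing torsion parameters for type {'-'.join(t)}")
        for atom in topology.atoms:
            if atom.atom_type not in self.lj_terms:
                raise KeyError(f"missing Lennard-Jones parameters for type {atom.atom_type}")
            if atom.label not in self.charges:
                raise KeyError(f"missing charge for atom {atom.label}")

    def charge_vector(self, topology: Topology) -> np.ndarray:
        return np.array([self.charges[a.label] for a in topology.atoms], dtype=float)


@dataclass
class Conformer:
    id: str
    coordinates: np.ndarray  # (N, 3) Angstrom
    qm_energy: float | None = None
    charges: np.ndarray | None = None  # per-atom, elementary charge


@dataclass
class ConformerSet:
    """Structures with optional reference energies and charge sets."""

    conformers: list[Conformer]
    topology: Topology

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    def __iter__(self):
        return iter(self.conformers)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conformers]

    def coordinates_array(self) -> np.ndarray:
        return np.stack([c.coordinates for c in self.conformers])

    def energies(self) -> np.ndarray:
        if any(c.qm_energy is None for c in self.conformers):
            raise ValueError("not every conformer carries a reference energy")
        return np.array([c.qm_energy for c in self.conformers], dtype=float)

    @property
    def reference_index(self) -> int:
        """Row of the minimum reference energy (lowest index on ties)."""
        e = self.energies()
        return int(np.argmin(e))

    def subset(self, indices: Sequence[int]) -> "ConformerSet":
        return ConformerSet([self.conformers[i] for i in indices], self.topology)

    def validate(self) -> None:
        n = self.topology.n_atoms
        for c in self.conformers:
            if c.coordinates.shape != (n, 3):
                raise ValueError(
                    f"conformer {c.id}: coordinate shape {c.coordinates.shape}, expected {(n, 3)}"
                )


# ---------------------------------------------------------------------------
# frcmod

_SECTIONS = ("MASS", "BOND", "ANGLE", "DIHE", "NONBON", "IMPROPER")


def _split_type(word: str, n: int) -> tuple[str, ...]:
    parts = [p.strip() for p in word.split("-")]
    if len(parts) != n:
        raise ValueError(f"expected {n} hyphen-separated atom types in {word!r}")
    return tuple(parts)


def read_frcmod(text: str) -> ParameterSet:
    """Parse an AMBER frcmod document into a (partial) ParameterSet.

    Negative-periodicity DIHE continuation lines are merged into one
    Fourier list per dihedral type; the divider column is applied as
    written (V = PK / IDIVF).  Duplicate terms: last wins with a warning.
    Charges and scee/scnb do not appear in frcmod and are left at their
    defaults.
    """
    ps = ParameterSet()
    section = None
    open_dihe: DihedralType | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if lineno == 1 and line.strip() and line.strip() not in _SECTIONS:
            continue  # title line
        stripped = line.strip()
        if not stripped:
            section = None
            open_dihe = None
            continue
        if stripped in _SECTIONS:
            section = stripped
            open_dihe = None
            continue
        if section is None:
            raise ValueError(f"line {lineno}: content outside a known section: {raw!r}")
        if section == "MASS":
            parts = stripped.split()
            ps.masses[parts[0]] = float(parts[1])
        elif section == "BOND":
            tok = stripped.split()
            t = _split_type(tok[0], 2)
            rest = tok[1:]
            key = t if t <= t[::-1] else t[::-1]
            if key in ps.bond_terms:
                warnings.warn(f"duplicate bond type {key}; last definition wins")
            ps.bond_terms[key] = (float(rest[0]), float(rest[1]))
        elif section == "ANGLE":
            tok = stripped.split()
            t = _split_type(tok[0], 3)
            rest = tok[1:]
            key = t if t <= t[::-1] else t[::-1]
            if key in ps.angle_terms:
                warnings.warn(f"duplicate angle type {key}; last definition wins")
            ps.angle_terms[key] = (float(rest[0]), float(rest[1]))
        elif section == "DIHE":
            tok = stripped.split()
            t = _split_type(tok[0], 4)
            rest = tok[1:]
            key = t if t <= t[::-1] else t[::-1]
            idivf, pk, phase, pn = float(rest[0]), float(rest[1]), float(rest[2]), float(rest[3])
            term = (int(abs(pn)), pk / idivf, _wrap_degrees(phase))
            if open_dihe == key:
                ps.torsion_terms[key].append(term)
            else:
                if key in ps.torsion_terms:
                    warnings.warn(f"duplicate dihedral type {key}; last definition wins")
                ps.torsion_terms[key] = [term]
            open_dihe = key if pn < 0 else None
        elif section == "NONBON":
            parts = stripped.split()
            ps.lj_terms[parts[0]] = (float(parts[1]), float(parts[2]))
        elif section == "IMPROPER":
            warnings.warn("IMPROPER section ignored (no improper torsions in this model)")
    return ps


def write_frcmod(ps: ParameterSet, title: str = "parameter modifications") -> str:
    """Emit a normalized frcmod document (divider written as 1)."""
    out = [title, "MASS"]
    for t in sorted(ps.masses):
        out.append(f"{t:<2s}  {ps.masses[t]:8.3f}")
    out.append("")
    out.append("BOND")
    for t in sorted(ps.bond_terms):
        kb, r0 = ps.bond_terms[t]
        out.append(f"{'-'.join(t):<7s}{kb:9.3f}  {r0:7.4f}")
    out.append("")
    out.append("ANGLE")
    for t in sorted(ps.angle_terms):
        kt, t0 = ps.angle_terms[t]
        out.append(f"{'-'.join(t):<10s}{kt:9.3f}  {t0:8.3f}")
    out.append("")
    out.append("DIHE")
    for t in sorted(ps.torsion_terms):
        terms = ps.torsion_terms[t]
        for k, (n, v, g) in enumerate(terms):
            pn = n if k == len(terms) - 1 else -n
            out.append(
                f"{'-'.join(t):<13s}  1  {v:10.5f}  {g:8.3f}  {pn:4d}."
            )
    out.append("")
    out.append("NONBON")
    for t in sorted(ps.lj_terms):
        rm, eps = ps.lj_terms[t]
        out.append(f"  {t:<2s}  {rm:8.4f}  {eps:8.4f}")
    out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# prep (charge/atom-type table only)


def read_prep_charges(text: str) -> tuple[dict[str, float], dict[str, str]]:
    """Extract label -> charge and label -> atom type from a prep table.

    Only the main atom table is consumed; the internal-coordinate geometry
    columns are ignored (geometry always comes from coordinate files).
    Table rows are recognized as lines whose first field is an integer
    index >= 4 (prep convention: the first three entries are dummies,
    which are skipped here if present).
    """
    charges: dict[str, float] = {}
    types: dict[str, str] = {}
    for raw in text.splitlines():
        parts = raw.split()
        if len(parts) < 5:
            continue
        try:
            idx = int(parts[0])
            q = float(parts[-1])
        except ValueError:
            continue
        label, atype = parts[1], parts[2]
        if label.upper() == "DUMM" or atype == "DU":
            continue
        if idx < 1:
            continue
        charges[label] = q
        types[label] = atype
    return charges, types


def write_prep(topology: Topology, charges: dict[str, float], residue: str = "0GB") -> str:
    """Write a minimal prep-style charge table for the topology."""
    out = [f"{residue} charges", f"{residue:<4s} INT 0"]
    for i, atom in enumerate(topology.atoms, start=4):
        q = charges.get(atom.label, 0.0)
        out.append(f"{i:4d}  {atom.label:<4s} {atom.atom_type:<3s} M  0 0 0  0.0 0.0 0.0 {q:9.4f}")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# coordinates


def _read_xyz(path: str) -> np.ndarray:
    with open(path) as fh:
        lines = fh.read().strip().splitlines()
    n = int(lines[0].split()[0])
    if len(lines) < n + 2:
        raise ValueError(f"{path}: XYZ header promises {n} atoms, file has fewer lines")
    rows = [ln.split() for ln in lines[2 : 2 + n]]
    return np.array([[float(v) for v in r[1:4]] for r in rows], dtype=float)


def _read_pdb(path: str, topology: Topology | None) -> np.ndarray:
    coords: list[tuple[str, np.ndarray]] = []
    seen_altloc = False
    taken: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            name = line[12:16].strip()
            altloc = line[16]
            if altloc not in (" ", ""):
                if name in taken:
                    seen_altloc = True
                    continue
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            if name in taken:
                continue
            taken.add(name)
            coords.append((name, xyz))
    if seen_altloc:
        warnings.warn(f"{path}: alternate locations present; kept the first occurrence")
    arr = np.array([c for _, c in coords], dtype=float)
    if topology is not None:
        labels = [n for n, _ in coords]
        if len(labels) != topology.n_atoms:
            raise ValueError(
                f"{path}: {len(labels)} atoms, topology expects {topology.n_atoms}"
            )
        if labels != topology.labels:
            if sorted(labels) != sorted(topology.labels):
                raise ValueError(f"{path}: atom names do not match the topology labels")
            warnings.warn(f"{path}: atom order differs from topology; reordered by label")
            order = [labels.index(l) for l in topology.labels]
            arr = arr[order]
    return arr


def read_coordinates(path: str, topology: Topology | None = None) -> np.ndarray:
    """Read one structure (Angstrom) from a PDB or XYZ file."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".xyz":
        arr = _read_xyz(path)
        if topology is not None and arr.shape[0] != topology.n_atoms:
            raise ValueError(
                f"{path}: {arr.shape[0]} atoms, topology expects {topology.n_atoms}"
            )
        return arr
    if ext == ".pdb":
        return _read_pdb(path, topology)
    raise ValueError(f"{path}: unsupported coordinate format {ext!r}")


def write_xyz(path: str, coordinates: np.ndarray, topology: Topology, comment: str = "") -> None:
    lines = [str(topology.n_atoms), comment]
    for atom, (x, y, z) in zip(topology.atoms, coordinates):
        lines.append(f"{atom.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dataset manifest


def read_manifest(path: str, topology: Topology) -> ConformerSet:
    """Read a conformer-dataset manifest (CSV).

    Columns: ``id``, ``xyz`` (coordinate file path, relative to the
    manifest), optional ``qm_energy`` (kcal/mol) and optional per-atom
    charge columns named ``q_<label>``.  The reference structure is the
    row with the minimum ``qm_energy`` (lowest row index on ties).
    """
    df = pd.read_csv(path)
    base = os.path.dirname(os.path.abspath(path))
    qcols = [c for c in df.columns if c.startswith("q_")]
    conformers = []
    for _, row in df.iterrows():
        fpath = row["xyz"]
        if not os.path.isabs(fpath):
            fpath = os.path.join(base, fpath)
        if not os.path.exists(fpath):
            raise FileNotFoundError(f"manifest references missing coordinate file {fpath}")
        coords = read_coordinates(fpath, topology)
        energy = None
        if "qm_energy" in df.columns and pd.notna(row["qm_energy"]):
            energy = float(row["qm_energy"])
        charges = None
        if qcols and all(pd.notna(row[c]) for c in qcols):
            qmap = {c[2:]: float(row[c]) for c in qcols}
            charges = np.array([qmap.get(a.label, 0.0) for a in topology.atoms])
        conformers.append(Conformer(str(row["id"]), coords, energy, charges))
    cs = ConformerSet(conformers, topology)
    cs.validate()
    return cs


def write_manifest(cs: ConformerSet, directory: str) -> str:
    """Write per-structure XYZ files plus ``manifest.csv``; returns its path."""
    os.makedirs(os.path.join(directory, "structures"), exist_ok=True)
    rows = []
    opt = [cs.topology.atoms[i].label for i in cs.topology.optimizable_atoms]
    has_charges = any(c.charges is not None for c in cs.conformers)
    for c in cs.conformers:
        rel = os.path.join("structures", f"{c.id}.xyz")
        write_xyz(os.path.join(directory, rel), c.coordinates, cs.topology, c.id)
        row: dict[str, object] = {"id": c.id, "xyz": rel, "qm_energy": c.qm_energy}
        if has_charges:
            for i, atom in enumerate(cs.topology.atoms):
                if atom.label in opt:
                    row[f"q_{atom.label}"] = (
                        c.charges[i] if c.charges is not None else np.nan
                    )
        rows.append(row)
    path = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# full-fidelity parameter serialization (YAML)


def parameters_to_dict(ps: ParameterSet) -> dict:
    """Plain-dict form of a ParameterSet (YAML/JSON friendly)."""
    return {
        "bond_terms": {"-".join(k): list(v) for k, v in ps.bond_terms.items()},
        "angle_terms": {"-".join(k): list(v) for k, v in ps.angle_terms.items()},
        "torsion_terms": {
            "-".join(k): [[n, v, g] for n, v, g in terms]
            for k, terms in ps.torsion_terms.items()
        },
        "lj_terms": {k: list(v) for k, v in ps.lj_terms.items()},
        "charges": dict(ps.charges),
        "scee": ps.scee,
        "scnb": ps.scnb,
        "dielectric": ps.dielectric,
        "masses": dict(ps.masses),
    }


def parameters_from_dict(d: dict) -> ParameterSet:
    return ParameterSet(
        bond_terms={tuple(k.split("-")): tuple(v) for k, v in d.get("bond_terms", {}).items()},
        angle_terms={tuple(k.split("-")): tuple(v) for k, v in d.get("angle_terms", {}).items()},
        torsion_terms={
            tuple(k.split("-")): [(int(n), float(v), float(g)) for n, v, g in terms]
            for k, terms in d.get("torsion_terms", {}).items()
        },
        lj_terms={k: tuple(v) for k, v in d.get("lj_terms", {}).items()},
        charges=dict(d.get("charges", {})),
        scee=float(d.get("scee", 1.0)),
        scnb=float(d.get("scnb", 1.0)),
        dielectric=float(d.get("dielectric", 1.0)),
        masses=dict(d.get("masses", {})),
    )


# ---------------------------------------------------------------------------
# shipped starting parameters (GLYCAM06-role fixture)

_BOND_TABLE: dict[BondType, tuple[float, float]] = {
    ("Cg", "Cg"): (310.0, 1.520),
    ("Cg", "Os"): (285.0, 1.460),
    ("Cg", "Oh"): (320.0, 1.430),
    ("Cg", "H1"): (340.0, 1.092),
    ("Ho", "Oh"): (553.0, 0.960),
}

_ANGLE_TABLE: dict[AngleType, tuple[float, float]] = {
    ("Cg", "Cg", "Cg"): (45.0, 113.5),
    ("Cg", "Cg", "Os"): (70.0, 108.5),
    ("Cg", "Os", "Cg"): (50.0, 113.0),
    ("Cg", "Cg", "Oh"): (70.0, 109.5),
    ("Cg", "Cg", "H1"): (45.0, 111.0),
    ("H1", "Cg", "H1"): (40.0, 109.5),
    ("Oh", "Cg", "Os"): (75.0, 109.0),
    ("H1", "Cg", "Oh"): (60.0, 110.0),
    ("H1", "Cg", "Os"): (60.0, 110.0),
    ("Cg", "Oh", "Ho"): (55.0, 109.5),
}

_TORSION_TABLE: dict[DihedralType, list[FourierTerm]] = {
    ("Cg", "Cg", "Cg", "Cg"): [(3, 0.45, 0.0)],
    ("Cg", "Cg", "Cg", "Oh"): [(1, 0.20, 180.0), (3, 0.30, 0.0)],
    ("Cg", "Cg", "Cg", "Os"): [(1, 0.25, 180.0), (3, 0.25, 0.0)],
    ("Cg", "Cg", "Cg", "H1"): [(3, 0.16, 0.0)],
    ("Oh", "Cg", "Cg", "Oh"): [(2, 0.30, 0.0), (3, 0.20, 0.0)],
    ("Oh", "Cg", "Cg", "Os"): [(1, 0.35, 180.0), (3, 0.25, 0.0)],
    ("H1", "Cg", "Cg", "Oh"): [(3, 0.15, 0.0)],
    ("H1", "Cg", "Cg", "Os"): [(3, 0.15, 0.0)],
    ("H1", "Cg", "Cg", "H1"): [(3, 0.17, 0.0)],
    ("Cg", "Cg", "Os", "Cg"): [(1, 0.40, 180.0), (2, 0.55, 0.0), (3, 0.25, 0.0)],
    ("Cg", "Os", "Cg", "Oh"): [(1, 0.60, 180.0), (2, 0.95, 0.0)],
    ("Cg", "Os", "Cg", "H1"): [(3, 0.27, 0.0)],
    ("Cg", "Cg", "Oh", "Ho"): [(1, 0.25, 0.0), (3, 0.18, 0.0)],
    ("H1", "Cg", "Oh", "Ho"): [(3, 0.16, 0.0)],
    ("Ho", "Oh", "Cg", "Os"): [(1, 0.45, 0.0), (3, 0.20, 0.0)],
}

_LJ_TABLE: dict[str, tuple[float, float]] = {
    "Cg": (1.9080, 0.1094),
    "Os": (1.6837, 0.1700),
    "Oh": (1.7210, 0.2104),
    "H1": (1.3870, 0.0157),
    "Ho": (0.0000, 0.0000),
}

_CHARGE_TABLE: dict[str, float] = {
    "C1": 0.509, "C2": 0.246, "C3": 0.286, "C4": 0.254, "C5": 0.283, "C6": 0.277,
    "O1": -0.639, "O2": -0.713, "O3": -0.699, "O4": -0.710, "O5": -0.574, "O6": -0.682,
    "HO1": 0.445, "HO2": 0.427, "HO3": 0.427, "HO4": 0.436, "HO6": 0.427,
    "H1": 0.0, "H2": 0.0, "H3": 0.0, "H4": 0.0, "H5": 0.0, "H61": 0.0, "H62": 0.0,
}

_MASS_TABLE = {"Cg": 12.01, "Os": 16.00, "Oh": 16.00, "H1": 1.008, "Ho": 1.008}


def glucose_parameters() -> ParameterSet:
    """The shipped starting parameter set for the glucose template.

    A synthetic GLYCAM06-style fixture: AMBER-typical bond, angle and
    Lennard-Jones constants, small torsion Fourier series, a neutral
    ensemble-style charge set with aliphatic hydrogens at zero, and
    unscaled 1-4 interactions (scee = scnb = 1, the GLYCAM convention).
    It plays the role of the reference parameter set that fitting is
    penalized toward.
    """
    return ParameterSet(
        bond_terms=dict(_BOND_TABLE),
        angle_terms=dict(_ANGLE_TABLE),
        torsion_terms={k: list(v) for k, v in _TORSION_TABLE.items()},
        lj_terms=dict(_LJ_TABLE),
        charges=dict(_CHARGE_TABLE),
        scee=1.0,
        scnb=1.0,
        dielectric=1.0,
        masses=dict(_MASS_TABLE),
    )
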