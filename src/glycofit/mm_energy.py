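"""AMBER-form molecular-mechanics energy and the relative energy error.

The potential is the standard AMBER functional form: harmonic bonds and
angles, a torsion Fourier series with periodicities 1..6, and pairwise
Lennard-Jones plus Coulomb interactions.  Pairs separated by one or two
bonds are excluded; 1-4 pairs are scaled by 1/scnb (van der Waals) and
1/scee (electrostatics); everything further apart interacts fully.  No
distance cutoff is applied: the engine targets a single molecule in
vacuum, matching the quantum-chemical reference energies the parameters
are fitted to.

The relative energy error (REE) of a structure s against a reference
structure is

    REE(s) = (E_ref,s - E_ref,refstruct) - (E_MM,s - E_MM,refstruct)

so an exact force field gives REE = 0 for every structure regardless of
the absolute energy offsets of either method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .forcefield_io import ConformerSet, FourierTerm, ParameterSet
from .molecule_model import Topology

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "REEResult",
    "torsion_energy",
    "coulomb",
    "coulomb_14",
    "lj",
    "lj_14",
    "total_energy",
    "relative_energy_error",
]

#: Electrostatic conversion constant in kcal*Angstrom/(mol*e^2), AMBER convention.
COULOMB_CONSTANT = 332.0522173


@dataclass
class EnergyBreakdown:
    """Per-term decomposition of one structure's MM energy (kcal/mol)."""

    bond: float = 0.0
    angle: float = 0.0
    torsion: float = 0.0
    lj_14: float = 0.0
    coulomb_14: float = 0.0
    lj_nb: float = 0.0
    coulomb_nb: float = 0.0
    per_dihedral_type: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    per_atom_coulomb: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return (
            self.bond
            + self.angle
            + self.torsion
            + self.lj_14
            + self.coulomb_14
            + self.lj_nb
            + self.coulomb_nb
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "torsion": self.torsion,
            "lj_14": self.lj_14,
            "coulomb_14": self.coulomb_14,
            "lj_nb": self.lj_nb,
            "coulomb_nb": self.coulomb_nb,
            "total": self.total,
        }


def torsion_energy(phi: float, fourier: list[FourierTerm]) -> float:
    """Fourier torsion energy sum_n V_n (1 + cos(n*phi - gamma_n)).

    ``phi`` in radians; the phases in ``fourier`` are in degrees, as
    stored in parameter files.
    """
    e = 0.0
    for n, v, gamma_deg in fourier:
        if not 1 <= n <= 6:
            raise ValueError(f"torsion periodicity {n} outside 1..6")
        e += v * (1.0 + math.cos(n * phi - math.radians(gamma_deg)))
    return e


def coulomb(qi: float, qj: float, r: float, dielectric: float = 1.0) -> float:
    """Point-charge Coulomb energy k_C qi qj / (eps r) in kcal/mol."""
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    return COULOMB_CONSTANT * qi * qj / (dielectric * r)


def coulomb_14(qi: float, qj: float, r: float, scee: float, dielectric: float = 1.0) -> float:
    """1-4 Coulomb interaction, scaled by 1/scee."""
    return coulomb(qi, qj, r, dielectric) / scee


def lj(a: float, b: float, r: float) -> float:
    """12-6 Lennard-Jones energy A/r^12 - B/r^6 in kcal/mol."""
    if r <= 0:
        raise ValueError("interatomic distance must be positive")
    r6 = r**6
    return a / (r6 * r6) - b / r6


def lj_14(a: float, b: float, r: float, scnb: float) -> float:
    """1-4 van der Waals interaction, scaled by 1/scnb."""
    return lj(a, b, r) / scnb


def total_energy(
    topology: Topology, parameters: ParameterSet, coordinates: np.ndarray
) -> EnergyBreakdown:
    """Evaluate the full AMBER-form energy of one structure.

    Raises ``KeyError`` naming the first topology term type without a
    parameter entry.
    """
    parameters.validate_against(topology)
    bd = EnergyBreakdown()
    coords = np.asarray(coordinates, dtype=float)

    for b in topology.bonds:
        kb, r0 = parameters.bond_terms[topology.bond_type(b)]
        r = geometry.bond_length(coords, *b)
        bd.bond += kb * (r - r0) ** 2

    for a in topology.angles:
        kt, t0 = parameters.angle_terms[topology.angle_type(a)]
        theta = geometry.bond_angle(coords, *a)
        bd.angle += kt * (theta - math.radians(t0)) ** 2

    for d in topology.dihedrals:
        dtype = topology.dihedral_type(d)
        phi = geometry.dihedral_angle(coords, *d)
        e = torsion_energy(phi, parameters.torsion_terms[dtype])
        bd.torsion += e
        bd.per_dihedral_type[dtype] = bd.per_dihedral_type.get(dtype, 0.0) + e

    q = parameters.charge_vector(topology)
    eps = parameters.dielectric
    per_atom = np.zeros(topology.n_atoms)
    for (i, j), cls in topology.pair_class.items():
        if cls in ("12", "13"):
            continue
        r = geometry.bond_length(coords, i, j)
        ti, tj = topology.atoms[i].atom_type, topology.atoms[j].atom_type
        a_ij, b_ij = parameters.lj_ab(ti, tj)
        if cls == "14":
            bd.lj_14 += lj_14(a_ij, b_ij, r, parameters.scnb)
            ec = coulomb_14(q[i], q[j], r, parameters.scee, eps)
            bd.coulomb_14 += ec
        else:
            bd.lj_nb += lj(a_ij, b_ij, r)
            ec = coulomb(q[i], q[j], r, eps)
            bd.coulomb_nb += ec
        # half of each pair energy attributed to each participating atom
        per_atom[i] += 0.5 * ec
        per_atom[j] += 0.5 * ec

    bd.per_atom_coulomb = {
        topology.atoms[i].label: float(per_atom[i]) for i in range(topology.n_atoms)
    }
    return bd


@dataclass
class REEResult:
    """Per-structure relative energy errors plus summary statistics."""

    ree: np.ndarray  # signed, kcal/mol, one entry per structure
    reference_index: int
    ids: list[str]

    @property
    def mean(self) -> float:
        """Signed mean REE."""
        return float(np.mean(self.ree))

    @property
    def mean_abs(self) -> float:
        return float(np.mean(np.abs(self.ree)))

    @property
    def sd(self) -> float:
        return float(np.std(self.ree))


def relative_energy_error(
    conformer_set: ConformerSet,
    parameters: ParameterSet,
    reference_index: int | None = None,
) -> REEResult:
    """Signed REE for every structure against the designated reference.

    The reference defaults to the structure with the lowest reference
    (QM-role) energy.  Every structure, including the reference, must
    carry a reference energy.
    """
    topology = conformer_set.topology
    e_qm = conformer_set.energies()
    ref = conformer_set.reference_index if reference_index is None else reference_index
    e_mm = np.array(
        [total_energy(topology, parameters, c.coordinates).total for c in conformer_set]
    )
    ree = (e_qm - e_qm[ref]) - (e_mm - e_mm[ref])
    return REEResult(ree=ree, reference_index=ref, ids=conformer_set.ids)
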