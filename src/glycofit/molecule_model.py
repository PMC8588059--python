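"""Molecular topology for a single small molecule.

A :class:`Topology` holds the atoms and bonds of one molecule and derives
everything the AMBER-style energy function needs: the angle triples, the
dihedral quadruples, and the classification of every atom pair as 1-2,
1-3, 1-4 or non-bonded.  Pair classes are assigned by the *shortest*
bond-path distance, so the classes partition the set of all pairs and a
ring pair can never be simultaneously excluded and scaled.

The package ships the 24-atom beta-D-glucopyranose topology (4C1 chair)
with the GLYCAM-style atom labels C1..C6, O1..O6, H1..H5, H61, H62 and
the hydroxyl hydrogens HO1..HO4, HO6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "build_connectivity",
    "glucose_template",
    "glucose_geometry",
    "canonical_bond_type",
    "canonical_angle_type",
    "canonical_dihedral_type",
]


@dataclass(frozen=True)
class Atom:
    """One atom: a unique label, element symbol and force-field type."""

    label: str
    element: str
    atom_type: str
    is_aliphatic_hydrogen: bool = False


def canonical_bond_type(a: str, b: str) -> tuple[str, str]:
    return (a, b) if (a,) <= (b,) else (b, a)


def canonical_angle_type(a: str, b: str, c: str) -> tuple[str, str, str]:
    return (a, b, c) if (a,) <= (c,) else (c, b, a)


def canonical_dihedral_type(a: str, b: str, c: str, d: str) -> tuple[str, str, str, str]:
    fwd, rev = (a, b, c, d), (d, c, b, a)
    return fwd if fwd <= rev else rev


@dataclass
class Topology:
    """Atoms, bonds and all derived bonded/non-bonded term structure."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    pair_class: dict[tuple[int, int], str] = field(default_factory=dict)
    is_connected: bool = True

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.atoms]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no atom labelled {label!r}") from None

    @property
    def optimizable_atoms(self) -> list[int]:
        """Indices of atoms whose charge is free during fitting.

        Aliphatic hydrogens carry a fixed zero charge (GLYCAM convention)
        and are excluded; for glucose this leaves 17 atoms.
        """
        return [i for i, a in enumerate(self.atoms) if not a.is_aliphatic_hydrogen]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.bonds)
        return g

    def rings(self) -> list[list[int]]:
        """Minimum cycle basis of the bond graph, each ring in bond order."""
        return [list(c) for c in nx.cycle_basis(self.graph())]

    def ring_bonds(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for ring in self.rings():
            n = len(ring)
            for k in range(n):
                i, j = ring[k], ring[(k + 1) % n]
                out.add((min(i, j), max(i, j)))
        return out

    def bond_type(self, bond: tuple[int, int]) -> tuple[str, str]:
        i, j = bond
        return canonical_bond_type(self.atoms[i].atom_type, self.atoms[j].atom_type)

    def angle_type(self, angle: tuple[int, int, int]) -> tuple[str, str, str]:
        i, j, k = angle
        t = [self.atoms[x].atom_type for x in (i, j, k)]
        return canonical_angle_type(*t)

    def dihedral_type(self, dih: tuple[int, int, int, int]) -> tuple[str, str, str, str]:
        t = [self.atoms[x].atom_type for x in dih]
        return canonical_dihedral_type(*t)

    def dihedral_types(self) -> list[tuple[str, str, str, str]]:
        """Sorted unique dihedral types present in the topology."""
        return sorted({self.dihedral_type(d) for d in self.dihedrals})

    def pairs_of_class(self, cls: str) -> list[tuple[int, int]]:
        return sorted(p for p, c in self.pair_class.items() if c == cls)


def build_connectivity(atoms: Sequence[Atom], bonds: Iterable[tuple[int, int]]) -> Topology:
    """Derive angles, dihedrals and pair classes from atoms and bonds.

    Angles are every pair of bonds sharing a middle atom; dihedrals every
    chain of three bonds, enumerated per quadruple (no AMBER divider).
    Derived terms are canonically ordered so that output is reproducible.

    Raises ``ValueError`` on duplicate labels, self-bonds, duplicate bonds
    or out-of-range indices.  A disconnected bond graph only sets
    ``is_connected = False``.
    """
    atoms = list(atoms)
    n = len(atoms)
    labels = [a.label for a in atoms]
    if len(set(labels)) != n:
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate atom labels: {dupes}")

    norm_bonds: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in bonds:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"bond ({i}, {j}) references a missing atom")
        if i == j:
            raise ValueError(f"self-bond on atom index {i}")
        b = (min(i, j), max(i, j))
        if b in seen:
            raise ValueError(f"duplicate bond {b}")
        seen.add(b)
        norm_bonds.append(b)
    norm_bonds.sort()

    # hydrogens bonded to a single carbon neighbour are "aliphatic"
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in norm_bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)
    flagged = []
    for idx, a in enumerate(atoms):
        aliph = (
            a.element == "H"
            and len(nbrs[idx]) == 1
            and atoms[next(iter(nbrs[idx]))].element == "C"
        )
        flagged.append(Atom(a.label, a.element, a.atom_type, aliph))

    angles = []
    for j in range(n):
        ns = sorted(nbrs[j])
        for ai in range(len(ns)):
            for ak in range(ai + 1, len(ns)):
                angles.append((ns[ai], j, ns[ak]))
    angles.sort()

    dihedrals = []
    for j, k in norm_bonds:
        for i in sorted(nbrs[j] - {k}):
            for l in sorted(nbrs[k] - {j}):
                if i == l:
                    continue  # three-membered ring chain folds back
                fwd, rev = (i, j, k, l), (l, k, j, i)
                dihedrals.append(fwd if fwd <= rev else rev)
    dihedrals = sorted(set(dihedrals))

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(norm_bonds)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    pair_class: dict[tuple[int, int], str] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dist.get(i, {}).get(j)
            if d == 1:
                pair_class[(i, j)] = "12"
            elif d == 2:
                pair_class[(i, j)] = "13"
            elif d == 3:
                pair_class[(i, j)] = "14"
            else:
                pair_class[(i, j)] = "nonbonded"

    return Topology(
        atoms=flagged,
        bonds=norm_bonds,
        angles=angles,
        dihedrals=dihedrals,
        pair_class=pair_class,
        is_connected=nx.is_connected(g) if n else True,
    )


# beta-D-glucopyranose: ring O5-C1-C2-C3-C4-C5, hydroxyls at C1..C4 and C6,
# hydroxymethyl C6 on C5.  24 atoms, 24 bonds, one ring.
_GLUCOSE_ATOMS: list[tuple[str, str, str]] = [
    ("C1", "C", "Cg"),
    ("C2", "C", "Cg"),
    ("C3", "C", "Cg"),
    ("C4", "C", "Cg"),
    ("C5", "C", "Cg"),
    ("C6", "C", "Cg"),
    ("O1", "O", "Oh"),
    ("O2", "O", "Oh"),
    ("O3", "O", "Oh"),
    ("O4", "O", "Oh"),
    ("O5", "O", "Os"),
    ("O6", "O", "Oh"),
    ("H1", "H", "H1"),
    ("H2", "H", "H1"),
    ("H3", "H", "H1"),
    ("H4", "H", "H1"),
    ("H5", "H", "H1"),
    ("H61", "H", "H1"),
    ("H62", "H", "H1"),
    ("HO1", "H", "Ho"),
    ("HO2", "H", "Ho"),
    ("HO3", "H", "Ho"),
    ("HO4", "H", "Ho"),
    ("HO6", "H", "Ho"),
]

_GLUCOSE_BONDS: list[tuple[str, str]] = [
    # pyranose ring
    ("O5", "C1"),
    ("C1", "C2"),
    ("C2", "C3"),
    ("C3", "C4"),
    ("C4", "C5"),
    ("C5", "O5"),
    # exocyclic heavy atoms
    ("C1", "O1"),
    ("C2", "O2"),
    ("C3", "O3"),
    ("C4", "O4"),
    ("C5", "C6"),
    ("C6", "O6"),
    # hydroxyl hydrogens
    ("O1", "HO1"),
    ("O2", "HO2"),
    ("O3", "HO3"),
    ("O4", "HO4"),
    ("O6", "HO6"),
    # aliphatic hydrogens
    ("C1", "H1"),
    ("C2", "H2"),
    ("C3", "H3"),
    ("C4", "H4"),
    ("C5", "H5"),
    ("C6", "H61"),
    ("C6", "H62"),
]

#: Ring atoms in the conventional order used for puckering analysis.
GLUCOSE_RING_ORDER = ["O5", "C1", "C2", "C3", "C4", "C5"]


def glucose_template() -> Topology:
    """The beta-D-glucopyranose topology with GLYCAM-style atom labels.

    24 atoms and 24 bonds (one ring); the 7 aliphatic hydrogens are
    flagged, leaving 17 charge-optimizable atoms.
    """
    atoms = [Atom(l, e, t) for l, e, t in _GLUCOSE_ATOMS]
    lab = {a.label: i for i, a in enumerate(atoms)}
    bonds = [(lab[a], lab[b]) for a, b in _GLUCOSE_BONDS]
    return build_connectivity(atoms, bonds)


def glucose_geometry() -> np.ndarray:
    """4C1-chair Cartesian coordinates (Angstrom) for the template.

    The geometry is a synthetic fixture: an energy-minimized conformer
    built once with a cheminformatics toolkit and frozen as package data,
    in the same atom order as :func:`glucose_template`.
    """
    text = resources.files("glycofit.data").joinpath("glucose_4c1.xyz").read_text()
    lines = text.strip().splitlines()
    n = int(lines[0].split()[0])
    coords = np.array(
        [[float(v) for v in ln.split()[1:4]] for ln in lines[2 : 2 + n]], dtype=float
    )
    return coords
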