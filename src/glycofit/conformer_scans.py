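"""Deformation scans and conformational analysis for pyranose rings.

Three kinds of deformation series are generated for validating fitted
parameters against reference energy curves: rotation about the C5-C6
(hydroxymethyl) bond, rotation about the O1-C1 (anomeric hydroxyl) bond,
and a single-parameter ring-flip coordinate that bends the anomeric
carbon out of the ring plane.  Analysis utilities classify C5-C6
hydroxymethyl rotamers (gg/gt/tg), estimate rotamer populations, and
compute Cremer-Pople ring-puckering parameters.
"""

from __future__ import annotations

import numpy as np

from . import geometry
from .forcefield_io import Conformer, ConformerSet
from .molecule_model import GLUCOSE_RING_ORDER, Topology

__all__ = [
    "set_dihedral",
    "measure_dihedral",
    "make_rotation_scan",
    "bend_ring_atom",
    "make_ring_flip_scan",
    "classify_rotamer",
    "rotamer_populations",
    "cremer_pople",
]


def _resolve(topology: Topology, labels) -> tuple[int, ...]:
    return tuple(l if isinstance(l, int) else topology.index(l) for l in labels)


def measure_dihedral(topology: Topology, coords: np.ndarray, labels) -> float:
    """Torsion angle of four labelled atoms, in degrees in (-180, 180]."""
    i, j, k, l = _resolve(topology, labels)
    return float(np.degrees(geometry.dihedral_angle(coords, i, j, k, l)))


def _moving_side(topology: Topology, j: int, k: int) -> list[int]:
    """Atoms on the k-side after cutting bond (j, k); error for ring bonds."""
    g = topology.graph()
    g.remove_edge(j, k)
    import networkx as nx

    comp = nx.node_connected_component(g, k)
    if j in comp:
        raise ValueError(
            f"bond {topology.atoms[j].label}-{topology.atoms[k].label} is in a ring; "
            "rotating it would tear the ring"
        )
    return sorted(comp - {k})


def set_dihedral(
    topology: Topology, coordinates: np.ndarray, labels, target_deg: float
) -> np.ndarray:
    """Rigidly rotate the distal side of a bond to a target torsion.

    The atoms beyond the central bond (the side of the fourth atom) are
    rotated about the bond axis so that the measured i-j-k-l torsion
    equals ``target_deg``.  Bond lengths and angles are untouched; the
    central bond must not be part of a ring.
    """
    i, j, k, l = _resolve(topology, labels)
    coords = np.array(coordinates, dtype=float)
    current = geometry.dihedral_angle(coords, i, j, k, l)
    delta = np.radians(target_deg) - current
    moving = _moving_side(topology, j, k)
    axis = coords[k] - coords[j]
    coords[moving] = geometry.rotate_about_axis(coords[moving], coords[k], axis, delta)
    achieved = geometry.dihedral_angle(coords, i, j, k, l)
    # the sign of the rotation depends on the axis orientation; flip if needed
    err = (np.degrees(achieved) - target_deg + 180.0) % 360.0 - 180.0
    if abs(err) > 1e-6:
        coords = np.array(coordinates, dtype=float)
        coords[moving] = geometry.rotate_about_axis(coords[moving], coords[k], axis, -delta)
    return coords


def make_rotation_scan(
    conformer: Conformer,
    topology: Topology,
    dihedral_labels,
    start: float = 0.0,
    stop: float = 350.0,
    step: float = 10.0,
) -> ConformerSet:
    """One structure per grid angle of a driven torsion (default 0..350 by 10)."""
    if step <= 0:
        raise ValueError("step must be positive")
    angles = np.arange(start, stop + 1e-9 * step, step)
    name = "-".join(str(l) for l in dihedral_labels)
    out = []
    for ang in angles:
        coords = set_dihedral(topology, conformer.coordinates, dihedral_labels, float(ang))
        out.append(Conformer(f"{conformer.id}_rot_{name}_{ang:06.1f}", coords))
    return ConformerSet(out, topology)


def bend_ring_atom(
    topology: Topology, coordinates: np.ndarray, flip_atom: str, angle_deg: float
) -> np.ndarray:
    """Rotate a ring atom and its exocyclic substituents about the axis
    through its two ring neighbours by ``angle_deg``.

    This is the single-parameter "bending" coordinate that drives a ring
    atom out of the mean plane toward ring inversion; the ring
    neighbours themselves do not move.
    """
    fi = topology.index(flip_atom) if isinstance(flip_atom, str) else flip_atom
    ring = next((r for r in topology.rings() if fi in r), None)
    if ring is None:
        raise ValueError(f"{flip_atom} is not a ring atom")
    pos = ring.index(fi)
    nb1, nb2 = ring[pos - 1], ring[(pos + 1) % len(ring)]

    g = topology.graph()
    g.remove_edge(fi, nb1)
    g.remove_edge(fi, nb2)
    import networkx as nx

    moving = sorted(nx.node_connected_component(g, fi))
    coords = np.array(coordinates, dtype=float)
    axis = coords[nb2] - coords[nb1]
    coords[moving] = geometry.rotate_about_axis(
        coords[moving], coords[nb1], axis, np.radians(float(angle_deg))
    )
    return coords


def make_ring_flip_scan(
    conformer: Conformer,
    topology: Topology,
    flip_atom: str = "C1",
    start: float = -4.0,
    stop: float = 5.0,
    step: float = 1.0,
) -> ConformerSet:
    """Bend a ring atom by a grid of angles (default -4..5 by 1 degree).

    One structure per grid angle; the 0-degree structure is the input
    itself.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    angles = np.arange(start, stop + 1e-9 * step, step)
    out = []
    for ang in angles:
        coords = bend_ring_atom(topology, conformer.coordinates, flip_atom, float(ang))
        out.append(Conformer(f"{conformer.id}_flip_{flip_atom}_{ang:+05.1f}", coords))
    return ConformerSet(out, topology)


def classify_rotamer(phi_deg: float) -> str:
    """gg/gt/tg class of an O5-C5-C6-O6 torsion (degrees).

    Bins of width 120 degrees centered on the staggered orientations:
    gg at -60, gt at +60, tg at 180.
    """
    phi = (float(phi_deg) + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    if phi == -180.0:
        phi = 180.0
    if -120.0 <= phi < 0.0:
        return "gg"
    if 0.0 <= phi < 120.0:
        return "gt"
    return "tg"


def rotamer_populations(
    source: ConformerSet | np.ndarray,
    topology: Topology | None = None,
    dihedral_labels=("O5", "C5", "C6", "O6"),
    bins: int = 72,
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Rotamer class fractions and a normalized torsion density.

    ``source`` is either a conformer set (the torsion is measured on
    every structure) or an array of torsion angles in degrees.  Returns
    ``(fractions, bin_edges_deg, density_per_degree)``; the density
    integrates to 1 over the full 360-degree circle.
    """
    if isinstance(source, ConformerSet):
        topo = topology or source.topology
        phis = np.array(
            [measure_dihedral(topo, c.coordinates, dihedral_labels) for c in source]
        )
    else:
        phis = np.asarray(source, dtype=float)
    if phis.size == 0:
        raise ValueError("no structures to analyze")
    phis = (phis + 180.0) % 360.0 - 180.0
    classes = [classify_rotamer(p) for p in phis]
    fractions = {c: classes.count(c) / len(classes) for c in ("gg", "gt", "tg")}
    hist, edges = np.histogram(phis, bins=bins, range=(-180.0, 180.0), density=True)
    return fractions, edges, hist


def cremer_pople(ring_coords: np.ndarray) -> tuple[float, float, float]:
    """Cremer-Pople puckering parameters of a six-membered ring.

    ``ring_coords`` are the six ring atoms in bond order (for the
    pyranose template: O5, C1, C2, C3, C4, C5, see
    ``GLUCOSE_RING_ORDER``).  Returns ``(Q, theta_deg, phi_deg)`` with
    the total puckering amplitude Q in Angstrom and the spherical-polar
    pucker angles in degrees; a planar ring has Q = 0 (theta/phi then
    undefined, returned as 0).
    """
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise ValueError("expected six ring atoms with 3 coordinates each")
    r = r - r.mean(axis=0)
    n_ring = 6
    j = np.arange(n_ring)
    rp = (r * np.sin(2.0 * np.pi * j / n_ring)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2.0 * np.pi * j / n_ring)[:, None]).sum(axis=0)
    normal = np.cross(rp, rpp)
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise ValueError("degenerate (collinear) ring geometry")
    z = r @ (normal / norm)

    q2cos = np.sqrt(2.0 / n_ring) * (z * np.cos(4.0 * np.pi * j / n_ring)).sum()
    q2sin = -np.sqrt(2.0 / n_ring) * (z * np.sin(4.0 * np.pi * j / n_ring)).sum()
    q2 = np.hypot(q2cos, q2sin)
    q3 = np.sqrt(1.0 / n_ring) * ((-1.0) ** j * z).sum()
    big_q = float(np.sqrt(q2**2 + q3**2))
    if big_q < 1e-12:
        return 0.0, 0.0, 0.0
    theta = float(np.degrees(np.arccos(np.clip(q3 / big_q, -1.0, 1.0))))
    phi = float(np.degrees(np.arctan2(q2sin, q2cos)) % 360.0)
    return big_q, theta, phi


def ring_coordinates(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Ring atom coordinates in the conventional puckering order."""
    return coords[[topology.index(l) for l in GLUCOSE_RING_ORDER]]
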