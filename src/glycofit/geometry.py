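"""Internal Cartesian geometry helpers (Angstrom, radians)."""

from __future__ import annotations

import numpy as np


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[i] - coords[j]))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in radians."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i-j-k-l in radians, in (-pi, pi] (IUPAC convention)."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.arctan2(y, x))


def dihedral_angles_batch(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Torsions for many structures at once.

    coords: (S, N, 3); quads: (D, 4) atom indices -> (S, D) radians.
    """
    i, j, k, l = quads.T
    b1 = coords[:, j] - coords[:, i]
    b2 = coords[:, k] - coords[:, j]
    b3 = coords[:, l] - coords[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2n)
    x = (n1 * n2).sum(-1)
    y = (m * n2).sum(-1)
    return np.arctan2(y, x)


def rotate_about_axis(
    coords: np.ndarray, point: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    """Rodrigues rotation of points about a line (point, axis) by angle (rad)."""
    u = axis / np.linalg.norm(axis)
    p = coords - point
    cos, sin = np.cos(angle), np.sin(angle)
    rotated = p * cos + np.cross(u, p) * sin + np.outer(p @ u, u) * (1.0 - cos)
    return rotated + point
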