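"""Independent oracles, written separately from the package's engine.

The brute-force energy evaluator classifies pairs with its own BFS and
sums every term with explicit Python loops; it shares no code with the
vectorized engine it cross-checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(n_atoms: int, bonds) -> list[list[int]]:
    adj = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    dist = [[-1] * n_atoms for _ in range(n_atoms)]
    for s in range(n_atoms):
        dist[s][s] = 0
        dq = deque([s])
        while dq:
            u = dq.popleft()
            for v in adj[u]:
                if dist[s][v] < 0:
                    dist[s][v] = dist[s][u] + 1
                    dq.append(v)
    return dist


def _angle(a, b, c):
    u, v = a - b, c - b
    return math.acos(
        max(-1.0, min(1.0, float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))))
    )


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.atan2(float(np.dot(m, n2)), float(np.dot(n1, n2)))


def brute_force_total_energy(topology, parameters, coords) -> float:
    """AMBER-form energy by direct double loops; no shared engine code."""
    kc = 332.0522173
    coords = np.asarray(coords, float)
    n = topology.n_atoms
    bonds = list(topology.bonds)
    dist = bfs_distances(n, bonds)

    e = 0.0
    for i, j in bonds:
        kb, r0 = parameters.bond_terms[topology.bond_type((i, j))]
        e += kb * (float(np.linalg.norm(coords[i] - coords[j])) - r0) ** 2

    # angles: every bonded triple, enumerated independently
    for j in range(n):
        nbrs = [k for k in range(n) if dist[j][k] == 1]
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                kt, t0 = parameters.angle_terms[topology.angle_type((i, j, k))]
                e += kt * (_angle(coords[i], coords[j], coords[k]) - math.radians(t0)) ** 2

    # torsions: every chain of three bonds, once per quadruple
    seen = set()
    for j in range(n):
        for k in range(n):
            if dist[j][k] != 1:
                continue
            for i in range(n):
                if dist[i][j] != 1 or i == k:
                    continue
                for l in range(n):
                    if dist[k][l] != 1 or l == j or l == i:
                        continue
                    key = (i, j, k, l) if (i, j, k, l) <= (l, k, j, i) else (l, k, j, i)
                    if key in seen:
                        continue
                    seen.add(key)
                    phi = _dihedral(coords[i], coords[j], coords[k], coords[l])
                    for nn, v, g in parameters.torsion_terms[topology.dihedral_type(key)]:
                        e += v * (1.0 + math.cos(nn * phi - math.radians(g)))

    q = [parameters.charges[a.label] for a in topology.atoms]
    types = [a.atom_type for a in topology.atoms]
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i][j]
            if 0 < d <= 2:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            a_ij, b_ij = parameters.lj_ab(types[i], types[j])
            e_lj = a_ij / r**12 - b_ij / r**6
            e_c = kc * q[i] * q[j] / (parameters.dielectric * r)
            if d == 3:
                e += e_lj / parameters.scnb + e_c / parameters.scee
            else:
                e += e_lj + e_c
    return e


def golden_section_minimize(f, lo, hi, tol=1e-10, max_iter=500):
    """1-D golden-section minimum of a unimodal function on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if abs(b - a) < tol:
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)
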