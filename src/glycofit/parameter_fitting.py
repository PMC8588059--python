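"""Penalized relative-energy-error fitting of torsion, charge and scee
parameters.

The cost minimized is

    C = (1/M) sum_s REE(s)^2
        + lambda_csum * (sum_i q_i)^2
        + lambda_chg  * sum_i (q_i - qbar_i)^2 / (2 sigma_i)^2
        + lambda_dih  * sum_{t,n} (V_{t,n} - V_{t,n}^ref)^2
        + lambda_scee * (scee - scee_ref)^2

over the torsion Fourier amplitudes and phases, the charges of the
non-aliphatic-hydrogen atoms, and the 1-4 electrostatic scaling factor
scee.  Bond, angle and Lennard-Jones parameters stay at their reference
values.  The neutrality penalty runs over *all* atomic charges
(including the fixed zeros); the per-atom charge and torsion penalties
run over the free parameters only.  Minimization is full-batch gradient
descent with the Adadelta update rule, which needs no learning rate.

Gradients are exact analytic derivatives; the dependence of the
reference structure's MM energy on the current parameters is included.
All expensive structure-dependent quantities (per-type torsion phase
sums, inverse-distance matrices, frozen energy terms) are precomputed
once per dataset, so one epoch costs a handful of small matrix products.

Two numerical choices make Adadelta behave on this landscape.  First,
the update carries a step-scale multiplier (default 0.3): with the
neutrality weight at 1e7 the cost surface has a curvature ratio of
roughly seven orders of magnitude, and unscaled Adadelta steps
oscillate destructively along the stiff direction.  Second, the
optimizer works on the charge block in a rotated orthonormal basis
whose first coordinate is the total-charge direction: the neutrality
penalty is stiff along exactly that direction, and Adadelta's
per-component adaptivity only helps when stiffness is axis-aligned.
The cost function itself is evaluated in natural coordinates either
way; the rotation changes nothing but the optimizer's path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .dataset_curation import ChargeStatistics
from .forcefield_io import ConformerSet, DihedralType, ParameterSet
from .mm_energy import COULOMB_CONSTANT
from .molecule_model import Topology

__all__ = [
    "FreeParameterMask",
    "FitConfig",
    "FitResult",
    "FitWorkspace",
    "cost",
    "gradient",
    "AdadeltaState",
    "adadelta_step",
    "fit",
]


@dataclass
class FreeParameterMask:
    """Which parameters the optimizer may move.

    ``torsion_types=None`` frees every dihedral type present in the
    topology, each with all six Fourier periodicities; ``charge_atoms=None``
    frees every non-aliphatic-hydrogen atom.
    """

    torsion_types: list[DihedralType] | None = None
    fit_amplitudes: bool = True
    fit_phases: bool = True
    charge_atoms: list[str] | None = None
    fit_scee: bool = True


@dataclass
class FitConfig:
    """Penalty weights, optimizer settings and the free-parameter mask."""

    lambda_csum: float = 1.0e7
    lambda_chg: float = 0.1
    lambda_dih: float = 3.0
    lambda_scee: float = 100.0
    rho: float = 0.95  # Adadelta decay
    adadelta_eps: float = 1.0e-6  # numerical-stability constant
    learning_rate: float = 0.3  # step-scale multiplier on the Adadelta update
    max_epochs: int = 5000
    tolerance: float = 1.0e-8  # relative train-cost change
    patience: int = 50  # epochs the tolerance must hold
    sigma_floor: float = 0.01  # e; floor for the charge-penalty denominator
    seed: int = 0
    mask: FreeParameterMask = field(default_factory=FreeParameterMask)

    def __post_init__(self) -> None:
        for name in ("lambda_csum", "lambda_chg", "lambda_dih", "lambda_scee"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class FitWorkspace:
    """Cached per-structure features for fast cost/gradient evaluation.

    For every structure the workspace stores, once:

    * the constant energy (bonds, angles, Lennard-Jones, frozen torsion
      types) that no free parameter touches,
    * per free dihedral type t and periodicity n, the phase sums
      ``sum_inst cos(n phi)`` and ``sum_inst sin(n phi)``, from which the
      torsion energy is linear in (V cos gamma, V sin gamma),
    * symmetric inverse-distance matrices restricted to the non-bonded
      and 1-4 pair classes, from which every Coulomb sum is the quadratic
      form  q^T G q / 2.
    """

    def __init__(
        self,
        conformer_set: ConformerSet,
        reference_params: ParameterSet,
        config: FitConfig,
        charge_stats: ChargeStatistics | None = None,
    ):
        self.topology: Topology = conformer_set.topology
        self.conformer_set = conformer_set
        self.reference_params = reference_params
        self.config = config
        topo = self.topology
        mask = config.mask

        self.free_types: list[DihedralType] = (
            list(mask.torsion_types)
            if mask.torsion_types is not None
            else topo.dihedral_types()
        )
        opt_labels = [topo.atoms[i].label for i in topo.optimizable_atoms]
        free_labels = (
            list(mask.charge_atoms) if mask.charge_atoms is not None else opt_labels
        )
        unknown = set(free_labels) - set(opt_labels)
        if unknown:
            raise ValueError(f"charge atoms not optimizable: {sorted(unknown)}")
        self.free_charge_idx = np.array([topo.index(l) for l in free_labels], dtype=int)
        self.free_charge_labels = free_labels

        coords = conformer_set.coordinates_array()  # (S, N, 3)
        n_struct = coords.shape[0]
        self.n_struct = n_struct
        self.e_qm = conformer_set.energies()
        self.ref_index = conformer_set.reference_index

        # torsion phase sums for free types; frozen types fold into const
        quads = np.array(topo.dihedrals, dtype=int)
        phis = geometry.dihedral_angles_batch(coords, quads)  # (S, D)
        type_of = [topo.dihedral_type(tuple(q)) for q in topo.dihedrals]
        tindex = {t: i for i, t in enumerate(self.free_types)}
        n_types = len(self.free_types)
        self.counts = np.zeros(n_types)
        self.cos_sums = np.zeros((n_struct, n_types, 6))
        self.sin_sums = np.zeros((n_struct, n_types, 6))
        frozen_torsion = np.zeros(n_struct)
        nvals = np.arange(1, 7)
        for d, t in enumerate(type_of):
            if t in tindex:
                ti = tindex[t]
                self.counts[ti] += 1
                nphi = np.outer(phis[:, d], nvals)  # (S, 6)
                self.cos_sums[:, ti, :] += np.cos(nphi)
                self.sin_sums[:, ti, :] += np.sin(nphi)
            else:
                terms = reference_params.torsion_terms[t]
                for n, v, g in terms:
                    frozen_torsion += v * (
                        1.0 + np.cos(n * phis[:, d] - np.radians(g))
                    )

        # pairwise inverse distances split by class
        diff = coords[:, :, None, :] - coords[:, None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        with np.errstate(divide="ignore"):
            inv = np.where(dist > 0, 1.0 / np.maximum(dist, 1e-300), 0.0)
        n_atoms = topo.n_atoms
        mask_nb = np.zeros((n_atoms, n_atoms), dtype=bool)
        mask_14 = np.zeros((n_atoms, n_atoms), dtype=bool)
        for (i, j), cls in topo.pair_class.items():
            if cls == "nonbonded":
                mask_nb[i, j] = mask_nb[j, i] = True
            elif cls == "14":
                mask_14[i, j] = mask_14[j, i] = True
        self.g_nb = inv * mask_nb  # (S, N, N)
        self.g_14 = inv * mask_14

        # constant energy: bonds, angles, all Lennard-Jones, frozen torsions
        const = frozen_torsion.copy()
        for b in topo.bonds:
            kb, r0 = reference_params.bond_terms[topo.bond_type(b)]
            r = dist[:, b[0], b[1]]
            const += kb * (r - r0) ** 2
        for a in topo.angles:
            kt, t0 = reference_params.angle_terms[topo.angle_type(a)]
            u = coords[:, a[0]] - coords[:, a[1]]
            v = coords[:, a[2]] - coords[:, a[1]]
            cosang = (u * v).sum(-1) / (
                np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
            )
            theta = np.arccos(np.clip(cosang, -1.0, 1.0))
            const += kt * (theta - np.radians(t0)) ** 2
        lj_a = np.zeros((n_atoms, n_atoms))
        lj_b = np.zeros((n_atoms, n_atoms))
        types = [a.atom_type for a in topo.atoms]
        for i in range(n_atoms):
            for j in range(n_atoms):
                lj_a[i, j], lj_b[i, j] = reference_params.lj_ab(types[i], types[j])
        inv6 = inv**6
        lj_pair = lj_a * inv6**2 - lj_b * inv6
        const += 0.5 * (lj_pair * mask_nb).sum(axis=(1, 2))
        const += 0.5 * (lj_pair * mask_14).sum(axis=(1, 2)) / reference_params.scnb
        self.const_energy = const

        # fixed part of the charge vector (everything not in the free set)
        q_ref = reference_params.charge_vector(topo)
        self.q_fixed = q_ref.copy()
        self.q_fixed[self.free_charge_idx] = 0.0

        # penalty references
        self.v_ref = np.zeros((n_types, 6))
        self.gamma_ref = np.zeros((n_types, 6))
        for t, ti in tindex.items():
            for n, v, g in reference_params.torsion_terms.get(t, []):
                self.v_ref[ti, n - 1] = v
                self.gamma_ref[ti, n - 1] = np.radians(g)
        self.scee_ref = reference_params.scee

        if charge_stats is not None:
            self.q_bar = np.array(
                [charge_stats.mean[l] for l in free_labels], dtype=float
            )
            sig = np.array([charge_stats.sd[l] for l in free_labels], dtype=float)
            if config.lambda_chg > 0 and np.any(sig < config.sigma_floor):
                warnings.warn(
                    "charge-penalty SDs below the floor; clamped to "
                    f"{config.sigma_floor} e"
                )
            self.sigma = np.maximum(sig, config.sigma_floor)
        else:
            self.q_bar = q_ref[self.free_charge_idx]
            self.sigma = np.full(len(free_labels), max(config.sigma_floor, 0.1))

        self.n_v = n_types * 6

    # -- parameter vector layout: [V (T*6), gamma (T*6), q_free, scee] ------

    def initial_vector(self, start_params: ParameterSet) -> np.ndarray:
        topo = self.topology
        v = np.zeros((len(self.free_types), 6))
        g = np.zeros((len(self.free_types), 6))
        for ti, t in enumerate(self.free_types):
            for n, amp, gam in start_params.torsion_terms.get(t, []):
                v[ti, n - 1] = amp
                g[ti, n - 1] = np.radians(gam)
        q = start_params.charge_vector(topo)[self.free_charge_idx]
        return np.concatenate([v.ravel(), g.ravel(), q, [start_params.scee]])

    def unpack(self, p: np.ndarray):
        nv = self.n_v
        v = p[:nv].reshape(-1, 6)
        g = p[nv : 2 * nv].reshape(-1, 6)
        q_free = p[2 * nv : 2 * nv + len(self.free_charge_idx)]
        scee = float(p[-1])
        return v, g, q_free, scee

    def to_parameter_set(self, p: np.ndarray) -> ParameterSet:
        """Materialize a full ParameterSet from a parameter vector."""
        v, g, q_free, scee = self.unpack(p)
        ps = self.reference_params.copy()
        for ti, t in enumerate(self.free_types):
            ps.torsion_terms[t] = [
                (n, float(v[ti, n - 1]), float(np.degrees(g[ti, n - 1]) % 360.0))
                for n in range(1, 7)
            ]
        for k, idx in enumerate(self.free_charge_idx):
            ps.charges[self.topology.atoms[idx].label] = float(q_free[k])
        ps.scee = scee
        return ps

    def free_flags(self) -> np.ndarray:
        """Boolean vector marking the components the optimizer may move."""
        m = self.config.mask
        nv = self.n_v
        flags = np.ones(2 * nv + len(self.free_charge_idx) + 1, dtype=bool)
        if not m.fit_amplitudes:
            flags[:nv] = False
        if not m.fit_phases:
            flags[nv : 2 * nv] = False
        if not m.fit_scee:
            flags[-1] = False
        return flags

    # -- energies and derivatives ------------------------------------------

    def _energies(self, p: np.ndarray, subset: np.ndarray):
        v, g, q_free, scee = self.unpack(p)
        eps = self.reference_params.dielectric
        q = self.q_fixed.copy()
        q[self.free_charge_idx] = q_free

        a_cos = v * np.cos(g)
        a_sin = v * np.sin(g)
        etor = (
            (self.counts * v.sum(axis=1)).sum()
            + np.einsum("stn,tn->s", self.cos_sums[subset], a_cos)
            + np.einsum("stn,tn->s", self.sin_sums[subset], a_sin)
        )
        gq_nb = np.einsum("sij,j->si", self.g_nb[subset], q)
        gq_14 = np.einsum("sij,j->si", self.g_14[subset], q)
        ec_nb = 0.5 * COULOMB_CONSTANT / eps * np.einsum("si,i->s", gq_nb, q)
        ec_14 = 0.5 * COULOMB_CONSTANT / (eps * scee) * np.einsum("si,i->s", gq_14, q)
        e = self.const_energy[subset] + etor + ec_nb + ec_14
        return e, (gq_nb, gq_14, ec_14, q, scee)

    def cost_and_gradient(
        self, p: np.ndarray, subset: np.ndarray, want_gradient: bool = True
    ):
        """Penalized cost, penalty breakdown and (optionally) its gradient.

        ``subset`` are positions in the workspace's structure list over
        which the data term runs; the REE reference structure is always
        the dataset's designated reference, whose energy is recomputed
        from the current parameters.
        """
        cfg = self.config
        subset = np.asarray(subset, dtype=int)
        rows = np.concatenate([subset, [self.ref_index]])
        e, (gq_nb, gq_14, ec_14, q, scee) = self._energies(p, rows)
        e_s, e_ref = e[:-1], e[-1]
        m = len(subset)
        eps = self.reference_params.dielectric

        ree = (self.e_qm[subset] - self.e_qm[self.ref_index]) - (e_s - e_ref)
        data = float(np.mean(ree**2))

        v, g, q_free, _ = self.unpack(p)
        q_all_sum = float(q.sum())
        chi_csum = q_all_sum**2
        chi_chg = float((((q_free - self.q_bar) / (2.0 * self.sigma)) ** 2).sum())
        chi_dih = float(((v - self.v_ref) ** 2).sum())
        chi_scee = (scee - self.scee_ref) ** 2
        penalties = {
            "chi2_csum": chi_csum,
            "chi2_chg": chi_chg,
            "chi2_dih": chi_dih,
            "chi2_scee": chi_scee,
            "data": data,
        }
        total = (
            data
            + cfg.lambda_csum * chi_csum
            + cfg.lambda_chg * chi_chg
            + cfg.lambda_dih * chi_dih
            + cfg.lambda_scee * chi_scee
        )
        if not want_gradient:
            return total, penalties, None

        # dE/dparam for every evaluated row (subset + reference)
        cos_g, sin_g = np.cos(g), np.sin(g)
        d_v = (
            self.counts[None, :, None]
            + self.cos_sums[rows] * cos_g
            + self.sin_sums[rows] * sin_g
        )  # (R, T, 6)
        d_gamma = v * (-sin_g * self.cos_sums[rows] + cos_g * self.sin_sums[rows])
        d_q = COULOMB_CONSTANT / eps * (gq_nb + gq_14 / scee)  # (R, N)
        d_q = d_q[:, self.free_charge_idx]
        d_scee = -ec_14 / scee  # (R,)

        # chain rule through REE: dREE/dtheta = -(dE_s - dE_ref)
        w = 2.0 / m * ree  # (M,)
        def data_grad(de):  # de: (R, ...)
            diff = de[:-1] - de[-1]
            return -np.tensordot(w, diff, axes=(0, 0))

        g_v = data_grad(d_v) + 2.0 * cfg.lambda_dih * (v - self.v_ref)
        g_gamma = data_grad(d_gamma)
        g_q = (
            data_grad(d_q)
            + 2.0 * cfg.lambda_csum * q_all_sum
            + 2.0 * cfg.lambda_chg * (q_free - self.q_bar) / (4.0 * self.sigma**2)
        )
        g_scee = float(data_grad(d_scee)) + 2.0 * cfg.lambda_scee * (scee - self.scee_ref)

        grad = np.concatenate([g_v.ravel(), g_gamma.ravel(), g_q, [g_scee]])
        grad[~self.free_flags()] = 0.0
        return total, penalties, grad

    def ree(self, p: np.ndarray, subset: np.ndarray) -> np.ndarray:
        subset = np.asarray(subset, dtype=int)
        rows = np.concatenate([subset, [self.ref_index]])
        e, _ = self._energies(p, rows)
        return (self.e_qm[subset] - self.e_qm[self.ref_index]) - (e[:-1] - e[-1])


def cost(
    parameters: ParameterSet,
    conformer_set: ConformerSet,
    reference_params: ParameterSet,
    charge_stats: ChargeStatistics | None,
    config: FitConfig,
) -> tuple[float, dict[str, float]]:
    """Penalized cost of a parameter set on a training set (from scratch)."""
    ws = FitWorkspace(conformer_set, reference_params, config, charge_stats)
    p = ws.initial_vector(parameters)
    total, penalties, _ = ws.cost_and_gradient(p, np.arange(len(conformer_set)), False)
    return total, penalties


def gradient(
    parameters: ParameterSet,
    conformer_set: ConformerSet,
    reference_params: ParameterSet,
    charge_stats: ChargeStatistics | None,
    config: FitConfig,
) -> np.ndarray:
    """Analytic cost gradient in the workspace's parameter-vector layout."""
    ws = FitWorkspace(conformer_set, reference_params, config, charge_stats)
    p = ws.initial_vector(parameters)
    _, _, grad = ws.cost_and_gradient(p, np.arange(len(conformer_set)))
    return grad


@dataclass
class AdadeltaState:
    """Running averages of squared gradients and squared updates."""

    avg_sq_grad: np.ndarray
    avg_sq_update: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "AdadeltaState":
        return cls(np.zeros(n), np.zeros(n))


def adadelta_step(
    grad: np.ndarray,
    state: AdadeltaState,
    rho: float = 0.95,
    eps: float = 1.0e-6,
    learning_rate: float = 1.0,
) -> np.ndarray:
    """One Adadelta update; returns the parameter increment.

    Accumulate E[g^2]; Delta x = -RMS[Dx]/RMS[g] * g; accumulate
    E[Dx^2].  The published rule has no learning rate (the default
    here); the optional multiplier scales the step inside the update
    feedback loop, which tames oscillation on very stiff directions.
    The state is updated in place.
    """
    state.avg_sq_grad = rho * state.avg_sq_grad + (1.0 - rho) * grad**2
    update = (
        -learning_rate
        * np.sqrt(state.avg_sq_update + eps)
        / np.sqrt(state.avg_sq_grad + eps)
        * grad
    )
    state.avg_sq_update = rho * state.avg_sq_update + (1.0 - rho) * update**2
    return update


@dataclass
class FitResult:
    """Optimized parameters plus the full optimization record."""

    parameters: ParameterSet
    train_cost: list[float]
    test_cost: list[float]
    penalties: dict[str, float]
    ree_train_mean: float
    ree_train_mean_abs: float
    ree_test_mean: float | None
    ree_test_mean_abs: float | None
    epochs: int
    stop_reason: str


def fit(
    conformer_set: ConformerSet,
    starting_params: ParameterSet,
    charge_stats: ChargeStatistics | None,
    config: FitConfig,
    train_indices: list[int] | None = None,
    test_indices: list[int] | None = None,
) -> FitResult:
    """Minimize the penalized cost with full-batch Adadelta.

    ``train_indices``/``test_indices`` index into ``conformer_set``;
    without them the whole set trains and no test curve is tracked.
    Phases are wrapped into [0, 2 pi) after every step; aliphatic
    hydrogens never enter the parameter vector so their charges remain
    exactly zero.  Deterministic for a given configuration.
    """
    ws = FitWorkspace(conformer_set, starting_params, config, charge_stats)
    train = (
        np.asarray(train_indices, dtype=int)
        if train_indices is not None
        else np.arange(len(conformer_set))
    )
    test = np.asarray(test_indices, dtype=int) if test_indices is not None else None

    p = ws.initial_vector(starting_params)
    state = AdadeltaState.zeros(p.size)
    nv = ws.n_v
    n_q = len(ws.free_charge_idx)
    q_slice = slice(2 * nv, 2 * nv + n_q)
    # orthonormal charge basis with the total-charge direction first
    if n_q > 1:
        basis = np.linalg.qr(
            np.column_stack([np.ones(n_q) / np.sqrt(n_q), np.eye(n_q)[:, 1:]])
        )[0]
    else:
        basis = np.eye(max(n_q, 1))
    free = ws.free_flags()

    train_curve: list[float] = []
    test_curve: list[float] = []
    stop_reason = "max epochs reached"
    stable = 0
    last_good = p.copy()
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        total, penalties, grad = ws.cost_and_gradient(p, train)
        if not np.isfinite(total):
            p = last_good
            stop_reason = "non-finite cost; reverted to last good state"
            break
        last_good = p.copy()
        train_curve.append(total)
        if test is not None and test.size:
            t_cost, _, _ = ws.cost_and_gradient(p, test, want_gradient=False)
            test_curve.append(t_cost)
        if len(train_curve) >= 2:
            prev, cur = train_curve[-2], train_curve[-1]
            rel = abs(prev - cur) / max(abs(prev), 1e-300)
            stable = stable + 1 if rel < config.tolerance else 0
            if stable >= config.patience:
                stop_reason = "converged: relative cost change below tolerance"
                break
        if n_q:
            grad[q_slice] = basis.T @ grad[q_slice]
        update = adadelta_step(
            grad, state, config.rho, config.adadelta_eps, config.learning_rate
        )
        if n_q:
            update[q_slice] = basis @ update[q_slice]
        p = p + np.where(free, update, 0.0)
        p[nv : 2 * nv] = np.mod(p[nv : 2 * nv], 2.0 * np.pi)

    final_params = ws.to_parameter_set(p)
    _, penalties, _ = ws.cost_and_gradient(p, train, want_gradient=False)
    ree_train = ws.ree(p, train)
    ree_test = ws.ree(p, test) if test is not None and test.size else None
    return FitResult(
        parameters=final_params,
        train_cost=train_curve,
        test_cost=test_curve,
        penalties=penalties,
        ree_train_mean=float(np.mean(ree_train)),
        ree_train_mean_abs=float(np.mean(np.abs(ree_train))),
        ree_test_mean=None if ree_test is None else float(np.mean(ree_test)),
        ree_test_mean_abs=None if ree_test is None else float(np.mean(np.abs(ree_test))),
        epochs=epoch,
        stop_reason=stop_reason,
    )
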