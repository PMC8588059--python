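"""Conformer dataset curation: dedup, outlier removal, split, charge stats.

Near-identical structures are removed with a greedy keep-first pass at an
RMSD threshold of 0.05 Angstrom (inclusive), so that over-represented
regions of conformational space do not dominate the fit.  Structures with
a pathologically large Lennard-Jones energy are also removed: the LJ
parameters are frozen during fitting, so a steric-clash energy error
cannot legitimately be absorbed by the free torsion/charge parameters.
The curated set is split 7:3 into training and test subsets, with the
reference structure always kept in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .forcefield_io import ConformerSet, ParameterSet
from .mm_energy import total_energy
from .molecule_model import Topology

__all__ = [
    "CurationReport",
    "ChargeStatistics",
    "rmsd",
    "deduplicate",
    "filter_lj_outliers",
    "split",
    "charge_statistics",
]


@dataclass
class CurationReport:
    """What a curation pass removed, retained and why."""

    input_count: int
    retained_ids: list[str]
    removed_duplicates: list[tuple[str, str]] = field(default_factory=list)  # (id, kept id)
    removed_outliers: list[tuple[str, float]] = field(default_factory=list)  # (id, LJ value)
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def removed_duplicate_count(self) -> int:
        return len(self.removed_duplicates)

    @property
    def removed_outlier_count(self) -> int:
        return len(self.removed_outliers)


def rmsd(x: np.ndarray, y: np.ndarray, superpose: bool = True) -> float:
    """Root-mean-square deviation between two structures (Angstrom).

    With ``superpose`` the optimal rigid-body superposition (centroid
    removal plus the optimal rotation) is applied first, making the value
    frame-independent; without it the literal coordinate-difference RMSD
    is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("structures must share an (N, 3) shape")
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty structures")
    if not superpose:
        return float(np.sqrt(((x - y) ** 2).sum() / n))
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    _, rssd = Rotation.align_vectors(xc, yc)
    return float(rssd / np.sqrt(n))


def _pair_screen_features(coords: np.ndarray) -> np.ndarray:
    """Cheap rotation-invariant fingerprint: per-atom centroid distances.

    For any rigid superposition, | |x_i| - |R y_i| | <= |x_i - R y_i|
    atom by atom, so the RMS difference of these profiles is a lower
    bound on the superposed RMSD.
    """
    c = coords - coords.mean(axis=0)
    return np.linalg.norm(c, axis=1)


def deduplicate(
    conformer_set: ConformerSet, threshold: float = 0.05, superpose: bool = True
) -> tuple[ConformerSet, CurationReport]:
    """Greedy keep-first deduplication at an inclusive RMSD threshold.

    Structures are visited in input order; one is dropped when it lies
    within ``threshold`` of any previously retained structure.  A cheap
    rotation-invariant fingerprint whose RMS change lower-bounds the
    superposed RMSD prunes candidate pairs before the exact
    superposition is computed.
    """
    n = len(conformer_set)
    coords = conformer_set.coordinates_array()
    feats = np.stack([_pair_screen_features(c) for c in coords])
    retained: list[int] = []
    removed: list[tuple[str, str]] = []
    ids = conformer_set.ids
    for i in range(n):
        dup_of = None
        if retained:
            gap = np.sqrt(((feats[retained] - feats[i]) ** 2).mean(axis=1))
            if not superpose:
                # literal RMSD has no rotation-invariant lower bound; check all
                candidates = list(retained)
            else:
                candidates = [retained[k] for k in np.nonzero(gap <= threshold * 1.0001)[0]]
            for j in candidates:
                if rmsd(coords[j], coords[i], superpose=superpose) <= threshold:
                    dup_of = j
                    break
        if dup_of is None:
            retained.append(i)
        else:
            removed.append((ids[i], ids[dup_of]))
    report = CurationReport(
        input_count=n,
        retained_ids=[ids[i] for i in retained],
        removed_duplicates=removed,
    )
    return conformer_set.subset(retained), report


def filter_lj_outliers(
    conformer_set: ConformerSet,
    parameters: ParameterSet,
    iqr_factor: float | None = 10.0,
    absolute_threshold: float | None = None,
) -> tuple[ConformerSet, CurationReport]:
    """Remove structures whose total Lennard-Jones energy is an outlier.

    Default rule: LJ (scaled 1-4 plus non-bonded) above
    ``median + iqr_factor * IQR`` of the set.  An absolute threshold in
    kcal/mol may be given instead; passing both rules as ``None``
    disables filtering.
    """
    topology = conformer_set.topology
    lj_vals = np.array(
        [
            (b := total_energy(topology, parameters, c.coordinates)).lj_14 + b.lj_nb
            for c in conformer_set
        ]
    )
    if absolute_threshold is not None:
        cutoff = absolute_threshold
    elif iqr_factor is not None:
        q1, med, q3 = np.percentile(lj_vals, [25, 50, 75])
        cutoff = med + iqr_factor * max(q3 - q1, 0.0)
    else:
        cutoff = np.inf
    keep = [i for i in range(len(conformer_set)) if lj_vals[i] <= cutoff]
    removed = [
        (conformer_set.ids[i], float(lj_vals[i]))
        for i in range(len(conformer_set))
        if lj_vals[i] > cutoff
    ]
    report = CurationReport(
        input_count=len(conformer_set),
        retained_ids=[conformer_set.ids[i] for i in keep],
        removed_outliers=removed,
    )
    return conformer_set.subset(keep), report


def split(
    conformer_set: ConformerSet, fraction: float = 0.7, seed: int = 0
) -> tuple[list[int], list[int]]:
    """Random train/test split (default 7:3) keeping the reference in train.

    Returns index lists into ``conformer_set``; the first
    ``ceil(fraction * N)`` shuffled structures form the training set.
    """
    n = len(conformer_set)
    if n < 2:
        raise ValueError("need at least two structures to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    n_train = int(np.ceil(fraction * n))
    train, test = order[:n_train], order[n_train:]
    ref = conformer_set.reference_index
    if ref in test:
        swap = train[-1]
        train[train.index(swap)] = ref
        test[test.index(ref)] = swap
    return [int(i) for i in train], [int(i) for i in test]


@dataclass
class ChargeStatistics:
    """Ensemble mean and population SD of per-structure atomic charges.

    Defined only for the charge-optimizable atoms (aliphatic hydrogens
    carry fixed zero charge in every charge set).
    """

    mean: dict[str, float]
    sd: dict[str, float]
    sample_count: int

    def arrays(self, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) over the optimizable atoms, in topology order."""
        labels = [topology.atoms[i].label for i in topology.optimizable_atoms]
        return (
            np.array([self.mean[l] for l in labels]),
            np.array([self.sd[l] for l in labels]),
        )


def charge_statistics(conformer_set: ConformerSet) -> ChargeStatistics:
    """Per-atom mean and population SD over the available charge sets.

    Conformers without a charge set are skipped; the sample count reports
    how many contributed.  A nonzero charge on an aliphatic hydrogen in
    any set is an error, since those charges are fixed at zero by
    convention.
    """
    topology = conformer_set.topology
    sets = [c.charges for c in conformer_set if c.charges is not None]
    if len(sets) < 2:
        raise ValueError("need at least two conformers with charge sets")
    q = np.stack(sets)  # (M, N)
    for i, atom in enumerate(topology.atoms):
        if atom.is_aliphatic_hydrogen and np.any(q[:, i] != 0.0):
            raise ValueError(f"aliphatic hydrogen {atom.label} carries a nonzero charge")
    opt = topology.optimizable_atoms
    labels = [topology.atoms[i].label for i in opt]
    mean = q[:, opt].mean(axis=0)
    sd = q[:, opt].std(axis=0)  # population SD: ensemble statistic
    return ChargeStatistics(
        mean=dict(zip(labels, mean.tolist())),
        sd=dict(zip(labels, sd.tolist())),
        sample_count=q.shape[0],
    )
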