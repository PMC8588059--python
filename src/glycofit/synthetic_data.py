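"""Synthetic glucose conformer datasets with a known-truth energy oracle.

Real re-parameterization runs fit against quantum-chemical conformer
energies and ensembles of electrostatic-potential-derived charges.
Neither is computable here, so this module generates stand-ins with a
*known* ground truth: conformers are built from the shipped 4C1 chair by
uniformly resampling the exocyclic torsions, optionally bending the
anomeric carbon to perturb the ring pucker, and adding small Cartesian
jitter; their "reference" energies are the MM energies under a
ground-truth parameter set plus optional Gaussian noise, and per-structure
charge sets are independent normal draws around stated per-atom means.

Because the truth is known, curation, fitting and evaluation can be
tested end to end: a correct fitting pipeline must recover the
ground-truth torsion amplitudes, charges and 1-4 scaling factor from a
perturbed start when the energy noise is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformer_scans import bend_ring_atom, set_dihedral
from .forcefield_io import Conformer, ConformerSet, ParameterSet, glucose_parameters
from .mm_energy import total_energy
from .molecule_model import Topology, glucose_geometry, glucose_template

__all__ = [
    "GeneratorConfig",
    "ground_truth_parameters",
    "generate_conformers",
    "oracle_energies",
    "emulate_resp_sets",
    "make_dataset",
    "DRIVEN_TORSION_TYPES",
    "perturb_parameters",
]

#: Exocyclic torsions resampled by the generator, outermost rotation first.
DEFAULT_DIHEDRAL_RANGES: dict[tuple[str, str, str, str], tuple[float, float]] = {
    ("O5", "C5", "C6", "O6"): (0.0, 360.0),  # hydroxymethyl omega
    ("C5", "C6", "O6", "HO6"): (0.0, 360.0),
    ("C2", "C1", "O1", "HO1"): (0.0, 360.0),
    ("C1", "C2", "O2", "HO2"): (0.0, 360.0),
    ("C2", "C3", "O3", "HO3"): (0.0, 360.0),
    ("C3", "C4", "O4", "HO4"): (0.0, 360.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a diverse vacuum conformer ensemble: every
    exocyclic torsion uniform over the full circle, ring-pucker
    perturbation of up to +/-4 degrees of anomeric-carbon bending,
    0.02 Angstrom Cartesian jitter, and noise-free oracle energies.
    """

    n_structures: int = 1000
    seed: int = 0
    dihedral_ranges: dict[tuple[str, str, str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIHEDRAL_RANGES)
    )
    jitter_sigma: float = 0.02  # Angstrom, per Cartesian component
    pucker_amplitude: float = 4.0  # degrees of C1 bending, uniform in +/- this
    energy_noise_sigma: float = 0.0  # kcal/mol
    charge_sd: float = 0.03  # elementary charge, per-atom SD of emulated charge sets
    ground_truth: ParameterSet | None = None  # defaults to ground_truth_parameters()

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.pucker_amplitude < 0:
            raise ValueError("spread parameters must be non-negative")
        if self.energy_noise_sigma < 0 or self.charge_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


# documented perturbations of the shipped starting set; chosen so that
# recovering the truth from the start exercises every free parameter class
_TRUTH_TORSION_CHANGES: dict[tuple[str, str, str, str], list[tuple[int, float, float]]] = {
    ("Oh", "Cg", "Cg", "Os"): [(1, 0.80, 0.0), (2, 0.25, 0.0), (3, 0.45, 0.0)],
    ("Cg", "Cg", "Oh", "Ho"): [(1, 0.60, 0.0), (3, 0.35, 0.0)],
    ("Ho", "Oh", "Cg", "Os"): [(1, 0.95, 0.0), (2, 0.40, 0.0), (3, 0.20, 0.0)],
    ("Oh", "Cg", "Cg", "Oh"): [(2, 0.55, 0.0), (3, 0.20, 0.0)],
}

_TRUTH_CHARGE_CHANGES: dict[str, float] = {
    "C1": 0.480,
    "C2": 0.237,
    "O1": -0.670,
    "HO1": 0.475,
    "O5": -0.540,
    "O6": -0.700,
    "C6": 0.300,
}

_TRUTH_SCEE = 1.05


def ground_truth_parameters() -> ParameterSet:
    """The generator's default ground truth.

    The shipped starting parameter set with documented perturbations of
    the exocyclic torsion series, seven atomic charges (net charge kept
    exactly zero) and the 1-4 electrostatic scaling factor, so that a
    fit started from the unperturbed set has something non-trivial to
    recover.
    """
    ps = glucose_parameters()
    for t, terms in _TRUTH_TORSION_CHANGES.items():
        ps.torsion_terms[t] = list(terms)
    ps.charges.update(_TRUTH_CHARGE_CHANGES)
    ps.scee = _TRUTH_SCEE
    assert abs(sum(ps.charges.values())) < 1e-12
    return ps


#: Torsion types whose dihedral angles the default generator drives over
#: the full circle.  Their Fourier amplitudes are identifiable from the
#: synthetic data; ring-locked types (whose instances barely move) are not.
DRIVEN_TORSION_TYPES: list[tuple[str, str, str, str]] = [
    ("Oh", "Cg", "Cg", "Os"),  # hydroxymethyl omega (O5-C5-C6-O6)
    ("Cg", "Cg", "Oh", "Ho"),  # hydroxyl rotations
    ("Ho", "Oh", "Cg", "Os"),  # anomeric hydroxyl (HO1-O1-C1-O5)
]


def perturb_parameters(
    ps: ParameterSet,
    torsion_types=None,
    dv: float = 1.0,
    dq: float = 0.05,
    dscee: float = -0.05,
) -> ParameterSet:
    """Deterministically perturbed copy of a parameter set.

    Every Fourier amplitude of the selected torsion types (all six
    periodicities, zeros included) is shifted by alternating +/-``dv``;
    every optimizable-atom charge by alternating +/-``dq``; scee by
    ``dscee``.  Phases are untouched.  This is the standard starting
    point for recovery experiments: far from the truth in every free
    parameter class, at unchanged phase conventions.
    """
    out = ps.copy()
    types = torsion_types if torsion_types is not None else DRIVEN_TORSION_TYPES
    sign = 1
    for t in types:
        amps = {n: v for n, v, g in out.torsion_terms.get(t, [])}
        gams = {n: g for n, v, g in out.torsion_terms.get(t, [])}
        terms = []
        for n in range(1, 7):
            terms.append((n, amps.get(n, 0.0) + sign * dv, gams.get(n, 0.0)))
            sign = -sign
        out.torsion_terms[t] = terms
    sign = 1
    topo = glucose_template()
    for i in topo.optimizable_atoms:
        label = topo.atoms[i].label
        out.charges[label] = out.charges[label] + sign * dq
        sign = -sign
    out.scee = ps.scee + dscee
    return out


def generate_conformers(
    config: GeneratorConfig, topology: Topology | None = None
) -> ConformerSet:
    """Sample glucose conformers from the 4C1 fixture geometry.

    For each structure the configured torsions are driven to independent
    uniform draws, the anomeric carbon is bent by a uniform pucker
    perturbation, and Gaussian jitter is added to every coordinate.
    Fully reproducible from the seed.
    """
    topo = topology or glucose_template()
    base = glucose_geometry()
    rng = np.random.default_rng(config.seed)
    out = []
    for s in range(config.n_structures):
        coords = base.copy()
        for labels, (lo, hi) in config.dihedral_ranges.items():
            coords = set_dihedral(topo, coords, labels, float(rng.uniform(lo, hi)))
        if config.pucker_amplitude > 0:
            ang = float(rng.uniform(-config.pucker_amplitude, config.pucker_amplitude))
            coords = bend_ring_atom(topo, coords, "C1", ang)
        if config.jitter_sigma > 0:
            coords = coords + rng.normal(0.0, config.jitter_sigma, coords.shape)
        out.append(Conformer(f"s{s:05d}", coords))
    return ConformerSet(out, topo)


def oracle_energies(
    conformer_set: ConformerSet,
    ground_truth: ParameterSet | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ConformerSet:
    """Attach QM-role energies: ground-truth MM totals plus Gaussian noise.

    Returns a new conformer set; the reference structure is then the
    minimum-energy row by construction of the downstream convention.
    """
    truth = ground_truth or ground_truth_parameters()
    rng = np.random.default_rng(seed)
    topo = conformer_set.topology
    out = []
    for c in conformer_set:
        e = total_energy(topo, truth, c.coordinates).total
        if noise_sigma > 0:
            e += float(rng.normal(0.0, noise_sigma))
        out.append(Conformer(c.id, c.coordinates, float(e), c.charges))
    return ConformerSet(out, topo)


def emulate_resp_sets(
    conformer_set: ConformerSet,
    charge_mean: dict[str, float] | None = None,
    charge_sd: dict[str, float] | float = 0.03,
    seed: int = 0,
) -> ConformerSet:
    """Attach per-structure charge sets drawn from per-atom normals.

    Stands in for an ensemble of per-structure fitted ESP charges: each
    optimizable atom's charge is an independent draw around its stated
    mean; aliphatic hydrogens are exactly zero in every set.  Charge
    statistics computed on the output recover the inputs within sampling
    error.
    """
    topo = conformer_set.topology
    truth_q = charge_mean or ground_truth_parameters().charges
    rng = np.random.default_rng(seed)
    opt = set(topo.optimizable_atoms)
    mu = np.array(
        [truth_q[a.label] if i in opt else 0.0 for i, a in enumerate(topo.atoms)]
    )
    if isinstance(charge_sd, dict):
        sd = np.array(
            [charge_sd.get(a.label, 0.0) if i in opt else 0.0 for i, a in enumerate(topo.atoms)]
        )
    else:
        sd = np.array([charge_sd if i in opt else 0.0 for i in range(topo.n_atoms)])
    out = []
    for c in conformer_set:
        q = mu + rng.normal(0.0, 1.0, topo.n_atoms) * sd
        q[[i for i in range(topo.n_atoms) if i not in opt]] = 0.0
        out.append(Conformer(c.id, c.coordinates, c.qm_energy, q))
    return ConformerSet(out, topo)


def make_dataset(config: GeneratorConfig) -> ConformerSet:
    """Generate conformers with oracle energies and emulated charge sets."""
    truth = config.ground_truth or ground_truth_parameters()
    cs = generate_conformers(config)
    cs = oracle_energies(cs, truth, config.energy_noise_sigma, seed=config.seed + 1)
    cs = emulate_resp_sets(cs, truth.charges, config.charge_sd, seed=config.seed + 2)
    return cs
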