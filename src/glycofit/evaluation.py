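"""Comparing two parameter sets: improvement decomposition and scan RMSE.

The drop in the mean relative energy error between two parameter sets
A (the incumbent, e.g. the unmodified carbohydrate force field) and B
(the refit) is attributed to individual parameters:

* per dihedral type d, the mean over structures of the per-type torsion
  energy difference,
* per atom i, the mean of the half-shared Coulomb and scaled 1-4
  Coulomb pair sums touching i,

summed into a dihedral part and a charge part.  Two labelled variants
are computed.  The *literal* variant averages the raw per-structure
terms.  The *reference-corrected* variant takes every per-structure term
relative to the reference structure, for which the additivity identity

    <REE_A> - <REE_B> = DIH + CHG            (signed means)

holds exactly, because only torsion and Coulomb terms differ between
the two sets and the REE itself is reference-relative.  The literal
variant's additivity residual equals the reference-structure term
difference and is reported rather than assumed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield_io import ConformerSet, DihedralType, ParameterSet
from .mm_energy import REEResult, relative_energy_error, total_energy

__all__ = ["EvaluationReport", "improvement_decomposition", "scan_rmse"]


@dataclass
class EvaluationReport:
    """Per-parameter improvement decomposition of A versus B."""

    delta_d: dict[DihedralType, float]
    delta_i: dict[str, float]
    delta_dih: float
    delta_chg: float
    delta_d_corrected: dict[DihedralType, float]
    delta_i_corrected: dict[str, float]
    delta_dih_corrected: float
    delta_chg_corrected: float
    ree_a: REEResult | None
    ree_b: REEResult | None
    additivity_residual: float | None
    additivity_residual_corrected: float | None
    scan_rmse: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Tabular summary mirroring the published improvement layout."""
        rows = []
        if self.ree_a is not None and self.ree_b is not None:
            rows.append(("A (incumbent)", self.ree_a.mean, np.nan))
            rows.append(
                ("B (refit)", self.ree_b.mean, self.delta_dih_corrected + self.delta_chg_corrected)
            )
            rows.append(("charge part", np.nan, self.delta_chg_corrected))
            rows.append(("dihedral part", np.nan, self.delta_dih_corrected))
        return pd.DataFrame(rows, columns=["parameter set", "<REE> [kcal/mol]", "Delta [kcal/mol]"])


def improvement_decomposition(
    conformer_set: ConformerSet,
    params_a: ParameterSet,
    params_b: ParameterSet,
) -> EvaluationReport:
    """Attribute the A-to-B change in mean REE to torsions and charges.

    Requires the same structures evaluated under both parameter sets;
    structures need QM-role energies only for the <REE> columns and the
    additivity residuals (the Delta terms themselves are pure MM).
    """
    topo = conformer_set.topology
    breakdowns_a = [total_energy(topo, params_a, c.coordinates) for c in conformer_set]
    breakdowns_b = [total_energy(topo, params_b, c.coordinates) for c in conformer_set]

    dtypes = topo.dihedral_types()
    atom_labels = [a.label for a in topo.atoms]
    m = len(conformer_set)

    tor_a = np.array([[bd.per_dihedral_type.get(t, 0.0) for t in dtypes] for bd in breakdowns_a])
    tor_b = np.array([[bd.per_dihedral_type.get(t, 0.0) for t in dtypes] for bd in breakdowns_b])
    chg_a = np.array([[bd.per_atom_coulomb[l] for l in atom_labels] for bd in breakdowns_a])
    chg_b = np.array([[bd.per_atom_coulomb[l] for l in atom_labels] for bd in breakdowns_b])

    # literal variant: raw per-structure means, incumbent minus refit
    delta_d = dict(zip(dtypes, (tor_a - tor_b).mean(axis=0)))
    delta_i = dict(zip(atom_labels, (chg_a - chg_b).mean(axis=0)))

    have_energies = all(c.qm_energy is not None for c in conformer_set)
    ree_a = ree_b = None
    residual = residual_corr = None
    if have_energies:
        ree_a = relative_energy_error(conformer_set, params_a)
        ree_b = relative_energy_error(conformer_set, params_b)
        ref = conformer_set.reference_index
    else:
        ref = 0

    # reference-corrected variant: each term relative to the reference
    # structure, signed (refit minus incumbent) so that the additivity
    # identity <REE_A> - <REE_B> = DIH + CHG holds exactly
    tor_ac = tor_a - tor_a[ref]
    tor_bc = tor_b - tor_b[ref]
    chg_ac = chg_a - chg_a[ref]
    chg_bc = chg_b - chg_b[ref]
    delta_d_corr = dict(zip(dtypes, (tor_bc - tor_ac).mean(axis=0)))
    delta_i_corr = dict(zip(atom_labels, (chg_bc - chg_ac).mean(axis=0)))

    delta_dih = float(sum(delta_d.values()))
    delta_chg = float(sum(delta_i.values()))
    delta_dih_corr = float(sum(delta_d_corr.values()))
    delta_chg_corr = float(sum(delta_i_corr.values()))

    if have_energies:
        gap = ree_a.mean - ree_b.mean
        residual = float(gap - (delta_dih + delta_chg))
        residual_corr = float(gap - (delta_dih_corr + delta_chg_corr))

    return EvaluationReport(
        delta_d=delta_d,
        delta_i=delta_i,
        delta_dih=delta_dih,
        delta_chg=delta_chg,
        delta_d_corrected=delta_d_corr,
        delta_i_corrected=delta_i_corr,
        delta_dih_corrected=delta_dih_corr,
        delta_chg_corrected=delta_chg_corr,
        ree_a=ree_a,
        ree_b=ree_b,
        additivity_residual=residual,
        additivity_residual_corrected=residual_corr,
    )


def scan_rmse(scan_set: ConformerSet, parameters: ParameterSet) -> float:
    """Root-mean-square REE over a deformation scan (kcal/mol).

    The scan carries its own reference: the structure with the lowest
    QM-role energy within the scan.
    """
    if len(scan_set) == 0:
        raise ValueError("empty scan")
    ree = relative_energy_error(scan_set, parameters)
    return float(np.sqrt(np.mean(ree.ree**2)))
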