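"""Published reference values for the beta-D-glucose refit.

The re-optimized charge set, the fitted 1-4 electrostatic scaling
factor, and the REE-improvement summary published for the refit of the
GLYCAM06 glucose parameters against DFT conformer energies.  These are
inputs for consistency checks and worked examples: the charge table must
be neutral to printed precision, and the improvement entries must obey
the additivity identity within table rounding.
"""

from __future__ import annotations

__all__ = [
    "OPTIMIZED_CHARGES",
    "OPTIMIZED_SCEE",
    "REE_SUMMARY",
    "ROTAMER_FRACTIONS",
    "SCAN_RMSE_AVERAGES",
]

#: Re-optimized atomic partial charges (elementary charge); aliphatic
#: hydrogens are fixed at zero and omitted.
OPTIMIZED_CHARGES: dict[str, float] = {
    "C1": 0.3807,
    "HO1": 0.4278,
    "O1": -0.6496,
    "C2": 0.3003,
    "O2": -0.6958,
    "HO2": 0.4496,
    "C3": 0.2904,
    "O3": -0.7011,
    "HO3": 0.4365,
    "C4": 0.2602,
    "O4": -0.7168,
    "HO4": 0.4256,
    "C5": 0.2169,
    "O5": -0.4806,
    "C6": 0.2861,
    "O6": -0.6717,
    "HO6": 0.4413,
}

#: Fitted 1-4 electrostatic scaling factor.
OPTIMIZED_SCEE: float = 1.017

#: Mean REE (kcal/mol) and improvement Delta (kcal/mol) per parameter class:
#: (mean REE, Delta relative to the incumbent force field).
REE_SUMMARY: dict[str, tuple[float, float | None]] = {
    "incumbent": (3.744, None),
    "charges and dihedrals": (0.282, 3.463),
    "charges only": (2.964, 0.781),
    "dihedrals only": (1.064, 2.681),
}

#: gg/gt/tg hydroxymethyl rotamer fractions from the validation MD runs.
ROTAMER_FRACTIONS: dict[str, dict[str, float]] = {
    "incumbent": {"gg": 0.454, "gt": 0.517, "tg": 0.028},
    "refit": {"gg": 0.580, "gt": 0.405, "tg": 0.016},
}

#: Mean scan RMSE (kcal/mol) over 20 validation structures per
#: deformation mode: (incumbent, refit).
SCAN_RMSE_AVERAGES: dict[str, tuple[float, float]] = {
    "C5-C6 rotation": (1.327, 1.351),
    "O1-C1 rotation": (2.058, 1.886),
    "C1 ring flip": (1.315, 1.145),
}
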