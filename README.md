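# glycofit

Re-optimization of AMBER/GLYCAM-style force-field parameters for
β-D-glucopyranose against reference conformer energies.

Carbohydrate force fields are known to misrank glucose conformers: the
relative energies of hydroxymethyl rotamers, hydroxyl orientations and
ring-puckered structures computed with the stock carbohydrate parameters
can deviate by several kcal/mol from quantum-chemical references, which
in turn skews rotamer populations in molecular-dynamics simulations.
`glycofit` is a toolkit for researchers who want to refit the parameters
that matter for these errors — the torsion Fourier coefficients
V·[1 + cos(nφ − γ)], the atomic partial charges of the 17
non-aliphatic-hydrogen atoms, and the 1–4 electrostatic scaling factor
`scee` — while keeping bonds, angles and Lennard-Jones terms fixed.

The fit minimizes the mean squared **relative energy error**

REE(s) = (E_ref,s − E_ref,ref) − (E_MM,s − E_MM,ref)

over a curated conformer dataset, plus penalty terms that keep the
molecule neutral (weight 10⁷), the charges near their ensemble means,
and the torsions and `scee` near their reference values (weights 0.1,
3.0 and 100.0), using full-batch Adadelta gradient descent with exact
analytic gradients and a 7:3 train/test split. See `docs/methods.md`
for the model, the numerical choices and their rationale.

The package contains, as importable modules with a thin `glycofit` CLI
on top:

- the glucose topology (24 atoms, one ring) with derived angles,
  dihedrals and shortest-path 1-2/1-3/1-4/non-bonded pair classes;
- an AMBER-form vacuum energy engine with per-term decomposition;
- readers/writers for frcmod, prep charge tables, PDB/XYZ coordinates
  and a CSV dataset manifest;
- dataset curation (RMSD deduplication at 0.05 Å, Lennard-Jones outlier
  removal, train/test split, per-atom charge statistics);
- the penalized fit itself;
- evaluation (per-dihedral-type and per-atom improvement decomposition,
  deformation-scan RMSE);
- conformer scans (bond-rotation and ring-flip series, gg/gt/tg rotamer
  analysis, Cremer–Pople puckering);
- a synthetic-data generator whose ground-truth energy oracle stands in
  for the quantum-chemical reference, so the whole pipeline is testable
  offline.

## Worked example

Generate 500 noise-free synthetic conformers from the known ground
truth, perturb that truth (±1 kcal/mol on the driven torsion
amplitudes, ±0.05 e on the charges, −0.05 on scee), and fit back:

```python
from glycofit import (GeneratorConfig, make_dataset, ground_truth_parameters,
                      charge_statistics, split, fit, FitConfig, FreeParameterMask,
                      relative_energy_error, improvement_decomposition)
from glycofit.synthetic_data import perturb_parameters, DRIVEN_TORSION_TYPES

data = make_dataset(GeneratorConfig(n_structures=500, seed=7))
stats = charge_statistics(data)
truth = ground_truth_parameters()
start = perturb_parameters(truth)          # V +/-1 kcal/mol, q +/-0.05 e, scee -0.05

print(f"<|REE|> before fit: {relative_energy_error(data, start).mean_abs:.3f} kcal/mol")

config = FitConfig(lambda_chg=0.0, lambda_dih=0.0, lambda_scee=0.0,
                   max_epochs=12000, tolerance=0.0,
                   mask=FreeParameterMask(torsion_types=list(DRIVEN_TORSION_TYPES),
                                          fit_phases=False))
train, test = split(data, 0.7, seed=1)
result = fit(data, start, stats, config, train, test)

print(f"<|REE|> after fit:  {result.ree_train_mean_abs:.3f} (train) / "
      f"{result.ree_test_mean_abs:.3f} (test) kcal/mol")
print(f"fitted scee: {result.parameters.scee:.4f}  (truth {truth.scee})")
print(f"net charge:  {sum(result.parameters.charges.values()):+.2e} e")

report = improvement_decomposition(data, start, result.parameters)
print(f"improvement: dihedral part {report.delta_dih_corrected:.3f} "
      f"+ charge part {report.delta_chg_corrected:.3f} kcal/mol")
```

Output:

```
<|REE|> before fit: 5.675 kcal/mol
<|REE|> after fit:  0.031 (train) / 0.031 (test) kcal/mol
fitted scee: 1.0480  (truth 1.05)
net charge:  -6.48e-04 e
improvement: dihedral part -3.304 + charge part 0.251 kcal/mol
```

The perturbed parameters misrank conformers by 5.7 kcal/mol on average;
after fitting, train and test errors agree at 0.03 kcal/mol (no
overfitting), the 1–4 scaling factor is recovered to 0.002, the
neutrality penalty holds the net charge below 10⁻³ e, and the
improvement decomposition attributes the change to dihedral versus
charge parameters (the parts sum exactly to the signed mean-REE gap;
signs are per-part, the perturbation helped one class and hurt the
other).

The same pipeline is available from a shell:

```
glycofit synth --n 1000 --seed 0 -o data/
glycofit curate -i data/manifest.csv -o curated/
glycofit fit -i curated/manifest.csv --split-file curated/split.csv -o fitresult/
glycofit evaluate -i curated/manifest.csv -a start -b fitresult/optimized.yaml -o eval/
glycofit scan -i chair.xyz --kind rotation --params start --params truth -o scan/
glycofit analyze -i scan/manifest.csv -o analysis/
```

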