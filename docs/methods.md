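# Methods

## The model

`glycofit` re-optimizes a subset of the force-field parameters of
β-D-glucopyranose — the torsion Fourier coefficients, the atomic partial
charges of the 17 non-aliphatic-hydrogen atoms, and the 1–4 electrostatic
scaling factor `scee` — so that molecular-mechanics (MM) relative energies
reproduce a set of reference conformer energies. The MM potential is the
standard AMBER functional form:

    E = Σ_bonds k_b (r − r_0)²
      + Σ_angles k_θ (θ − θ_0)²
      + Σ_dihedrals Σ_{n=1..6} V_n [1 + cos(nφ − γ_n)]
      + Σ_{1-4} [ (A/r¹² − B/r⁶)/scnb + k_C q_i q_j /(ε r scee) ]
      + Σ_{nb}  [ A/r¹² − B/r⁶ + k_C q_i q_j /(ε r) ]

with k_C = 332.0522173 kcal·Å/(mol·e²), ε = 1 (vacuum), no distance
cutoff, 1–2 and 1–3 pairs excluded, and pairs classed by *shortest*
bond-path distance so the classes partition all pairs (a ring pair can
never be both excluded and scaled). Dihedral quadruples are enumerated
one instance per chain of three bonds, with no divider; derived terms
are canonically ordered. Bond, angle and Lennard-Jones parameters are
evaluated but never fitted: an error in a frozen term must not be
absorbed by the free ones.

The quantity fitted is the relative energy error of structure *s*
against the most stable reference structure *ref*:

    REE(s) = (E_ref,s − E_ref,ref) − (E_MM,s − E_MM,ref),

which is invariant to the absolute energy offsets of either method.

## The cost function

    C = (1/M) Σ_s REE(s)²
      + λ_csum (Σ_i q_i)²                        — neutrality
      + λ_chg  Σ_i (q_i − q̄_i)²/(2σ_i)²          — stay near ensemble charges
      + λ_dih  Σ_{t,n} (V_{t,n} − V_{t,n}^ref)²   — stay near reference torsions
      + λ_scee (scee − scee_ref)²                 — stay near reference scee

Defaults: λ_csum = 10⁷, λ_chg = 0.1, λ_dih = 3.0, λ_scee = 100.0. The
neutrality penalty runs over *all* charges including the fixed zeros of
the seven aliphatic hydrogens; χ_chg and χ_dih run over free parameters
only, and χ_dih compares amplitudes only (phases are unpenalized). The
σ_i are per-atom standard deviations of an ensemble of per-structure
charge sets, floored at 0.01 e to avoid division blow-up. The reference
structure's MM energy is recomputed from the current parameters inside
every REE, and its dependence is carried through the analytic gradient.

## Optimization

Full-batch gradient descent with the Adadelta update (ρ = 0.95,
stability constant 10⁻⁶), exact analytic gradients, phases wrapped into
[0°, 360°) after every step, and a 7:3 train/test split with the
reference structure always in training. Two numerical choices were
needed beyond the published update rule, both verified against an
L-BFGS solution of the identical cost:

* **Step scale 0.3.** With λ_csum = 10⁷ the cost surface has a curvature
  ratio of ~10⁷ between the total-charge direction and the softest
  torsion directions. The learning-rate-free update oscillates
  destructively along the stiff direction (the train cost grows without
  bound); a multiplier below ~0.5 inside the update feedback loop
  restores monotone descent.
* **Rotated charge basis.** Adadelta adapts per *component*, but the
  stiff direction is the uniform combination of all 17 charges. The
  optimizer therefore works on the charge block in a fixed orthonormal
  basis whose first coordinate is the total charge; the cost is always
  evaluated in natural coordinates, so this changes the optimizer's
  path and nothing else.

Stopping: 5000 epochs by default, or a relative train-cost change below
10⁻⁸ sustained for 50 epochs. Near the optimum the total charge keeps
oscillating at an amplitude set by the stability constant
(≈ 0.3·√ε ≈ 6×10⁻⁴ e at the defaults); deep-convergence experiments
that need a tighter floor lower `adadelta_eps`.

## Synthetic data: what it emulates and what it does not

No quantum-chemistry or MD engine is available to this package, so the
generator emulates the study conditions with a *known* ground truth:

* Conformers start from a shipped 4C1-chair geometry (a synthetic
  fixture built once with a cheminformatics toolkit; Cremer–Pople
  Q = 0.567 Å, θ = 2.9°). Each structure re-draws all five hydroxyl
  torsions and the hydroxymethyl ω uniformly over the full circle,
  bends the anomeric carbon by up to ±4° to perturb the ring pucker,
  and adds 0.02 Å Gaussian jitter per coordinate.
* "QM" energies are MM energies under a ground-truth parameter set (the
  shipped starting set with documented perturbations of four torsion
  types, seven charges and scee = 1.05, net charge exactly zero), plus
  optional independent Gaussian noise.
* Per-structure charge sets are independent per-atom normal draws
  (default SD 0.03 e), aliphatic hydrogens exactly zero.

Passing tests on these data show that the pipeline recovers parameters
when the model family is exactly realizable and the conformational
diversity is uniform. They do not show anything about basis-set or
functional error, Boltzmann-weighted sampling, solvent effects, or
charge sets derived from real electrostatic potentials — real reference
data have structure (correlated noise, model-form error) that the
generator deliberately omits.

## The recovery experiment

The headline self-check fits n = 2000 noise-free structures from a
start perturbed by ±1 kcal/mol on every free amplitude, ±0.05 e on
every free charge and −0.05 on scee, and requires recovery within
0.1 kcal/mol, 0.01 e and 0.01 respectively, with |Σq| < 10⁻³ e. Two
design points matter:

* **Only the anchoring penalties are relaxed** (λ_chg = λ_dih =
  λ_scee = 0; λ_csum stays at 10⁷). Each of the three anchors pulls
  toward the *reference* values, which differ from the truth by
  construction; in particular the scee anchor cannot be overcome by the
  data because a 1/scee change is nearly collinear with a charge
  rescaling, so leaving it on pins scee ≈ 1 regardless of the truth.
* **Only identifiable torsion types are freed**: the three types whose
  dihedrals the generator actually drives. A singular-value analysis of
  the REE Jacobian shows exact null directions for ring-locked types
  (their instances barely move, so six Fourier amplitudes are fitted to
  what is effectively a constant), and near-collinearity among all
  types sharing one driven bond. Freeing everything is fine in
  production fits, where λ_dih regularizes the null space; it is wrong
  in a recovery experiment with λ_dih = 0.

16 000 epochs converge this experiment in about a minute; the fitted
parameters land well inside all tolerances (typically
ΔV ≲ 0.006 kcal/mol, Δq ≲ 0.001 e, Δscee ≲ 0.001).

## Evaluation conventions

The improvement of parameter set B over A is decomposed per dihedral
type and per atom (half of each Coulomb pair energy attributed to each
participant). Two labelled variants are reported. The *literal* variant
averages raw per-structure term differences (A − B). The
*reference-corrected* variant takes every term relative to the
reference structure and is signed (B − A), for which

    ⟨REE_A⟩ − ⟨REE_B⟩ = Δ_DIH + Δ_CHG

holds exactly (to 10⁻¹⁰ numerically) whenever A and B share their
bond/angle/LJ parameters, because REE is itself reference-relative. The
literal variant's additivity residual equals the reference-structure
term difference and is reported, not assumed zero. ⟨REE⟩ summaries give
the signed mean, the mean absolute value and the SD, since published
tables do not always say which convention they print.

## Other conventions and defaults

* **Deduplication**: greedy keep-first pass at RMSD ≤ 0.05 Å
  (inclusive), with optimal rigid-body superposition on by default —
  conformers arrive in arbitrary frames, and the literal
  coordinate-difference RMSD would be frame-dependent. A
  rotation-invariant per-atom centroid-distance fingerprint, whose RMS
  change provably lower-bounds the superposed RMSD, prunes candidate
  pairs before the exact Kabsch computation.
* **Lennard-Jones outliers**: structures whose total LJ energy exceeds
  median + 10×IQR of the set are removed (configurable absolute
  threshold accepted). The rule is scale-free and robust; the factor is
  deliberately loose so only r⁻¹²-blow-up clashes trigger it.
* **Charge statistics**: population (not sample) SD, as an ensemble
  statistic.
* **Rotamers**: classification by the O5–C5–C6–O6 torsion with
  gg = [−120°, 0°), gt = [0°, 120°), tg the remainder — the standard
  staggered-orientation bins; a documented convention, not inferred
  intent.
* **Ring flip coordinate**: rigid rotation of C1 and its exocyclic
  substituents about the O5⋯C2 axis; the simplest single-parameter
  bending coordinate toward ring inversion.
* **Cremer–Pople**: ring order O5, C1..C5 with the standard mean-plane
  convention; for six-membered rings Q² = q₂² + q₃² equals Σz².
* **Units**: Å, kcal/mol, elementary charge; degrees in files, radians
  internally. frcmod dividers are applied as written on read and
  emitted as 1 on write.

## Known limitations

* The torsion amplitude/phase pair (V, γ) is sign-degenerate
  ((−V, γ+180°) is the same function); fits that free phases can return
  either representative.
* Adadelta's residual total-charge oscillation means |Σq| floors at
  ~6×10⁻⁴ e under the default stability constant rather than scaling
  indefinitely with λ_csum.
* The evaluation identity requires the compared sets to share frozen
  bond/angle/LJ parameters, which is how this package produces them.
* Scan generators assume an acyclic distal side (ring bonds cannot be
  rotation-driven) and a single ring for the flip coordinate.
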