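# noesa

NOE-restrained simulated-annealing refinement of NMR protein structures, at
desk scale.

Solution-NMR structure determination produces an ensemble of conformers that
must simultaneously satisfy experimental restraints — interproton distance
bounds from the nuclear Overhauser effect (NOE) and dihedral-angle intervals —
and look like a well-formed protein. Deposited NMR ensembles often do
neither as well as they could: restraint violations, steric clashes and poor
backbone statistics are common. `noesa` implements a complete refinement
protocol for this problem: it parses XPLOR/CNS restraint tables, converts them
to a CHARMM-style NOE block, refines each conformer by Metropolis Monte Carlo
simulated annealing in torsion space, and scores the result with the standard
evaluation statistics of the field.

The target function is a composite reduced-unit energy

```
E_tot = E_stereo + E_solv + E_exp + E_STAP
```

where `E_stereo` is a soft-core nonbonded repulsion (bond lengths and angles
are held ideal by the torsion-space parameterization), `E_solv` is a
contact-burial solvation surrogate, `E_exp = E_NOE + E_dihedral` scores the
experimental restraints — the NOE term with the soft-asymptote form (flat
inside the bounds `[d − d⁻, d + d⁺]`, harmonic just outside, linear with
bounded slope far outside; ambiguous restraints via the r⁻⁶-summed effective
distance `(Σ r_ij⁻⁶)^(−1/6)`), the dihedral term as a flat-bottom harmonic —
and `E_STAP` is a statistical torsion-angle potential, `−ln P` of a smoothed
2-D histogram over the φ-ψ, φ-χ1, ψ-χ1 and χ1-χ2 torsion pairs. Annealing
heats the system from 100 to 1000 (reduced temperature) over 3200 steps, holds
1000 for 4000 steps and cools to 25 over 8000 steps; acceptance follows
`min(1, exp(−ΔE·T_high/T))`.

Evaluation covers NOE violation statistics (maximum, RMS and exceedance counts
over 0.0/0.5/1.0/2.0 Å cutoffs, broken out by sequence separation:
intraresidual, sequential, medium-range 2–4, long-range ≥ 5), dihedral
violations, an all-atom clash score per 1000 atoms, a Ramachandran
allowed-region percentage, a torsion-window secondary-structure ratio, and the
Matthews correlation coefficient (MCC) between predicted and reference
ligand-binding residue sets,

```
MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
```

A synthetic-fixture module generates ideal-geometry peptides, truth-derived
restraint tables and perturbed starting structures, so the whole pipeline runs
and is tested without any downloads.

## Worked example

The packaged fixture is a 24-residue helix–turn–strand peptide with 200
truth-derived NOEs (60 intraresidual / 60 sequential / 40 medium / 40
long-range) and φ/ψ dihedral restraints; the start structure is the truth with
25° Gaussian noise on every rotatable torsion. Refine it end to end:

```sh
noesa demo --out demo_out --steps-scale 1.0 --seed 0
```

which prints (exactly this, from a real run):

```
Simulated-annealing refinement
==============================
seed: 0   steps: 15200   acceptance rate: 0.662
NOE restraints violated (start -> best): 59 -> 12

term             initial        best
E_tot            472.829      -6.268
E_stereo          22.197       1.552
E_solv           -56.270     -54.120
E_exp_noe        228.110       4.702
E_exp_dihe        88.516       1.224
E_stap           190.277      40.374

max NOE violation (all-range): 7.52 -> 1.63 A
CA RMSD to truth: 3.29 -> 0.28 A
```

Reading this: the perturbed start violates 59 of the 200 NOE restraints with a
worst upper-bound excess of 7.5 Å; after one full 15,200-step annealing run
the best-energy model violates 12, the worst excess is 1.6 Å, and the backbone
is within 0.28 Å RMSD of the ground truth. Every energy term in the breakdown
sums exactly to `E_tot`.

The same machinery is available as a library:

```python
from noesa import Refinement, default_tables
from noesa.synthetic import packaged_fixture

spec, truth, restraints, start = packaged_fixture()
result = Refinement(start, restraints, tables=default_tables()).fit(seed=0)
print(result.summary())
```

Other commands: `noesa convert` (XPLOR → CHARMM NOE block, with
category/duplicate accounting), `noesa refine --config run.yaml` (full
ensemble refinement with reports and energy traces), `noesa validate`
(violation statistics + geometry scores as JSON/CSV), `noesa mcc`
(binding-residue confusion counts and MCC).

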