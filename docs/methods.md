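# Methods

## Model and representation

`noesa` refines protein conformers in internal (torsion) coordinates. A
structure is parameterized by its rotatable torsions — backbone φ and ψ,
side-chain χ angles as defined per residue type — with bond lengths, bond
angles and ring/planar torsions fixed at ideal template values (Engh/Huber-like
backbone geometry; side-chain branch geometry calibrated against
MMFF-optimized L-amino acids so chirality and prochirality are correct).
Peptide ω angles are kept at 180° by default. Cartesian models are built from
torsions by the standard NeRF construction; `torsions_of` inverts
`rebuild_from_torsions` to below 1e-6 degrees, which the test suite asserts as
a property. Hydrogens are placed from the heavy-atom frame by hybridization
rules (tetrahedral CH/CH2, staggered methyls, in-plane amide and aromatic H,
anti hydroxyl/thiol H). Fused and five-membered rings are built from one
spanning path with fixed torsions; the closing bond enters the connectivity
but not the build, so ring closure is approximate at the ~0.1 Å level. Since
the energy has no bonded terms, this costs nothing; it only means proline χ
and ring-internal torsions are not degrees of freedom.

The N-terminus carries a single amide H rather than an NH3+ group, and the
C-terminus an OXT placed trans to O. Residue indices are 0-based in memory;
PDB files are 1-based on disk and the deposited residue numbers are retained
for restraint matching.

## Energy function

All terms are dimensionless ("reduced") energies; only the ratio of energy to
temperature matters to the sampler, so no physical unit is assigned.
`E_tot = E_stereo + E_solv + (E_NOE + E_dihedral) + E_STAP`, each term times a
configurable nonnegative weight (default 1.0, because no published weighting
applies to this reduced scale).

**NOE term (soft asymptote).** Per restraint with bounds [lower, upper], the
effective distance is `(Σ pairs r⁻⁶)^(−1/6)` over all atom pairs the two
selection groups resolve to (wildcards `#`, `*`, `%` expand against the model
at evaluation time). The energy is 0 inside the bounds,
`k·(r−upper)²` for `upper < r ≤ upper + r_switch`, then linear with slope
`min(f_max, 2·k·r_switch)`, C¹-continuous at the switch when the slope is
uncapped; short-side deviations are harmonic only. Defaults: `k = 1.0 Å⁻²`,
`r_switch = 1.0 Å`, `f_max = 2·k·r_switch`. The bounded far-side force is the
point of this functional form: a badly violated restraint pulls with constant
rather than diverging force.

**Dihedral term (flat-bottom harmonic).** Zero within ±δ of the target angle
(differences wrapped periodically), `k·(Δ−δ)²` beyond.

**Statistical torsion potential.** Per residue, the pairs (φ,ψ), (φ,χ1),
(ψ,χ1), (χ1,χ2) are scored by periodic bilinear interpolation of a 2-D grid of
`−ln P`, shifted so the minimum is 0. Grids can be built from any structure
set (`build_stap_table`: periodic histogram + pseudocount, wrapped-Gaussian
smoothing, normalization; defaults 10° bins, pseudocount 1, σ = 10°). The
packaged default is *not* database-derived: it is an analytic prior
(`reference_table`) of wrapped Gaussians at the canonical basins (α, β,
polyproline-II, left-handed α for the backbone; −60/180/+60 staggered rotamers
for χ) with a 10% uniform floor bounding the energy range. It plays the same
role as a knowledge-based torsion potential — pulling torsions toward
populated regions — without claiming PDB statistics.

**Stereochemical term.** Soft-core repulsion `((r_min − r)/r_min)²` over pairs
more than 3 bonds apart, with `r_min` the sum of per-element contact radii
(C 1.50, N 1.40, O 1.25, S 1.75, H 0.90 Å). The radii sit below van der Waals
values on purpose: the intrinsic 1-5 near-contacts of regular backbone
conformations (e.g. O(i)···H(i) at 2.31 Å) must score zero so that ideal
secondary structure is not penalized. Bonded geometry needs no penalty because
it is frozen by the parameterization.

**Solvation surrogate.** Per heavy atom, burial = number of non-bonded heavy
atoms within 6.5 Å; energy = burial × element preference (C, S −0.02; N, O
+0.01). This drives hydrophobic burial and polar exposure. It is a declared
stand-in for an implicit-solvent model, chosen for determinism and O(n²) cost;
it is not a generalized-Born calculation and is never labeled as one.

## Annealing

Metropolis Monte Carlo in torsion space under the schedule: heat 100 → 1000
over 3200 steps, hold 1000 for 4000 steps, cool 1000 → 25 over 8000 steps
(15,200 steps total; temperatures are reduced units labeled in kelvin).
Acceptance is `min(1, exp(−ΔE·T_ref/T))` with `T_ref` the hold temperature, so
the hold phase samples `exp(−E)` exactly and the final phase is nearly greedy.
One move perturbs one uniformly chosen rotatable torsion by Gaussian noise
(σ = 8° default) and rigidly rotates the downstream subtree — algebraically
identical to rebuilding from the updated torsion set, at the cost of one small
rotation. The sampler's statistical correctness is tested directly: sampling
a single torsion against a known table at the hold temperature reproduces its
Boltzmann distribution (χ² goodness of fit, 50k samples).

Runs are pure functions of (inputs, seed); ensemble refinement gives member
*i* the seed `base_seed + i`, so results are reproducible and order-
independent. The representative conformer is the lexicographic minimum of
(number of violated NOE restraints, `E_tot`) over the best-energy models —
"fewest violations, then lowest energy".

## Restraint handling

The XPLOR/CNS `assign` dialect is parsed for NOE tables (with `or`
continuations appending selections to the same ambiguous restraint, `!`
comments, terminal wildcards stored verbatim) and for 4-selection dihedral
tables (wildcards rejected there, since a dihedral needs exactly four atoms).
Sequence-separation categories use the universal convention: intraresidual 0,
sequential 1, medium 2–4, long ≥ 5; an ambiguous restraint is classified by
its *minimum* pair separation (a restraint is as local as its closest
interpretation; the maximum rule is available as a flag). Duplicates (same
selection sets, side-swap insensitive) are merged to the tightest bounds by
default, with `first` and `error` modes exposed; bound conflicts raise with
both source line numbers rather than resolving silently. The CHARMM NOE block
writer emits one ASSIGN per restraint with KMIN/RMIN/KMAX/RMAX/FMAX fields at
3-decimal precision, and its parser inverts it exactly at that precision.

## Validation statistics

NOE violations are upper-bound excesses of the effective distance; for an
ensemble the per-restraint violation is averaged over models before taking
max/RMS/exceedance counts (per-model statistics via a flag). The RMS is over
all restraints with satisfied ones contributing zero (violated-only mode via a
flag). Exceedance counts are over the 0.0/0.5/1.0/2.0 Å cutoffs and are
monotone by construction. The clash score counts nonbonded pairs closer than
summed contact radii minus a 0.4 Å overlap allowance, per 1000 atoms. The
Ramachandran percentage thresholds the φ-ψ prior grid (threshold 4.0 in −ln P
units by default, config-exposed) and reports the fraction of non-terminal
residues in allowed bins. The secondary-structure ratio is a torsion-window
heuristic (helix window with run ≥ 3, sheet windows with run ≥ 2, else coil)
and is labeled as such — it is not DSSP and does no hydrogen-bond analysis.
Binding residues are those with any heavy atom strictly within 4.5 Å of a
ligand heavy atom; predicted vs reference sets are compared by confusion
counts and MCC, with the convention MCC = 0 when a margin of the table is
empty (an all-wrong table with no empty margin is −1 by the formula itself).

## Synthetic study conditions

The packaged fixture is a 24-residue helix–turn–strand peptide (helix 0–10,
turn 11–13, strand 14–23). The turn torsions and side-chain rotamers were
fixed once by a greedy clash relaxation of the ideal-geometry build, chosen so
the strand packs against the helix and >100 genuine long-range proton contacts
exist — without that packing a "long-range" NOE category would be
unsatisfiable. Restraints: 200 NOEs (60 intraresidual / 60 sequential / 40
medium / 40 long-range) sampled from proton pairs under 5.5 Å (the physical
NOE observability range), target = true distance + N(0, 0.1 Å), bounds ± 0.5 Å;
φ/ψ dihedral restraints at truth ± N(0, 5°) with δ = 20° and k = 0.02 deg⁻²;
generator seed 1337. The construction asserts that the truth satisfies ≥ 95%
of the emitted restraints. Starting structures add N(0, 25°) noise to every
rotatable torsion.

What a passing recovery run shows: that the energy function plus sampler can
pull a heavily distorted conformer back to the restraint-consistent fold —
max violation and coordinate RMSD both drop in ≥ 9 of 10 seeds. What it does
not show: performance on real spectra, with assignment ambiguity, sparse or
erroneous restraints, or real conformational averaging.

## Numerical choices and problem sizes

Dihedrals follow the sign convention shared by gemmi/Biopython/MDAnalysis
(right-handed helices have negative φ). Angles are wrapped to [−180, 180);
torsion differences are wrapped before taking magnitudes, so there is no seam
at ±180°. The ensemble topology check is exact (atom names, counts, residue
sequence). Energy evaluation precompiles restraint selections, nonbonded
masks and torsion quadruples once per topology and then evaluates all terms
from one squared-distance matrix (~1.3 ms for the 396-atom fixture), which
puts a full 15,200-step annealing run near 30 s. The acceptance-criteria
suite runs the recovery check at the full schedule for 10 seeds;
`scripts/acceptance.py` reports means over 3 full-schedule replicas, a
reporting choice that keeps the whole script under two minutes on one CPU.

## Known limitations

Ideal internal geometry cannot reproduce strained real structures; proline φ
and ring torsions are frozen; no alternate locations, no mmCIF write, no
hydrogen-bond-based secondary structure; the solvation and stereochemical
terms are qualitative surrogates, so absolute energies are not comparable to
force-field energies; refinement of very long chains will be slow since a
backbone move rotates O(n) atoms and the energy is O(n²).
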