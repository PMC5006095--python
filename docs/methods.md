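# Methods

## The model

`dmmpbsa` scores rigid protein-peptide docking poses with an end-point
(MM-PBSA-style) estimate of the binding free energy and with a dampened
variant of it. For a pose partitioned into receptor and peptide, four binding
differences are computed (complex minus free partners, with both free states
kept in the bound conformation, so bonded terms cancel):

- `dE_coul` — intermolecular Coulomb energy (shifted, 8.5 A cutoff),
- `dE_LJ` — intermolecular Lennard-Jones energy (switched on 6.5-8.5 A),
- `dG_polar` — Poisson-Boltzmann polar solvation difference,
- `dG_nonpolar` — `gamma * SASA` difference, equal to `-gamma * BSA`.

These are grouped into a polar block and a nonpolar block and combined as

    dG_comp(alpha) = alpha * (dE_coul + dG_polar) + (dE_LJ + dG_nonpolar)

`alpha = 1` is the canonical MM-PBSA estimate; `alpha = 0.2` is the dampened
dMM-PBSA score, analogous to the 0.2 weight that empirical docking scores put
on electrostatics. Because alpha only rescales an already-computed block,
both scores come from a single PB calculation per pose. Solute entropy is
deliberately not estimated: with rigid bound-state conformations on both
sides of the difference, its configurational part is ill-defined anyway, and
end-point entropy estimates carry errors an order of magnitude above the
other terms.

Cluster-level scores average the 4 best members of each pose cluster
("best-4" convention) and report the standard error `sigma / sqrt(N)` with
the sample standard deviation and `N = 4` (or the member count for smaller
clusters, which are flagged). Which score picks the best 4 is configurable
(`--best4-by`); by default the same score being ranked is used, which is
symmetric across scoring functions.

## Poisson-Boltzmann solver

The polar term comes from an internal finite-difference solver for

    div(eps grad u) - kbar^2 sinh(u) = -4 pi C rho,

with `u` the reduced potential (kT/e), `eps` the node-wise dielectric
(solute 2, solvent 80), `kbar^2` the ion-accessibility-masked screening
factor, `rho` the trilinearly spread fixed charge density, and `C` the vacuum
Bjerrum length at the working temperature (296 K, where kT = 2.4611 kJ/mol).
Defaults: 0.15 M 1:1 salt, 1.4 A solvent probe, 2.0 A Stern (ion-exclusion)
layer, 0.5 A fine grid spacing, nonlinear equation (the sinh term matters
only where salt is present; at zero salt the problem is exactly linear).

Numerical choices:

- **Molecular volume.** Two passes: nodes inside any atom sphere are solute;
  nodes inside the probe-expanded spheres revert to solvent wherever they lie
  within one probe radius of a probe-center-accessible node (computed with a
  Euclidean distance transform). This approximates the Connolly surface on
  the grid; re-entrant necks remain solute, isolated-atom probe shells do
  not.
- **Face dielectrics** are harmonic means of the adjacent node values
  (flux continuity across the dielectric boundary).
- **Charge spreading** is trilinear to the 8 surrounding nodes; total charge
  is conserved exactly, and the resulting (large) grid self-energy cancels
  exactly in the solvated-minus-dry difference below.
- **Boundary conditions.** The coarse grid uses a superposition of
  Debye-Huckel screened sphere monopoles; the fine grid interpolates the
  coarse solution (focusing); the "dry" reference uses unscreened
  Coulomb/eps_int monopoles.
- **Focusing grids.** Boxes are the complex's coordinate extremes padded by
  20 A (coarse) and 10 A (fine) on every side. The fine grid always honours
  the requested spacing; the coarse grid runs at twice that spacing
  (`coarse_spacing_factor = 2`), since it only supplies boundary potentials
  whose error decays over the 10 A margin. Matching coarse and fine spacing
  changes a Born-ion energy by under 1% (tested) at several times the cost.
- **Linear algebra.** Each linear(ised) problem is solved matrix-free by
  Jacobi-preconditioned conjugate gradients on the SPD 7-point system to a
  relative residual of 1e-6; the nonlinear equation adds damped Newton steps
  (sinh linearised about the current iterate, updates clipped at 2 kT).
- **Energies.** `G = 1/2 sum q_i u_i * kT` over grid charges. Each state's
  polar solvation is the solvated energy minus the energy in a uniform
  eps = 2 "dry" medium **on the same grids**; all six calculations (three
  states, two environments) share the grid pair built from the complex, so
  grid placement cancels in the binding difference.

Accuracy against the closed-form Born sphere (q = 1 e, eps 2 -> 80, no
salt, 0.25 A fine spacing): within 3% for radii 1.5-3.0 A; doubling the
charge reproduces the quadratic scaling within 1%. Shifting a toy dimer by
half a grid cell moves the binding polar term by under 2 kJ/mol at 0.25 A
spacing. Absolute polar energies remain solver-flavour-dependent (charge
spreading, surface construction, and boundary treatment all shift them),
which is why benchmark-scale absolute energies are not comparable across PB
implementations; correlations and differences are the meaningful outputs.

## MM term conventions

Shifted Coulomb `C q1 q2 / (eps r) * (1 - (r/rc)^2)^2` and X-PLOR switching
`S(r) = (rc^2 - r^2)^2 (rc^2 + 2r^2 - 3ron^2) / (rc^2 - ron^2)^3` follow the
CNS conventions used by the docking engine whose output this package rescores.
The MM dielectric defaults to 1 (explicit-water refinement convention);
implicit-solvent screening lives entirely in the PB term. LJ cross parameters
use geometric-mean combination for both sigma and epsilon. The preferred
source of MM terms is the parsed per-pose energy table from the docking run;
direct computation from the structure is the self-contained fallback, and the
output records which source was used. In fallback mode the desolvation and
restraint-violation terms of the empirical docking score default to zero and
that score is flagged "partial".

## Surface area

Shrake-Rupley sampling with a deterministic Fibonacci-spiral point set (960
points by default; no random seed enters, so SASA is bit-reproducible). An
isolated sphere agrees with `4 pi (r + probe)^2` within 2% at 960 points and
within 0.5% at 3840; two-sphere overlaps agree with the exact spherical-cap
formula within 1%. The same PQR radii feed the PB dielectric boundary and
the SASA calculation. BSA is reported as the positive magnitude
`(SASA_receptor + SASA_peptide) - SASA_complex`; published benchmark tables
print positive BSA although the literal complex-minus-free definition would
be negative — the positive magnitude is used here and the sign difference
treated as an erratum of that definition. `G_nonpolar = gamma * SASA` with
`gamma = 0.0227 kJ mol^-1 A^-2` and zero offset.

## Evaluation

The interface is defined on the reference structure as all residues with any
heavy-atom cross-contact within 10 A; i-RMSD is the backbone (N, CA, C, O)
RMSD over those residues after optimal least-squares superposition, and poses
under 2 A are near-native. The published protocol defers the exact interface
definition to its docking engine; the 10 A heavy-atom / backbone-fit choice
here follows common docking-assessment practice and is configurable. Pose
clustering is greedy neighbour-counting on the pairwise i-RMSD matrix
(largest neighbourhood first, ties to the lowest index, default 2.5 A
cutoff). Success curves report, per N, the percentage of systems with a
near-native pose among the best-4 members of the top-N clusters.

Pearson correlations carry two-tailed p-values from the exact t distribution
with n-2 degrees of freedom; the Fisher-z Gaussian approximation is available
behind a flag and differs negligibly at n = 19. Shapiro-Wilk is Royston's
algorithm (via scipy, cross-checked against an independent R run).
`dG_bind = RT ln K_D` at 298.15 K by default; the published K_D / dG_bind
pairs are internally inconsistent with any single temperature for two
systems, so printed dG_bind values are treated as authoritative and the
conversion is tested at +-0.5 kJ/mol where the rows are self-consistent.

## Alanine scanning

`ddG = dG_wt - dG_mutALA`: the addressed residue's side chain is truncated at
CB, CB is retyped to alanine (charge/radius/LJ from the bundled table), and
nothing is repacked or minimised (single-structure end-point convention).
Under this sign convention a mutation that removes favourable interface
contacts gives **negative** ddG (the wild type binds more strongly); the CLI
additionally prints the negated "binding loss" so the sign cannot be
misread. Wild type and mutant are always solved on the grids built from the
wild-type complex, so grid-placement artifacts cancel in the difference;
mutating an uncharged side chain 12 A from the interface changes the score
by well under 1 kJ/mol (tested). Gly (no CB), Pro (cyclic backbone), and Ala
targets are rejected. Over an ensemble (e.g. an NMR bundle) the mean and
`sigma/sqrt(N)` standard error are reported.

## Input handling

PQR is the native structure format (whitespace-separated, charge and radius
in the last two numeric columns; both the 10- and 11-field dialects are
read, only the 11-field dialect is written). Plain PDB decoys are read with
charge/radius/LJ assignment from a bundled reduced amino-acid table
(simplified OPLS-flavoured united-heavy-atom charges with integer residue net
charges, Bondi-based PB radii; provenance in the data file header). The
table is a documented stand-in: the original benchmark never states its
radius/charge subset, which is one reason absolute energies are not
transferable. Missing table entries are an error, never a silent skip;
hydrogens are not built; altloc B+ atoms are dropped with a warning and
insertion codes rejected, since docking decoys have neither. Per-pose energy
tables are TSV with header `pose_id e_elec e_lj e_desolv e_air bsa`; a
tolerant mapping from HADDOCK 2.1-style column names is available behind a
flag because that format is version-dependent.

## Synthetic data

The fixture generators are first-class, seeded (counter-based Philox, so
byte-identical across platforms) and emulate the *statistical* structure of
docking output, not protein physics:

- `toy_complex` — a ~27-atom two-chain complex held by one cross-interface
  salt bridge (+0.6/-0.6 e at ~3-4 A), with per-seed jitter.
- `make_decoys` — rigid peptide displacements from 0 to 25 A (rotation
  proportional to translation), guaranteeing near-native (< 2 A i-RMSD) and
  far (> 8 A) poses in every default ensemble; the generating transform is
  recorded. The default 200 poses mirror a standard docking run's output
  size.
- `decoy_energy_table` — MM terms computed from the poses; desolvation and
  restraint columns are *synthetic* seeded noise, since those are docking
  outputs this package only reads.
- `synthetic_benchmark` — score columns built as `r z + sqrt(1-r^2) eps`
  around experimental-range dG_bind values (uniform on [-45, -17] kJ/mol),
  so the population correlation equals the requested `target_r` (sign
  flipped for the BSA column). The mean sample correlation at n = 19 over
  500 seeds is within 0.05 of the target (tested).

Passing tests on these fixtures demonstrates correctness of the machinery
(energies, identities, ranking, statistics), not predictive performance on
real complexes: the toys have no secondary structure, no realistic force
field, and interfaces of a handful of atoms.

## Problem sizes and desk-scale limits

Tests and the acceptance script run Born ions at 0.25 A spacing and toy
complexes at 0.6-1.0 A spacing with reduced pads; these sizes exercise every
code path at interactive cost, and the Born oracle pins absolute accuracy at
the fine-spacing end. The following published results are **out of reach at
desk scale** and are deliberately not reproduced: the success-rate-vs-N
curves over the 19-complex benchmark, per-complex absolute energies and
their standard errors, the five-mutant alanine-scan correlations
(R = 0.88/0.86) on the NMR-bundle case study, and the single-pose
correlation ranges — all require the external PDB/NMR structures plus full
docking runs. What stands in for them: the in-package correlation row
recomputed from the printed benchmark columns, the Born/SASA/MM closed-form
oracles, the exact dampening identity, and the calibrated synthetic
benchmark recovery.

## Known limitations

- Absolute `dG_comp` values are large compared with experimental binding
  free energies (a known property of end-point estimates without entropy);
  only differences, rankings, and correlations are meaningful.
- The PB solver has no multigrid preconditioning; very fine grids on large
  complexes are slow. No periodic boundaries or membrane slabs.
- SES triangulation, curvature-corrected nonpolar models, Fnat/DockQ
  metrics, and docking itself (pose generation, restraint handling,
  desolvation potentials) are out of scope.
- The bundled parameter table covers the 20 standard amino acids (heavy
  atoms + backbone amide H); ligands and modified residues must arrive as
  PQR.
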