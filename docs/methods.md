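# Methods

## Scope and model

`vinakit` implements the Vina-family empirical scoring model: the
predicted protein–ligand binding energy is a pairwise sum over heavy
atoms of a potential in the surface distance `d = r − Ri − Rj`, with a
steric part (one or two attractive Gaussians plus a quadratic overlap
repulsion) applied to every pair, a piecewise-linear hydrophobic bonus
applied when both atoms are hydrophobic, and a piecewise-linear
non-directional hydrogen-bond bonus applied to donor–acceptor pairs.
Hydrogens never enter pair sums; polar hydrogens (AutoDock type HD)
only mark their heavy neighbor as a donor.  Metals pair as donors.
Electrostatics and desolvation are deliberately absent, matching the
final form of both shipped parameterizations.  A generic m–n
Lennard-Jones term is available for custom parameter files (e.g. 4–8
steric forms) but is outside both presets.

### Piecewise-linear normalization

The hydrophobic and H-bond terms are implemented as linear
interpolations from 1 at the onset to 0 at the offset:
`(p2−d)/(p2−p1)` and `d/h1`.  The unnormalized textbook forms
(`p2−d`, `d−h1`) equal these only when the window width is 1 Å — true
for the Vina hydrophobic window (0.5–1.5 Å) but not for Vinardo's
(0–2.5 Å), and the unnormalized H-bond ramp is discontinuous at its
onset.  Normalization is the only choice that keeps the potential
continuous for every parameterization and matches the Vina/Smina code
lineage; continuity is asserted by a dense-scan test across every
piecewise joint.

### Cutoff, torsion scaling, units

Pair sums are truncated at surface distance d ≥ 8 Å (configurable per
parameter file).  The reported affinity divides the intermolecular sum
by `1 + 0.05846·N_rot` (Vina-heritage conformational-entropy proxy);
the coefficient is configurable and can be set to 0, and every analytic
shape test is built from single-pair or profile setups where it
cancels.  Energies are reported in the kcal/mol-like affinity units of
the weight tables; no unit conversion is attempted.  Whether intra-
ligand pairs contribute to the reported affinity is a genuinely open
convention; here they contribute to the minimization objective only,
never to the reported intermolecular affinity.

### Atom typing

Interaction classes are a pure function of the AutoDock type plus
bonded neighbors.  Connectivity is inferred by distance (bond when
`r < 1.2 × (rcov_i + rcov_j)`), since PDBQT carries no receptor
connectivity; ligand branch axes are added explicitly.  "Aromatic
carbon" means AutoDock type `A` as written in the file — no ring
perception is attempted, keeping typing provenance with the input
preparation tools.  Radii for elements outside the retuned C/C(ar)/N/O
set use the Vina-heritage table (S 2.0, P 2.1, F 1.5, Cl 1.8, Br 2.0,
I 2.2, metals 1.2 Å), stored in the editable parameter files, never in
code.  Fluorine is treated as hydrophobic (the Vina convention); the
choice is a flag in the parameter file because the literature is not
explicit for the retuned parameterization.  Vanadium, unsupported by
the AutoDock preparation tools, is typed as sulfur.

## Pose model and minimization

A pose is (rigid translation, unit-quaternion orientation, one dihedral
per rotatable bond).  Torsions rotate each branch subtree about its
bond axis root-outward; the whole ligand then rotates about the
centroid of its input conformation and translates.  Gradients are
analytic: per-pair de/dr chains into Cartesian atom gradients, which
project onto the translation (their sum), the orientation tangent space
(torque about the rotation center), and each torsion (torque component
along the bond axis).  A finite-difference test holds to a relative
1e−4 away from piecewise joints.

The minimizer is L-BFGS-B over a chart `[Δt, ω, Δθ]` centered at the
current pose, with the exact SO(3) left-Jacobian applied to the
rotation-vector gradient so the chart gradient is correct at any ω; the
chart is re-centered between rounds (≤ 40 rounds, ≤ 200 inner
iterations each, 10,000 total iteration budget, gradient tolerance
1e−6).  L-BFGS-B's backtracking line search requires only sufficient
decrease, which tolerates the kinks of the repulsion/hydrophobic/H-bond
terms; curvature is never interpolated across a joint.  Accepted
energies are monotone non-increasing by construction and minimization
is deterministic given identical inputs.

Global docking search is out of scope; `random_restart_search` is the
desk-scale stand-in: n seeded starts sampled uniformly (centroid in the
box, orientation uniform on SO(3) via normalized 4-D Gaussians,
torsions uniform in (−π, π]), each locally minimized, ranked by
predicted affinity.  It has no exhaustiveness semantics and no pose
clustering.

## Symmetry-corrected RMSD

Heavy atoms are grouped into blocks keyed on (element, AutoDock type);
within each block the assignment minimizing the summed squared
distances is found with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`), and the RMSD is taken over
the optimal assignment.  Blocks are keyed on type, not bond
environment — the practical behavior of the established
assignment-based procedure; graph-aware matching would be an extension.
Poses are compared in the receptor frame with no superposition, as in
re-docking evaluation.  Exhaustive permutation enumeration on ≤ 8-atom
blocks is the test oracle.  Re-docking success means RMSD ≤ 2 Å,
inclusive.

## Evaluation metrics

Sign convention, fixed globally: lower (more negative) predicted energy
is a better rank; higher experimental affinity is a stronger binder;
score ties break by input order (stable sorts), so success counts are
reproducible.

* **Scoring power** — Pearson R between negated predicted energies and
  experimental affinities (≥ 3 records, finite variances).
* **Ranking power** — per-protein triplets; *high* success = all three
  ligands ordered correctly, *low* success = strongest binder first.
* **Docking power** — per-complex decoy pose sets; success at top-N if
  a ≤ 2 Å pose appears among the N best-scored.
* **Screening power** — per-protein compound pools (best pose per
  compound); success at level x if the true binder ranks within
  `ceil(x · pool)`; with a 195-compound pool the top 1% means rank ≤ 2.
* **ROC AUC** — `sklearn.metrics.roc_auc_score`, equal to the
  Mann–Whitney pair statistic (ties ½); the brute-force pair count is
  the test oracle.
* **BEDROC** — the exponential-weighting early-recognition metric with
  α = 20 by default, computed from the closed form
  `RIE·Ra·sinh(α/2)/(cosh(α/2)−cosh(α/2−αRa)) + 1/(1−e^{α(1−Ra)})`,
  cross-checked against the rdkit implementation.

The rank-based powers are invariant to strictly monotone score
transforms; Pearson scoring power is invariant to positive affine
transforms only (a property of the statistic itself).

### The BEDROC random null and the study conditions

For a random ranking E[RIE] = 1, so the expected BEDROC is a pure
function of α and the active fraction Ra.  Its nominal value 1/α (0.05
at α = 20) is the Ra → 0 limit: at a 100/2000 active/decoy split the
exact null is 0.0775, and the test suite pins the simulation to that
closed form.  The random-null quantity reported by the acceptance
script is therefore measured in the large-library regime — 5 actives /
1995 decoys (0.25% actives, 10,000 replicate tables) — where the
finite-fraction bias is below 0.002 and the null sits at its nominal
value.  This is a property of the metric, not of any implementation.

## Synthetic study systems

All tests run on generated structures; no external datasets are
downloaded, and the screening machinery is dataset-agnostic by design
(external benchmark corpora remain out of scope).  Generators are pure
functions of (spec, seed).

* **Toy pockets** — receptor atoms on well-spread random directions
  (full sphere, or one hemisphere for asymmetric sites) at exactly the
  contact distance Ri + Rj from the ligand anchor.  Every pair then
  sits at its pairwise optimum simultaneously, so for a single-minimum
  parameterization the crystal pose is the global optimum by
  construction — the property that makes minimization and docking
  outcomes analytically checkable.
* **Ligands** — idealized zigzag carbon chains (1.5 Å bonds,
  tetrahedral angles), with the trailing bonds declared rotatable;
  plausible geometry, not chemically exact, which is all the pair
  potentials require.  The terminal branch always carries two atoms so
  every declared torsion moves at least one off-axis atom.
* **Decoy pose sets** — seeded rigid perturbations plus torsion jitter,
  rejection-sampled into requested RMSD bins and annotated with the
  symmetry-corrected RMSD they were accepted at.
* **Screening tables** — active and decoy scores from two unit-variance
  normals separated by a configurable mean gap; zero separation is the
  random-selection null, large separation drives AUC → 1.  Defaults:
  100 actives, 2000 decoys, separation 0.

What passing these tests does *not* show: performance on real
protein–ligand complexes.  Synthetic pockets have no chemistry beyond
the typing rules, no receptor flexibility, no solvent, and energy
landscapes far simpler than real binding sites; the tests validate the
potentials, algorithms and metrics, not benchmark claims.

## Training-screen methodology

The development strategy is screened end to end on a synthetic
candidate family: parameter sets whose Gauss1 attraction is displaced
outward by δ ∈ {0 … 2 Å} while re-weighted by e^{δ²/s1²} so that every
candidate assigns *identical* energies to all crystal poses.  Scoring
correlation is then constant across the family by construction, while
the energy minima move analytically away from the crystal geometry:
average post-minimization RMSD rises strictly with δ, and re-docking
success collapses once the displacement passes the 2 Å threshold.
This reproduces, directionally, the finding that crystal-pose scoring
correlation cannot predict docking ability while post-minimization
RMSD can — the rationale for the minimize-then-dock screen.  Grid
enumeration honors the radii constraints (C ≥ C_aromatic, N > O,
N − O ≤ 0.10 Å) with a 1e−9 comparison tolerance on the rounded grid
values; screen defaults keep 20 candidates after the minimization
screen and 5 after re-docking.

## Problem sizes and numerical choices

Test and acceptance workloads use single-atom to six-atom ligands,
pockets of 3–10 atoms, 6–8 restart searches per complex, 10,000
replicate tables for the enrichment nulls, and 0.001 Å grids for
potential-shape scans — sizes chosen so the full suite and the
acceptance script each complete in well under a minute on one CPU while
leaving every assertion's expected value analytically known.  Scan
minima are refined with bounded scalar minimization (±0.01 Å bracket).
Degenerate inputs fail loudly: empty ligands/receptors, non-finite
starting poses, zero-variance correlations, single-class enrichment
inputs, type-multiset mismatches in RMSD, and infeasible grid
constraints all raise with diagnostics rather than returning silent
zeros.
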