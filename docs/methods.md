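# Methods

`loopcsa` rebuilds a protein loop — a contiguous segment whose conformation
is unknown while the rest of the structure (the *framework* or
*environment*) stays fixed — by global optimization of a hybrid
physics/knowledge-based energy over the loop's torsional degrees of
freedom, with the chain kept analytically closed onto the C-side anchor at
every step.  This note records the model, its assumptions, the parameters
that matter, and the choices made where the design was genuinely open.

## Structure model

Structures live in a polar-hydrogen (united-atom) representation: heavy
atoms plus hydrogens on N, O and S only; carbon-bound hydrogens are folded
into their carbons, which carry enlarged Lennard-Jones radii.  The packaged
parameter table (`data/atom_classes.txt`: 28 atom classes with charge,
rmin/2, well depth and surface tension) is a reduced, self-contained set
written for this package: charged side chains carry integer net charge,
neutral residues are neutral to within ~0.1 e, and radii/depths are in the
range conventional united-atom force fields use.  It is a *functional*
parameter set — the package's claims are about the functional forms and the
optimization protocol, not about reproducing any published force field's
numbers — and users can substitute their own table.

Loop degrees of freedom are backbone phi/psi per loop residue (omega held
trans at 180 deg, or cis at 0 deg for flagged cis-prolines, which sampling
preserves but never creates) and side-chain chi angles.  Rebuilds extend
the chain from the N-side anchor at ideal bond lengths and angles, so the
C-side anchor is only met after a closure step.  Proline's ring is fixed at
a single pucker and contributes no rotatable chi.  Missing side-chain atoms
in input structures are rebuilt at measurable chi values, falling back to
the most common rotamer.

## Tri-axial loop closure

With all non-pivot torsions frozen, choosing (phi, psi) at three pivot
residues so the chain meets the C-anchor is a classic inverse-kinematics
problem with up to 16 discrete solutions.  The implementation exploits the
kinematic structure directly: CA of the first and third pivots are fixed
points, CA of the middle pivot lies on the circle where two fixed-radius
spheres intersect, and for each circle angle the remaining freedom reduces
to two two-branch cone conditions (phi1 and psi3) plus one scalar
constraint — the N-CA-C angle at the middle pivot.  Scanning the circle
angle over a 1024-point grid for the four branch combinations, refining
brackets by vectorized bisection, and explicitly locating the
cone-feasibility boundaries (solution windows can be far narrower than any
fixed grid) enumerates the solution set.  This is numerically equivalent to
the classical reduction to a degree-16 polynomial; the root-bracketing form
was chosen because it made the near-tangent solutions explicit and testable
rather than hidden in polynomial conditioning.  Every returned solution is
verified by forward kinematics; anchor mismatch is below 1e-6 A in
practice against a 1e-4 A contract, and self-closure tests (delete the
pivot torsions of a closed loop, ask for them back) recover the original
assignment in 100% of tested problems.

A windowed variant (`tlc_solve_local`) searches only around the current
circle angle; it is the cheap path for re-closing after the small torsion
perturbations made inside refinement.

## Initial sampling (fragment assembly with closure)

Initial conformations draw (phi, psi) for every loop residue from a
fragment library derived from the same Ramachandran statistics table used
by the torsion energy (top 120 bins per residue class, probability-
weighted, uniformly smeared within the 10-degree bin), then solve closure
for a uniformly chosen pivot triple (pivots separated by at least one
residue when the loop has five or more).  Among closure roots the one with
the fewest steric clashes wins (backbone N/CA/C vs. environment heavy
atoms, clash when closer than 0.7 times the summed radii), ties broken by
least total torsion change.  Side chains start at the most common rotamer.
A failed closure is retried with a fresh draw up to 50 times per sample.

## Energy function

E_total = E_bonded + E_vdW + w_elec (E_Coulomb + E_GB) + w_sa E_SA
        + w_phipsi E_phi/psi + w_chi E_chi + w_hbond E_Hbond
        + w_pair E_atom-pair,

with default weights (w_elec, w_sa, w_phipsi, w_chi, w_hbond, w_pair) =
(0.16, 0.05, 1.2, 1.0, 4.0, 12.0).  All terms are restricted to loop-loop
and loop-environment interactions; the environment-environment part is
constant during sampling and dropped.

* **Bonded**: harmonic bonds (300 kcal/mol/A^2) and angles (50
  kcal/mol/rad^2) with equilibria measured from the builder's own ideal
  residue geometry (so freshly rebuilt loops sit exactly at the minimum), a
  1-cos(2 omega) peptide planarity term (12 kcal/mol) and a harmonic
  carbonyl improper (15 kcal/mol/rad^2).
* **van der Waals**: 12-6 Lennard-Jones, rmin_ij = rmin_i + rmin_j,
  eps_ij geometric mean; 1-2/1-3 excluded, 1-4 scaled by 0.5; switched off
  between 8 and 10 A; linearly continued below 0.6 rmin_ij so minimizers
  never see an unbounded wall.
* **Electrostatics**: vacuum Coulomb (332.0716 q_i q_j / r, same switch)
  plus a generalized-Born pair term with Still's f_GB and effective radii
  from a pairwise HCT descreening sum (scale 0.8, solvent dielectric 78.5,
  radii floored at 1/30 A^-1 inverse).  The radius calculator sits behind
  the `born_radii` method so a different descreening model can be swapped
  in.  GB self terms are included for loop atoms.
* **Surface area**: per-class surface tensions times Shrake-Rupley areas
  (192 golden-spiral points, 1.4 A probe) over loop atoms and environment
  atoms within 8 A of the loop.  Sphere points are oriented along a
  canonical principal-axis frame of the system, making the term exactly
  invariant under rigid transforms rather than invariant only on average.
* **Torsion statistics**: bicubic periodically interpolated -ln(frequency)
  tables on 10-degree bins for (phi, psi) (classes: generic, GLY, PRO) and
  chi (pooled rotamer profile).  The packaged defaults are analytic
  mixtures of wrapped Gaussians over the canonical basins; `derive-tables`
  rebuilds both from any training set with pseudocount 1.
* **Hydrogen bonds**: an orientation-dependent well over donor-H/acceptor
  pairs: distance well centred at 1.95 A (half-width 0.65 A), donor-H-A
  well centred at linearity, H-A-base well centred at 120 deg, all
  -cos^2 shaped (zero value and slope at their edges) and gated by a
  smooth distance envelope that reaches exactly zero at 2.6 A — the sum is
  C1 everywhere with no value beyond the cutoff.
* **Atom-pair potential**: a distance-binned potential of mean force
  (0.5 A bins to 15 A, eight coarse heavy-atom classes) with the
  ideal-gas r^alpha reference (alpha = 1.61 by default, 2 exactly for an
  ideal gas), u = -RT ln[N(r) / ((r/r_ref)^alpha N(r_ref))], RT = 0.5917
  kcal/mol, pseudocount 1, last bin zero by construction.  Two robustness
  rules extend the formula for sparse training data: bins below a pair's
  first observed contact get a +3 kcal/mol plateau (excluded volume must
  not become attractive through pseudocount ratios), and pairs with fewer
  than 5 reference-shell counts are zeroed as signal-free.  The packaged
  default potential is derived from a deterministic set of clash-screened
  scaffold structures; it is a stand-in trained on synthetic data and is
  labelled as such.

Analytic Cartesian gradients are implemented for the bonded, van der Waals
and Coulomb terms and verified against central differences to 1e-5
relative; GB, SA, hydrogen-bond and knowledge terms are evaluated
energy-only (refinement uses derivative-free steps, so gradients of those
terms buy little).

## Global optimization (conformational space annealing)

A bank of N closed conformations (N = 30 for loops under 12 residues, 50
otherwise; seeds per iteration M = 10/20) is initialized by fragment
sampling and evolved for up to `n_iterations` rounds (default 50, 10
trials per seed).  Each round: the M lowest-energy members not yet used as
seeds are selected; each seed is crossed with a random partner by splicing
a contiguous torsion segment (2 to n/2 residues) and re-closing on pivots
flanking the splice (least-change root); the trial then undergoes up to 3
greedy side-chain exchanges with random bank members (keep iff energy
drops), a short noisy-descent shake (downhill-only random chi/backbone
proposals, backbone ones re-closed), and a local minimization that
alternates unconstrained torsion relaxation (Powell on a surrogate that
ignores closure) with least-change closure re-projection, accepting the
projected state only when it improves — so member energies are monotone
non-increasing through refinement.  The trial replaces its nearest bank
member (unsuperposed loop main-chain RMSD; anchors are shared so no
superposition is wanted) if that distance is under D_cut and the energy is
lower, otherwise the worst member if it beats it.  D_cut decays
geometrically from half the initial mean pairwise bank distance to a fifth
of it.  Runs stop early after 5 idle iterations.  The final model is the
lowest-energy bank member rebuilt into the full structure; every run is
bit-reproducible from its seed and its serialized `run_config.yaml`.

The refinement design was the one genuinely open choice: a per-step
closed-manifold Powell minimization (re-closing at every objective call)
was implemented first, but needed roughly thirty times more closure solves
to converge worse; the relax/re-project alternation keeps the closure
count per trial in single digits and reaches the planted optima in the
benchmarks below.

## Evaluation metrics

Loop main-chain RMSD is over N, CA, C, O; all-atom RMSDs are minimized
over two-fold symmetric side-chain relabelings (ASP, GLU, PHE/TYR rings,
ARG, LEU, VAL — per-residue greedy choice, which is exact because residues
contribute independent sums; HIS is excluded as its ring atoms are not
type-symmetric).  The environment of a loop is every other residue with an
atom within 10 A (closed interval) of a loop C-beta (CA for glycine), and
E-RMSD — the framework-accuracy measure — is the all-atom RMSD over those
residues after superposing them onto the reference, flips included.
Hydrogens are excluded from RMSD sums by default.  When frameworks are
inexact, loop RMSD can optionally be computed after environment
superposition, which deliberately lets environmental error leak into the
loop number.

## Fixtures and what they do (and do not) show

Benchmarks are ideal-geometry helix-loop-helix mini-proteins (28 residues,
8-residue loop, flanks within 5 deg of canonical helix torsions, loop
torsions drawn from the Ramachandran table).  Environment perturbation
emulates the framework-accuracy regimes on the measured axis: side-chain
mode resamples environment chi toward random rotamer draws, backbone mode
additionally adds chain-correlated Gaussian phi/psi noise (AR(1), rho 0.6)
and rebuilds; a scale parameter is bisected until the achieved E-RMSD is
within 0.15 A of the target (0.9 A side-chain, 2.1 A backbone).  This
reproduces graded environmental error as measured by E-RMSD; it does not
reproduce thermal ensembles, crystal packing, or real rotamer
correlations, so passing benchmarks demonstrate the machinery (closure,
scoring, optimization, calibration), not accuracy on crystallographic
loops.  The planted-native benchmark makes the recovery criterion sharp:
its loop uses eight distinct residue types, each with a phi/psi table
basin (20-degree wrapped Gaussian over a 30% uniform floor) centred at
the native torsions, so the global optimum of the table energy is the
known native conformation and optimizer success is measurable as a loop
RMSD.

## Problem sizes and numerical choices

Tests and the acceptance script use 8-residue loops in 28-residue
scaffolds, 1000+ closure problems, 1e5-sample table derivations, 20-seed
toy-landscape and 10-seed planted-native optimizations with compact CSA
budgets (bank 15-30, up to 10 iterations, 1 trial per seed, ~120 surrogate
evaluations per refinement); these sizes were chosen to make the
statistical assertions stable while keeping a full run in minutes on one
core.  Closure roots are deduplicated at 1e-3 degrees; bisection runs to
~1e-14 rad; degenerate inputs (collinear superposition sets, unreachable
anchor gaps, empty environments, loops spanning chain breaks) raise
structured errors or return empty solution sets as documented per
operation.

## Known limitations

The parameter set is reduced and untrained; no claim is made about
absolute energies.  The atom-pair potential's default training set is
synthetic scaffolds, not a curated structure database.  The GB term uses
HCT-style radii, not the finite-difference-fit context measure of faster
approximate solvation models, and the pair potential is distance-only (no
dipole-orientation dependence).  Weight re-training against decoy sets is
out of scope.  Environment backbone is never re-sampled — only loop
degrees of freedom and, through exchanges, environment-adjacent side-chain
packing on the loop side of the interface.
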