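# Methods

This note documents the models, parameters and numerical choices behind
`sitedock`, and what its synthetic test systems do and do not show.

## Scope and assumptions

The package predicts binding ligands, poses and site residues for
*non-metal* ligands of a single-chain protein target, given template
protein–ligand complexes with target↔template residue alignments and a
per-template similarity score. Template search and scoring (e.g. an
HHsearch-style pipeline) are upstream of this package: templates,
alignments and scores are inputs. Structure prediction of the target is
likewise external — any experimental structure or model in PDB format is
accepted, up to 500 residues (larger inputs are rejected by the pipeline
driver, not the reader). The protein is rigid throughout docking; the
ligand is fully flexible (rigid-body motion plus all acyclic,
non-terminal single-bond torsions). Waters, single-atom ions and metals
are never candidate ligands.

## Template filtering and ligand selection

Each template is superposed onto the target over the supplied alignment
by maximizing the TM-score (normalized by target length,
`d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8)`). The superposition search seeds
iterative least-squares refinement from every contiguous aligned
fragment of length ≥ 4 and keeps the best transform; this is
reproducible and directly checkable against an exhaustive oracle, which
is why it was chosen over a heuristic subset of seeds. TM-score cutoffs
(0.5 / 0.4 / 0.3 depending on whether the best template scores > 0.8,
> 0.6 or ≤ 0.6) are applied with *strictly below* semantics: a candidate
exactly at the cutoff is kept. When more than 30 templates are supplied
the 30 best-scored are kept first.

Ligand candidates are pooled by 3-letter component code. "Positional
variation" of a candidate is operationalized as the maximum pairwise
distance between the center atoms (atom nearest the ligand's geometric
center, ties to the lowest index; distances rounded to 1e-6 Å before the
tie-break so numerically equal distances tie) of its poses mapped into
the target frame; candidates above 10 Å are dropped. Max-pairwise was
chosen over RMS-about-mean as the simplest spread statistic; the cutoff
is a config value. Ranking is by summed template score, ties broken by
more supporting templates, then lexicographic code.

## Energy model

The physical term follows the AutoDock3 functional form: 12-6 van der
Waals with arithmetic-mean radii and geometric-mean well depths; 12-10
hydrogen bonds for donor/acceptor heteroatom pairs (O/N at 1.9 Å,
5.0 kcal/mol; S at 2.5 Å, 1.0 kcal/mol); Coulomb electrostatics with the
Mehler–Solmajer sigmoidal distance-dependent dielectric; and a
Gaussian-envelope desolvation term carried by carbon atoms. Empirical
coefficients (0.1485 / 0.0656 / 0.1146 / 0.1711) and all pair parameters
live in a versioned text table (`data/ad3_params.txt`) so the potential
is auditable and swappable. The torsional-entropy term is omitted: it is
constant per ligand and cannot change pose ranking. The model is
united-atom; hydrogens are excluded from scoring. Protein partial
charges come from a small fixed backbone table (N −0.35, CA +0.10,
C +0.55, O −0.55, side chains neutral); ligand charges are Gasteiger,
computed at load. Each interacting pair's summed energy is capped at
+1.0 kcal/mol — applied per pair, not per term — so clashes from
imperfect structures cost a bounded penalty. The nonbonded cutoff is
12 Å with no smoothing. Ligand internal energy sums capped pair energies
over heavy-atom pairs three or more bonds apart that move relative to
each other under some rotatable torsion.

Restraints are built from every template containing the selected ligand:
for each template protein heavy atom within 5 Å of the template ligand
whose residue is aligned, matched by atom name to the target, and scores
nonzero, one restraint per ligand atom records the template distance
`r_ref`, the width `d_jk` (floored at 0.5 Å — identical structures give
`d_jk = 0` and Eq. for the Gaussian divides by `d²`; 0.5 Å is roughly
coordinate precision) and the weight `ω = TM · ResidueScore ·
E(r_ref)/E(r_min)`, clamped to [0, 1]. The residue score compares
side-chain orientations *after* rotating the template vector through the
superposition (orientation vectors are frame-dependent); glycine, with
no side chain, scores 1.0 on an amino-acid match within the 2 Å
deviation gate; anti-parallel orientations clamp to 0 rather than going
negative, since the score feeds a non-negative weight product.
Restraints with weight below 1e-6 are dropped, as are pure-repulsive
type pairs (no negative minimum — the optimality ratio is undefined).
The restraint energy floors the inner weighted Gaussian sum at 1e-12
before the log, and ligand atoms with no positive-weight restraint are
excluded from the outer sum entirely — an unrestrained atom should not
contribute a constant −ln(ε) ≈ 27.6 to every pose.

The hybrid weight of the restraint term is 1.1.

## Conformational space annealing

The pose is parameterized as translation (the pose centroid), a unit
quaternion, and one dihedral offset per rotatable torsion, applied to a
shared reference conformation taken from the first template pose;
template poses are expressed in this parameterization through a
least-squares rigid fit. The initial pool holds exactly 100 poses made
by cycling the template poses round-robin and perturbing (σ = 1.0 Å
translation, 15° rotation, 30° torsion), each locally minimized.
Local minimization is derivative-free Nelder–Mead over the 6+n_torsion
parameters with an explicitly scaled initial simplex (0.3 Å / ~0.2 rad)
— the default simplex barely perturbs zero-initialized coordinates and
stalls — and never returns a pose worse than its input. Each CSA round
generates trials by crossover (torsion-subset swap, translation
interpolation, quaternion slerp between two random pool members) and
mutation (fresh perturbation); a minimized trial replaces the worst
member of its `d_cut` neighborhood if better, else the global worst if
better, else is discarded. `d_cut` anneals geometrically from half the
initial pool diameter to 1.0 Å across the evaluation budget; the run
stops at the budget or after 5 replacement-free rounds. Pose distance is
heavy-atom RMSD in the fixed protein frame (no re-superposition),
minimized over element-preserving graph automorphisms so an aromatic
ring flip is the same pose. These internals (σs, operators, schedule,
stall rule) are documented configurable defaults of this implementation,
chosen to realize the annealing behavior, not claims about any
particular published optimizer's internals.

The final pool is clustered by single linkage at 2.0 Å (a standard
docking-pose clustering radius); the representative is the lowest-energy
member of the largest cluster, with size ties going to the cluster
holding the lower-energy pose. Binding-site residues are those with any
heavy atom within 4.5 Å of the pose (a common contact convention; a
vdW-sum + margin mode is available), and MCC is computed from the
residue-level confusion matrix with degenerate marginals scoring 0.

Every stochastic entry point takes an explicit seed; identical seeds and
inputs give bitwise-identical pools, clusters and summaries.

## Synthetic systems

The fixture generator builds a two-helix bundle (ideal helical Cα trace,
approximate N/C/O backbone positions, a radially outward CB pseudo-atom
as the side-chain centroid) with a small generic ligand — a bent
triatomic ether, a benzene-like ring, or a flexible carbon chain —
planted in the inter-helix groove. Templates are noisy copies of the
target (rigid per-residue Gaussian jitter of chosen σ, which controls
both the measured TM-score and the per-residue deviations `d_jk`),
carrying the planted ligand optionally displaced per template to realize
an exact center-atom spread, each written in its own random rigid frame.
A single surface-attached helix was rejected: it offers only ~3 nearly
coplanar restraint anchor atoms from one residue, which leaves a mirror
ambiguity in any distance-restraint landscape and turns pose-recovery
tests into tests of geometry, not of the optimizer. The truth record
(planted pose, binding residues, per-template transforms) is written
alongside the system.

These systems emulate the *geometry* of template-based docking —
controlled structural similarity, planted contacts, consistent or
scattered ligand placements — but not protein chemistry: sequences are a
fixed rotation of ten residue types, side chains are single
pseudo-atoms, and ligands are generic. Passing tests therefore
demonstrate that the machinery (superposition, filtering, restraint
construction, annealing, clustering, site extraction) behaves as
specified, not that prediction accuracy on real proteins matches any
benchmark.

## Problem sizes

Tests and the acceptance script run on 20–24-residue systems with 3–5
atom ligands, pools of 100, and budgets of a few thousand energy
evaluations per run — sizes at which enumeration oracles (exhaustive
fragment-seeded superposition, 6-D pose grids at 15°/0.25 Å, naive
double-loop restraint sums, O(n²) single-linkage) are exact and fast.
The CLI default budget is 50 000 evaluations per ligand.

## Known limitations

Protein flexibility, ensemble docking and covalent ligands are out of
scope. mmCIF input is not supported. Bond perception for HETATM groups
without an SDF sidecar is distance-based and single-bond only (ring
carbons are still typed aromatic for the potentials). The desolvation
parameters are modest defaults in the parameter table, not a fitted
set. Ligand identity is keyed by component code, so chemically similar
ligands with different codes are not pooled.
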