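# Methods

## Scope and model

`xldock` converts two kinds of live-cell crosslinking observations on a
peptide–receptor complex into geometric constraints, samples peptide
poses against them, and audits models and trajectories for constraint
satisfaction. It does not perform all-atom refinement, force-field
molecular dynamics, receptor backbone flexibility, or homology modelling;
those belong to production modelling suites. The package's claims are the
restraint logic itself and pose recovery on synthetic systems with known
ground truth.

### Crosslinker geometry and reach

Each pair-wise crosslink chemistry is described by a `CrosslinkerSpec`:
anchor-atom kinds on both sides, an upper-bound distance `d0`, and the
covalent chain of the crosslinked product as ideal internal coordinates.
The built-in registry:

| name | anchors | d0 (Å) | product chain |
|---|---|---|---|
| `LYS_CLAC_CYS` | Cβ ↔ Cβ | 10 | Cβ–Cγ–Cδ–Cε–Nζ–C(O)–CH2–S–Cβ |
| `NTERM_CLAC_CYS` | Nα ↔ Cβ | 5 | Nα–C(O)–CH2–S–Cβ |
| `AZI_PHOTO` | Cβ → nearest ligand heavy atom | 9 | (proximity probe, no chain) |

Bond metrics are standard ideal values for the actual chemistry of the
product: aliphatic C–C 1.53 Å with 111° angles, Cε–Nζ 1.47 Å, amide C–N
1.35 Å with sp² angles (121.7° at N, 116.5° at the carbonyl carbon),
C–S 1.81 Å, thioether C–S–C 98.9°. The carbonyl oxygen is off-path. We
deliberately use amide/thioether-specific values rather than a uniform
tetrahedral/trigonal assignment: the uniform variant overstates the
extended-chain reach by ~0.3 Å, while the chemistry-specific values put
the planar all-trans reach at 10.13 Å (Cβ–Cβ) and 5.19 Å (Nα–Cβ),
matching the whole-ångström crosslinking cutoffs of 10 Å and 5 Å that
the restraints use.

**Reach sampling.** `linker_reach` draws rotatable torsions i.i.d.
uniform on (−180°, 180°] — a free-molecule assumption with no Boltzmann
weighting — while amide torsions stay trans, and reports the
anchor–anchor distance distribution. Coordinates come from a vectorised
natural-extension-reference-frame (NeRF) chain builder. An exhaustive
torsion grid (`reach_grid`, trans point included) serves as an
independent check of the sampled maximum. Two numerical facts matter
here: (i) the sampled maximum can *slightly exceed* the planar all-trans
value when bond angles are heterogeneous (by ~0.02 Å for the lysine
chain), so the rigorous invariant is max ≤ Σ bond lengths, with the
all-trans value a near-bound; (ii) with 10⁵ samples the maximum is
within ~0.05 Å of the grid optimum for these chain lengths.

`AZI_PHOTO` has no pair-wise chain: it is a validation-only probe and is
never turned into a docking restraint.

### Hit calling

A photo-scan gives one band intensity per (ligand, receptor position).
Per ligand, the threshold is `threshold_fraction` × the maximum intensity
of that ligand (default 0.5), and a position is a hit when its intensity
is *strictly greater* (configurable to ≥ for sensitivity analysis). The
rule is scale-invariant per ligand, and raising the fraction can only
remove hits; both properties are tested. An all-zero ligand produces an
empty footprint with a warning, not an error. Intensities are taken as
already-quantified numbers — densitometry is out of scope.

### Restraints and scoring

Every pair-wise hit becomes one flat-bottom harmonic restraint with its
crosslinker's anchors and `d0`: E = 0 for d ≤ d0 and k(d − d0)² above,
continuous at d0. The default weight k = 10 energy/Å² is the weight used
when such restraints steer restrained molecular-dynamics runs; published
restrained-docking protocols do not state their weight, so one default
serves both contexts (flagged in the configuration documentation).
Satisfaction is inclusive (d ≤ d0), consistent with zero penalty at the
threshold. Reports round distances to 0.1 Å in text output and keep full
precision in JSON. Because published tables sometimes count a borderline
distance (e.g. 9.4 vs 9.0) as satisfied, validators expose an optional
`slack` parameter, default 0, rather than guessing an implicit tolerance.

Glycine has no Cβ; a virtual Cβ is constructed from backbone N/CA/C with
ideal tetrahedral geometry at 1.53 Å from Cα (never a Cα fallback), which
preserves Cβ–Cβ distance semantics and commutes with rigid motions.

### Docking sampler

The peptide is reduced to five atoms per residue (N, CA, C, O, Cβ) with
ideal internal geometry; coordinates regenerate exactly from (φ, ψ) plus
a rigid-body frame. ω is fixed trans. Starting folds: α-helical
(φ, ψ = −57°, −47°) or extended (−120°, 120°); the synthetic generator
adds a "kinked" variant (helical with two loop residues) mirroring the
bent agonist fold.

Scoring is deliberately minimal: a soft-sphere clash term
Σ k_clash·max(0, r_min − d)² over receptor–peptide heavy-atom pairs
(single r_min = 3.0 Å, k_clash = 1) plus the restraint penalties. The
receptor is **rigid** — the major simplification of this desk-scale
artifact relative to production protocols that relax side chains and
backbone hinges around the ligand.

Sampling is Metropolis Monte Carlo: moves are one-torsion perturbations
(40%, σ 12°), rigid translations (30%, σ 0.6 Å) and rigid rotations about
the peptide centroid (30%, σ 8°), under a four-stage temperature ladder
(25, 5, 1, 0.1) with move amplitudes annealed as √(T/T₀). The default
budget of 5·10⁴ steps is a desk-scale stand-in for production samplers
that spend >10⁷ steps. After sampling, the best pose undergoes a
deterministic quasi-Newton refinement of torsions + frame
(Monte-Carlo-minimisation style); it is accepted only if it does not
increase the energy. Replicas derive independent seeds from one master
seed, and a run is bit-reproducible per seed on one platform.
Contradictory restraints are not an error: the best pose is returned
with residual restraint energy and an `infeasible` flag.

### Validation and cross-validation

`measure_restraints` reports per-restraint distance, satisfied flag and
margin; `validate_photo` checks each footprint residue's Cβ against the
nearest ligand heavy atom (hydrogens excluded by element) at the 9 Å
probe radius. `cross_validate` measures a *foreign* restraint set in a
model after remapping ligand positions through an explicit
homologous-position table (e.g. an offset-by-one peptide pair); maps are
data, never inferred by sequence alignment, because published homolog
pairs encode one-off offsets rather than a general alignment rule. Rows
that cannot be mapped or resolved are reported untestable, never
silently dropped.

### Trajectory analysis

Trajectories are multi-model PDB — the lowest-common-denominator
container for snapshot series; binary formats would be adapters, not
core. Per-restraint distance traces carry `fraction_within` (fraction of
frames with d ≤ d0); minimum-distance traces track a probe Cβ against
all heavy atoms of a target chain; `displacement_summary` reports
centroid displacement and backbone RMSD of a region after least-squares
superposition on a caller-chosen anchor region (default receptor
backbone), since published figures do not state their fitting region.
`RunProtocol` books the restrained-then-free phases of a run (restraints
switched off after a stated time, e.g. 20 ns).

## Synthetic generator

`make_bundle` places ideal poly-alanine α-helices (rise 1.5 Å/residue,
100°/residue) antiparallel on a ring (default 7 helices of 25 residues,
ring radius 11 Å — helix-axis spacing 9.5 Å, comfortably above the
7.5 Å overlap limit), one receptor chain R with a 2-residue numbering gap
between helices and a helix-position generic-numbering map.
`plant_peptide` builds the peptide (chain L) in a named fold, centres it
in the pore along the bundle axis, rejects placements with heavy-atom
contacts under 2.5 Å, and records ground truth directly from
coordinates: photo truth = receptor residues whose Cβ is within 9 Å of
any peptide heavy atom (definitionally the validator's criterion), pair
truth = all anchor pairs within each pair-wise crosslinker's d0.

`simulate_photo_scan` assigns in-reach residues I = I_max·exp(−d/λ)
(defaults I_max 100, λ 4 Å — a decay length that puts hits called at the
50% rule within ~2.8 Å of the closest contact distance) and background b
(default 1) otherwise, with optional multiplicative lognormal noise; the
intensity law is an artifact choice, since no quantitative intensity
model is published. `simulate_pairwise` emits exactly the truth pairs
minus a seeded false-negative dropout. `perturb_trajectory` applies
smooth deterministic motion — rigid linear translation of the ligand
(`global_sway`, closed-form distance truth) or translation of a single
receptor residue (`local_loop`, a flexible-loop caricature).

What passing on these systems does *not* show: robustness to blot
saturation, position-dependent probe reactivity, expression variation,
receptor flexibility, or sequence-realistic energetics. The generator is
geometric ground truth, not biophysics.

## Problem sizes and defaults

The test suite and examples use the 7×25-residue bundle with an 8-mer
peptide, 10⁵ reach samples, 5·10⁴ docking steps and 10 recovery seeds —
sizes chosen so the whole pipeline runs end to end on a single CPU in
minutes while leaving the recovery experiment non-trivial (randomized
rigid starts up to a half-turn rotation and 6 Å offset). The grid oracle
uses 30° steps for the five-rotatable-torsion lysine chain and 15° for
the two-torsion N-terminal chain; both include the trans point, and the
cross-check tolerance (0.5 Å / 0.2 Å) reflects the corresponding grid
spacing.

## Known limitations

* Rigid receptor; no side chains beyond Cβ; single clash radius.
* Reach sampling ignores sterics and energetics of the linker itself
  (uniform torsions); it brackets, not weights, the feasible range.
* PDB is the only structure format (no mmCIF); author numbering is used
  throughout with no renumbering.
* Curated footprint fixtures cover only positions named in the source
  text and are marked as such; they are inputs, not computed results.
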