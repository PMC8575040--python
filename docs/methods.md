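# Methods

`pepstruct` predicts the tertiary structure of short peptides (5–40 natural
amino acids, linear or cyclic) from the primary sequence in three stages:
a neural network regresses inter-residue distances and backbone torsions,
these predictions become NMR-style interval restraints, and a restrained
simulated-annealing engine folds the peptide into a ranked ensemble.
This note records the model, its assumptions, the tunable parameters, and the
design choices made where the design was genuinely open.

## Peptide representation

Peptides live in a fixed input frame of length 50.  Each peptide is encoded
as

* `h` — a length-50 integer vector (0 = empty position, 1–20 = the natural
  amino acids in alphabetical one-letter order, 22 = non-natural, retained
  for format compatibility although the pipeline rejects non-natural
  residues);
* `C` — a symmetric 50×50 binary cyclization matrix (`C[i,j] = 1` when
  residues i and j are covalently bridged, e.g. a disulfide);
* `S = P·A` — a 50×15 physicochemical block, where `P` is the implicit
  50×21 one-hot matrix and `A` the reduced property matrix below;
* masks `m` (length 50) and `M = outer(m, m)` marking occupied positions.

`A` is produced from an AAindex-style table of 186 amino-acid property
scales: each scale is standardized over the 21 rows (20 amino acids plus an
"unknown" row holding column means), the table is reduced to 15 principal
components, and each component is min-max scaled to [0, 1].  The PCA sign is
fixed by making the largest-magnitude loading of each component positive, so
the serialized matrix is byte-identical across runs.  The exact AAindex
subset used in the original study is not identifiable, and nothing downstream
depends on which fixed table is chosen; the package therefore ships a seeded
synthetic stand-in generator (`synthetic.synthetic_property_scales`, low-rank
correlated noise labelled as synthetic) and reads real tables from CSV when
the user has one.

**Frame-shift augmentation.**  During training each peptide appears as 20
copies at offsets drawn uniformly (with replacement — the simplest
reading of "randomly shifted") from the admissible range; a seed is a
required parameter.  At prediction time all `50 − n + 1` offsets are
enumerated deterministically.  Outputs are shifted back to the peptide frame
and aggregated as per-entry means and *population* standard deviations
(divide by the count; the spread is a descriptive width, not an estimator of
a sampling distribution).  The aggregation pools frames *and* the
cross-validation fold models into one population — the prediction spread
should reflect both sources of disagreement, since both feed the same
restraint width.

## Network

Topology (frame length 50 throughout):

    h → embedding(12) → rows × m → concat S, C → (50, 77)
      → conv1d(128, 7) → BN → ReLU → spatial dropout
      → 2 × residual gated conv block
      → flatten → dense(1024) → BN → ReLU → dropout
      → heads: 2500 (ReLU) → (50,50)·M   Cα–Cα distances
               2500 (ReLU) → (50,50)·M   Cβ–Cβ distances
                200 (tanh) → (50,4)·m    (cos, sin) of φ and ψ

A gated convolution computes `conv_a(x) ⊙ σ(conv_b(x))`; each residual block
chains three of them (BN+ReLU after the first two, spatial dropout after the
third), adds the block input back, then applies BN, ReLU and spatial dropout.
The embedding output is concatenated with `S` and `C` — giving the
12 + 15 + 50 = 77 input channels — since the property information enters
per-position through `S`, not through the raw 21×15 matrix.

The loss is the sum of the three heads' masked MSEs: squared errors are
summed over masked entries only and divided by the number of masked entries
(an all-zero mask contributes 0).  The distance heads use `M` (further
restricted to non-glycine pairs for the Cβ head); the trig head uses a
defined-ness mask that zeroes the φ columns of the first residue and the ψ
columns of the last.  Head weights are equal — no reweighting is given in
the protocol, and the three heads have comparable masked-entry counts.

Training: Nadam, learning rate 0.001, batch size 32 (not printed anywhere;
a standard default, exposed in the hyperparameters), 400 epochs with no
early stopping, retaining the parameters of the epoch with the lowest
validation loss.  Dropout and spatial-dropout rates are likewise not
printed; the default is 0.2, exposed in configuration.  Ten-fold
cross-validation partitions the peptide records (never the augmented
samples, which would leak frames of a validation peptide into training);
prediction ensembles all fold models.

The network is implemented directly on numpy float32 arrays with
hand-written backpropagation (embedding, same-padded conv1d via sliding
windows, batch norm with running statistics, gated convs, dense layers,
inverted dropout, Nadam).  Gradients of every layer are verified against
central finite differences in the test suite.  Inference disables dropout
and uses running batch-norm statistics, so prediction is exactly
deterministic.

## Restraints

* Distances: for every unique residue pair i < j, one Cα–Cα and one Cβ–Cβ
  restraint with bounds `[mean − sd, mean + sd]`, lower bound floored at 0,
  glycine Cβ pairs skipped.  The conventional count for an n-mer is
  `2n(n−1)` — both orientations of each pair, both atom kinds.  Duplicate
  orientations are redundant for the annealer, so the set stores each
  unordered pair once with symmetrized bounds and reports the
  dual-orientation count (`nominal_distance_count`) alongside.
* Dihedrals: the angle is `atan2(mean sin, mean cos)`; a restraint
  `angle ± 15°` is emitted only when both trig standard deviations are below
  0.10 (strict), giving at most `2(n−1)` restraints.  Intervals are kept
  unwrapped (a 180° angle yields [165°, 195°]); both output dialects accept
  such values, and the internal energy measures angular deviation on the
  circle.  If both trig means vanish the direction is undefined and the
  angle is skipped with a warning.

Writers emit the XPLOR-NIH `.tbl` dialect (`assign (resid I and name K)
(resid J and name K) D DMINUS DPLUS`, three decimals; dihedral lines use the
four standard φ/ψ atoms with force constant 1.0 and exponent 2) and the
CYANA `.upl`/`.lol`/`.aco` dialects (two decimals, three-letter residue
codes).  Ordering is deterministic (Cα block then Cβ, row-major), and small
parsers for both dialects support byte-identical round trips.

## Structure calculation

The reference protocol hands the restraints to XPLOR-NIH torsion-angle
dynamics (2025 K → 25 K in 25 K steps, 100 structures, Cartesian
minimization last).  Re-implementing full torsion-angle dynamics would be
out of proportion here, so the engine performs Metropolis Monte-Carlo
annealing in (φ, ψ) torsion space under the *same* temperature schedule — a
protocol-equivalent stand-in, documented as such, with no claim of
XPLOR-NIH parity.  The XPLOR "tolerance factor" for the annealing stage is
carried in the schedule object for configuration compatibility but unused;
its meaning is not defined by the protocol description.

Energy model (flat-bottom, exactly zero inside all bounds):

* distance: `w_d · (max(0, d − upper)² + max(0, lower − d)²)`, `w_d = 1 Å⁻²`;
* dihedral: `w_a · excess²`, excess = angular distance (degrees) from θ to
  the restraint interval measured on the circle, `w_a = (π/180)²` (an
  excess in degrees contributes as its radian equivalent);
* steric: `w_s · max(0, 2.8 Å − r)²` over backbone-atom pairs at bond-graph
  separation ≥ 4, `w_s = 4`.  Pairs at separation ≤ 3 are excluded because
  1–4 distances inside the planar peptide group (e.g. O(i)–Cα(i+1) at
  2.77 Å) are fixed by covalent geometry and must not register as clashes.

Each run starts from the preliminary structure built from the predicted
dihedral angles (ideal covalent geometry, 180° where no prediction exists),
perturbs every torsion by Gaussian noise (σ = 30°), then cools through the
81 temperature levels with 50 pivot moves per level (both configurable).
A move rotates everything downstream of a randomly chosen φ/ψ bond by a
Gaussian angle whose width shrinks as √(T/T_init) from 60°; acceptance is
`exp(−ΔE/T)`.  Temperature and energy share one arbitrary unit — the
schedule's "K" labels are nominal.  Cyclization bonds are enforced as
Cβ–Cβ distance restraints in [3.0, 4.5] Å added from the record's bond
list (how bonds enter the annealing stage is otherwise unspecified; this
bracket covers the disulfide Cβ–Cβ distance range).

Cartesian minimization (L-BFGS with analytic gradients) then descends on
the restraint energy plus harmonic tethers keeping bond lengths
(w = 100 Å⁻²), bond angles (w = 50 rad⁻²), ω planarity and the Cβ
chirality torsion (w = 10 rad⁻²) at their ideal values; the ω and improper
tethers are needed because a purely Cartesian descent would otherwise be
free to twist the peptide plane or invert Cα chirality.  The minimizer
never returns a structure with higher energy than its input.  Models are
ranked by ascending final restraint energy.  Identical inputs and seed give
a bitwise-identical ensemble.

### Ideal geometry

One self-consistent internal-coordinate set is fixed: N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, Cα–Cβ 1.521 Å; angles N–Cα–C
111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O 120.8°, C–Cα–Cβ 110.1°;
ω fixed trans; Cβ placed by the tetrahedral construction with the
N–C–Cα–Cβ improper at +122.6° (L-chirality).  Building a backbone from
(φ, ψ) and re-measuring recovers the angles to ~1e−6°; a fully extended
chain has consecutive Cα–Cα spacing 3.8040 Å.

## Curation and evaluation

Curation keeps peptides of 5–40 residues whose ensemble spread — defined
as the mean pairwise backbone RMSD over all unordered model pairs after
superposition (parameter-free, versus e.g. mean-to-medoid) — is at most
2.50 Å; single-model records skip the spread test.  Training targets are
taken from the *first* model of each ensemble (which model the original
training used is unstated; the first is the conventional representative).
Sequence-redundancy reduction (CD-HIT at 0.9 identity) is an external
preprocessing step; `curate` accepts a precomputed representative list.

Backbone RMSD is computed over {N, Cα, C} after optimal superposition
(`scipy` rotation alignment; an independent quaternion oracle guards it in
tests).  Which atom set "backbone" means is not pinned down by the protocol;
{N, Cα, C} is the minimal set every experimental model provides, and O is
excluded so that terminal-residue bookkeeping cannot change the comparison.
The rigid core of a reference ensemble is found by iterating: superpose all
models onto the first over the current core's Cα atoms (starting from all
residues) and compute each residue's cross-model Cα-RMSD as the RMSF about
the ensemble mean; core residues at or above 1.5 Å (the criterion is a
strict <) are trimmed one at a time, worst first — pruning everything at
once lets a few very mobile termini wreck the initial superposition and
collapse the core — and once the core is clean, residues back under the
cutoff are re-admitted until a fixed point (the criterion alone does not say
how to iterate; trimming to a fixed point makes the result well defined,
idempotent and robust).  Cores smaller than three residues are reported as
empty since superposition needs three points.  A prediction is near-native when its
rigid-core B-RMSD to the reference's first model is below 4 Å.  The prime
model of a predicted ensemble is the lowest-energy model, or under the
`least_violations` criterion the model violating the fewest distance
restraints (ties: total violation magnitude, then model index).

## Synthetic fixtures

The generator produces what the pipeline needs to be tested end-to-end
without downloads: ideal-geometry peptides in helix (−57°, −47°), strand
(−119°, 113°) and coil motifs (coil φ ∈ (−180°, −30°), ψ ∈ (−90°, 180°) —
broadly plausible backbone regions, fixed as documented constants);
multi-model ensembles with per-residue Gaussian coordinate jitter; oracle
restraints bracketing a known structure with controllable slack; and random
training corpora.  A "strand" is a single extended strand — sheet pairing
would need hydrogen-bond modelling that is out of scope.  The fixtures do
not emulate realistic Ramachandran statistics, side chains beyond Cβ,
experimental coordinate error models, or sequence–structure correlation
beyond the motif assignment, so passing tests demonstrate that the
machinery is correct and self-consistent, not that benchmark accuracy on
real peptides is reproduced — that would require the curated experimental
corpus and full-scale training.

## Problem sizes in the shipped checks

The test suite and the acceptance script run everything at desk scale, as
the package's own choice of demonstration size: restraint-recovery folds 20
structures per fixture (12-mer helix, 10-mer strand, 16-mer mixed), slack
monotonicity uses 6 structures × 3 seeds per slack, and the smoke training
uses 200 synthetic peptides, 30 epochs and 2 folds with a reduced network
(32 filters, one residual block, 128 dense units).  The full-size defaults
(128 filters, two blocks, 1024 dense units, 400 epochs, 10 folds, 100
structures) remain the package defaults and are exercised structurally by
the same code paths.

## Known limitations

* The annealer is a Monte-Carlo stand-in for torsion-angle dynamics; its
  energies are not comparable to XPLOR-NIH or CYANA values.
* No side chains beyond Cβ, no hydrogens, no solvent or electrostatics.
* Non-natural amino acids are rejected (code 22 exists only for encoding
  compatibility).
* The synthetic corpus gives the network a learnable but artificial
  sequence→structure mapping; trained weights from it are a smoke-scale
  demonstration only.
* mmCIF is not read; PDB files with insertion codes or multiple chains are
  rejected rather than interpreted.
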