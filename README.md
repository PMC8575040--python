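# pepstruct

Peptide tertiary structure prediction from the primary sequence, for peptides
of 5–40 natural amino acids, linear or cyclic.

Short peptides rarely have enough evolutionary depth for the co-evolution
signals that power protein structure predictors, yet their bioactivity —
antimicrobial, anticancer, antiviral — depends directly on their fold.
`pepstruct` takes the route of NMR structure determination: instead of
predicting coordinates, a neural network predicts *structural restraints*,
and a simulated-annealing engine folds the peptide under them.

The pipeline:

1. **Encoding.** A peptide is placed in a 50-position frame and described by
   a one-hot code `h`, a cyclization matrix `C`, and a physicochemical block
   `S = P·A`, where `A` (21 × 15) compresses 186 amino-acid property scales
   by standardization → PCA → min–max scaling.  Each peptide is represented
   at several frame offsets (20 random shifts for training, all `50 − n + 1`
   shifts for prediction).
2. **Restraint prediction.** A gated residual 1-D convolutional network
   (embedding 12 → conv 128×7 → two residual gated blocks → dense 1024 →
   heads of 2500/2500/200 units) regresses the Cα–Cα and Cβ–Cβ distance
   matrices and (cos, sin) of φ/ψ, trained with a masked MSE under 10-fold
   cross-validation (Nadam, lr 0.001, lowest-validation-loss checkpoint).
   Predictions from all frames and fold models are averaged; their spread
   sets the restraint widths: distance bounds `mean ± sd`, dihedral bounds
   `atan2(s̄, c̄) ± 15°` kept only when both trig sds are below 0.10.
   For an n-mer this gives the conventional `2n(n−1)` distance restraints
   and up to `2(n−1)` dihedral restraints, written in XPLOR-NIH `.tbl` and
   CYANA `.upl`/`.lol`/`.aco` dialects.
3. **Folding.** Metropolis Monte-Carlo annealing in (φ, ψ) torsion space
   under flat-bottom restraint potentials, cooling 2025 K → 25 K in 25 K
   steps from a preliminary structure built at the predicted angles,
   followed by Cartesian L-BFGS minimization with ideal-geometry tethers;
   100 independent runs by default, ranked by final restraint energy.
   Evaluation reports backbone RMSD ({N, Cα, C}) for the best and the prime
   (lowest-energy) model, over the full chain and over the reference
   ensemble's rigid core (residues with cross-model Cα-RMSD < 1.5 Å), with
   a prediction called near-native below 4 Å rigid-core B-RMSD.

Everything — including the network, with hand-written backpropagation — runs
on the scientific Python stack (numpy/scipy/sklearn/biopython); no deep
learning framework is required.  A synthetic-fixture module generates
ideal-geometry peptides, jittered ensembles and oracle restraints so the
whole pipeline is testable without any structure downloads.

## Worked example

Fold an ideal 12-mer α-helix from restraints derived from its own geometry
(±0.5 Å, ±15°) — the standard self-consistency check:

```python
from pepstruct import synthetic as sy, anneal as an, evaluate as ev

ens = sy.make_ideal_peptide("ACDEFHIKLMNQ", sy.MotifSpec("helix"), seed=1)
rs = sy.oracle_restraints(ens, dist_slack=0.5)
pred = an.anneal(ens.peptide, rs, n_structures=10, seed=1)
report = ev.score_prediction(pred, ens)
```

Printing the restraint counts and report fields gives:

```text
peptide: ACDEFHIKLMNQ (12 residues)
distance restraints: 132 unique pairs (dual-orientation count 264)
dihedral restraints: 22
best B-RMSD:  0.28 A
prime B-RMSD: 0.34 A (model 1, lowest energy)
near-native:  True
```

The 132 unique pair restraints double to the conventional count
`2n(n−1) = 264` for n = 12; 22 dihedral restraints are `2(n−1)`.  The best
of 10 annealed models lands 0.28 Å from the source structure, and the
lowest-energy model is essentially as good — the restraints, not luck,
determine the fold.

## Command line

```bash
pepstruct fixtures  --out fixtures/ --seed 1          # synthetic PDBs + property matrix
pepstruct train     --n-peptides 200 --folds 2 --epochs 30 --out models/
pepstruct predict   --sequence ACDEFHIKLM --models models/ --out out/   # restraint files
pepstruct predict   --sequence ACDEFHIKLM --models models/ --out out/ \
                    --mode full --n-structures 100 --seed 1            # + ranked PDB
pepstruct fold      --sequence ... --distance-tbl d.tbl --dihedral-tbl a.tbl --out pred.pdb
pepstruct evaluate  --predicted pred.pdb --reference ref.pdb
```

Cyclic peptides take repeatable `--ss-bond I:J` flags; the bond enters the
encoding as `C[i,j] = 1` and the annealer as a Cβ–Cβ restraint in
[3.0, 4.5] Å.

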