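"""Synthetic fixtures: ideal-geometry peptides, jittered ensembles, oracle
restraints and smoke-scale training corpora.

Everything here is generated programmatically so the whole pipeline is
testable without structure downloads.  The fixtures emulate short peptide
backbones with ideal covalent geometry in helix / strand / coil motifs,
multi-model ensembles with controllable per-residue coordinate jitter, and
restraints derived from known structures with controllable slack.  They do
not emulate realistic Ramachandran statistics, side chains, or sheet pairing
(a "strand" is a single extended strand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataset import TrainingTargets, make_targets
from .featurize import FRAME
from .restraints import (
    DIHEDRAL_HALF_WIDTH,
    DihedralRestraint,
    DistanceRestraint,
    RestraintSet,
)
from .structures import (
    ONE_LETTER,
    BackboneResidue,
    PeptideRecord,
    StructureEnsemble,
    backbone_dihedrals,
    build_backbone,
    copy_model,
    pairwise_distances,
)

__all__ = [
    "MOTIF_ANGLES",
    "MotifSpec",
    "make_ideal_peptide",
    "jitter_ensemble",
    "oracle_restraints",
    "make_training_corpus",
    "synthetic_property_scales",
]

#: Canonical (phi, psi) per motif, degrees.
MOTIF_ANGLES = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
}
#: Coil angles are drawn uniformly from these broadly plausible ranges.
COIL_PHI_RANGE = (-180.0, -30.0)
COIL_PSI_RANGE = (-90.0, 180.0)


@dataclass(frozen=True)
class MotifSpec:
    """Secondary-structure motif of a synthetic peptide.

    ``motif``: ``helix`` | ``strand`` | ``coil`` | ``mixed``.  For ``mixed``,
    ``pattern`` gives one letter per residue (H/S/C); for the single-motif
    kinds the pattern is implied.
    """

    motif: str
    pattern: Optional[str] = None

    def per_residue(self, n: int) -> str:
        if self.motif == "mixed":
            if self.pattern is None or len(self.pattern) != n:
                raise ValueError("mixed motif needs a per-residue pattern of length n")
            return self.pattern.upper()
        code = {"helix": "H", "strand": "S", "coil": "C"}.get(self.motif)
        if code is None:
            raise ValueError(f"unknown motif {self.motif!r}")
        return code * n


def _motif_angles(pattern: str, rng: np.random.Generator):
    angles = []
    for ch in pattern:
        if ch == "H":
            angles.append(MOTIF_ANGLES["helix"])
        elif ch == "S":
            angles.append(MOTIF_ANGLES["strand"])
        elif ch == "C":
            angles.append(
                (rng.uniform(*COIL_PHI_RANGE), rng.uniform(*COIL_PSI_RANGE))
            )
        else:
            raise ValueError(f"unknown motif letter {ch!r}")
    return angles


def make_ideal_peptide(
    sequence: str, motif_spec: MotifSpec, seed: int = 0, record_id: str = "synthetic"
) -> StructureEnsemble:
    """Single-model ideal-geometry peptide following a motif specification."""
    n = len(sequence)
    rng = np.random.default_rng(seed)
    angles = _motif_angles(motif_spec.per_residue(n), rng)
    record = PeptideRecord(id=record_id, sequence=sequence)
    return StructureEnsemble(peptide=record, models=[build_backbone(sequence, angles)])


def jitter_ensemble(
    structure: StructureEnsemble,
    n_models: int,
    per_residue_sigma: Sequence[float],
    seed: int = 0,
) -> StructureEnsemble:
    """Ensemble of ``n_models`` copies with per-residue Gaussian atomic noise.

    ``per_residue_sigma[i]`` is the isotropic per-coordinate noise scale (A)
    applied to every atom of residue i+1.
    """
    base = structure.models[0]
    n = len(base)
    if len(per_residue_sigma) != n:
        raise ValueError("need one sigma per residue")
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        model = copy_model(base)
        for i, res in enumerate(model):
            s = float(per_residue_sigma[i])
            for name in res.atoms_present():
                res.atom(name)[:] += rng.normal(0.0, s, size=3) if s > 0 else 0.0
        models.append(model)
    return StructureEnsemble(peptide=structure.peptide, models=models)


def oracle_restraints(
    structure: StructureEnsemble, dist_slack: float, angle_slack: float = DIHEDRAL_HALF_WIDTH
) -> RestraintSet:
    """Ground-truth restraints bracketing a known single-model structure.

    Distance restraints ``[d - slack, d + slack]`` for all CA and non-glycine
    CB pairs; dihedral restraints ``[theta - angle_slack, theta + angle_slack]``
    for every defined phi/psi.  The source structure has zero violation
    energy under the result by construction.  Note dihedral intervals use the
    standard 15 deg half-width unless overridden; the RestraintSet type fixes
    the interval width, so ``angle_slack`` must equal 15.
    """
    if abs(angle_slack - DIHEDRAL_HALF_WIDTH) > 1e-9:
        raise ValueError("dihedral interval half-width is fixed at 15 deg")
    model = structure.models[0]
    n = len(model)
    distances = []
    for kind in ("CA", "CB"):
        d = pairwise_distances(model, kind)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(d[i, j]):
                    continue
                distances.append(
                    DistanceRestraint(
                        kind,
                        i + 1,
                        j + 1,
                        lower=max(0.0, d[i, j] - dist_slack),
                        upper=d[i, j] + dist_slack,
                    )
                )
    dihedrals = []
    for i, (phi, psi) in enumerate(backbone_dihedrals(model)):
        if phi is not None:
            dihedrals.append(
                DihedralRestraint(i + 1, "PHI", phi - angle_slack, phi + angle_slack)
            )
        if psi is not None:
            dihedrals.append(
                DihedralRestraint(i + 1, "PSI", psi - angle_slack, psi + angle_slack)
            )
    return RestraintSet(distances=distances, dihedrals=dihedrals, n=n)


def make_training_corpus(
    n_peptides: int,
    length_range: tuple[int, int] = (5, 40),
    motif_mix: Sequence[str] = ("helix", "strand", "coil"),
    seed: int = 0,
) -> list[tuple[PeptideRecord, TrainingTargets, StructureEnsemble]]:
    """Random synthetic training corpus.

    Random sequences over the 20 natural letters, motifs drawn from
    ``motif_mix``, targets from :func:`~pepstruct.dataset.make_targets` at a
    random admissible offset.  Deterministic given ``seed``.
    """
    if n_peptides < 10:
        raise ValueError("need at least 10 peptides")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_peptides):
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(list(ONE_LETTER), size=n))
        motif = str(rng.choice(list(motif_mix)))
        spec = MotifSpec(motif)
        ens = make_ideal_peptide(
            seq, spec, seed=int(rng.integers(2**31)), record_id=f"syn{k:04d}"
        )
        offset = int(rng.integers(0, FRAME - n + 1))
        out.append((ens.peptide, make_targets(ens, offset), ens))
    return out


def synthetic_property_scales(seed: int = 0, n_scales: int = 186) -> np.ndarray:
    """Synthetic stand-in for an AAindex-style property-scale table.

    Returns a (21, n_scales) array: 20 amino-acid rows of correlated smooth
    random scales plus an unknown row filled with column means.  The true
    AAindex subset used in the original study is not identifiable, and the
    encoding pipeline only requires *some* fixed 186-scale table; this one is
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    # low-rank structure + noise: property scales are heavily correlated
    basis = rng.normal(size=(20, 8))
    mix = rng.normal(size=(8, n_scales))
    table = basis @ mix + 0.3 * rng.normal(size=(20, n_scales))
    unknown = table.mean(axis=0, keepdims=True)
    return np.vstack([table, unknown])
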