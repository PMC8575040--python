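"""Superposition, backbone RMSD, rigid-core extraction and prediction scoring.

Backbone RMSD (B-RMSD) is computed over the {N, CA, C} atoms after optimal
rigid superposition.  The rigid core (RC) of an experimental ensemble is the
set of residues whose cross-model CA deviation stays below 1.5 A under an
iterative superpose-and-prune procedure; evaluation restricted to the RC
discounts flexible termini.  A prediction is called near-native when its RC
B-RMSD to the reference conformation is below 4 A.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    BACKBONE_ATOMS,
    Model,
    StructureEnsemble,
    model_coords,
)

__all__ = [
    "RIGID_CORE_CUTOFF",
    "NEAR_NATIVE_CUTOFF",
    "EvaluationReport",
    "kabsch_superpose",
    "backbone_rmsd",
    "rigid_core",
    "score_prediction",
]

RIGID_CORE_CUTOFF = 1.5  # A, per-residue cross-model CA-RMSD; strict <
NEAR_NATIVE_CUTOFF = 4.0  # A, RC B-RMSD; strict <


@dataclass
class EvaluationReport:
    """Per-peptide evaluation of a predicted ensemble against a reference."""

    best_brmsd: float
    prime_brmsd: float
    best_rc_brmsd: float
    prime_rc_brmsd: float
    rigid_core: tuple[int, ...]  # 1-based residue indices
    near_native: bool
    prime_criterion: str  # lowest_energy | least_violations
    prime_model_index: int  # 0-based index into the predicted ensemble

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv_row(self) -> str:
        """Tab-separated row: best, prime, and bracketed rigid-core values."""
        return "\t".join(
            [
                f"{self.best_brmsd:.2f}",
                f"{self.prime_brmsd:.2f}",
                f"({self.best_rc_brmsd:.2f})",
                f"({self.prime_rc_brmsd:.2f})",
                ",".join(map(str, self.rigid_core)),
                "near_native" if self.near_native else "non_native",
            ]
        )


def kabsch_superpose(coordsA: np.ndarray, coordsB: np.ndarray):
    """Optimal least-squares rigid superposition of B onto A.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coordsB @ rotation.T + translation`` best fits ``coordsA``; the rotation
    is proper (det +1).
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 matched points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0]), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    with warnings.catch_warnings():
        # align_vectors warns for ill-conditioned inputs; degenerate cases
        # are rejected above
        warnings.simplefilter("ignore")
        rot, rssd = Rotation.align_vectors(A0, B0)
    R = rot.as_matrix()
    t = ca - cb @ R.T
    rmsd = float(rssd) / np.sqrt(n)
    return R, t, rmsd


def backbone_rmsd(
    modelA: Model,
    modelB: Model,
    residue_subset: Optional[Sequence[int]] = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> float:
    """B-RMSD between two models over a residue subset (1-based indices)."""
    if len(modelA) != len(modelB):
        raise ValueError("models differ in length")
    if residue_subset is None:
        subset = range(1, len(modelA) + 1)
    else:
        subset = sorted(residue_subset)
        if not subset:
            raise ValueError("residue subset is empty")
    selA = [modelA[i - 1] for i in subset]
    selB = [modelB[i - 1] for i in subset]
    A = model_coords(selA, atom_names)
    B = model_coords(selB, atom_names)
    return kabsch_superpose(A, B)[2]


def select_core(per_residue_ca_rmsd: np.ndarray) -> list[int]:
    """Residues (1-based) whose cross-model CA-RMSD is strictly below 1.5 A."""
    return [i + 1 for i, v in enumerate(per_residue_ca_rmsd) if v < RIGID_CORE_CUTOFF]


def _ca_matrix(ensemble: StructureEnsemble) -> np.ndarray:
    return np.array([[res.CA for res in model] for model in ensemble.models])


def _core_rmsf(cas: np.ndarray, core_idx: np.ndarray) -> np.ndarray:
    """Per-residue cross-model CA-RMSD (RMSF about the ensemble mean) after
    superposing every model onto the first over the current core's CAs."""
    moved = [cas[0]]
    for m in range(1, cas.shape[0]):
        R, t, _ = kabsch_superpose(cas[0][core_idx], cas[m][core_idx])
        moved.append(cas[m] @ R.T + t)
    arr = np.array(moved)
    mean = arr.mean(axis=0)
    return np.sqrt(np.mean(np.sum((arr - mean) ** 2, axis=2), axis=0))


def rigid_core(reference_ensemble: StructureEnsemble) -> tuple[int, ...]:
    """Residues (1-based) forming the rigid core of an experimental ensemble.

    Iterative procedure: superpose every model onto the first over the current
    core's CA atoms (starting from all residues) and compute each residue's
    cross-model CA-RMSD (the RMSF about the ensemble mean).  Core residues at
    or above 1.5 A are trimmed one at a time (worst first) so that a few very
    mobile residues cannot collapse the whole core through a bad initial
    superposition; once the core is clean, residues back under the cutoff are
    re-admitted, and the loop stops at a fixed point.  Single-model ensembles
    return all residues; cores below 3 residues (too few to superpose) are
    reported as empty with a warning.
    """
    n = len(reference_ensemble.peptide.sequence)
    if reference_ensemble.n_models < 2:
        return tuple(range(1, n + 1))
    cas = _ca_matrix(reference_ensemble)  # (n_models, n, 3)
    core = list(range(n))  # 0-based during iteration
    seen: set[tuple[int, ...]] = set()
    for _ in range(20 * n):
        rmsf = _core_rmsf(cas, np.array(core))
        bad = [i for i in core if rmsf[i] >= RIGID_CORE_CUTOFF]
        if bad:
            worst = max(bad, key=lambda i: rmsf[i])
            core = [i for i in core if i != worst]
            if len(core) < 3:
                warnings.warn("rigid core collapsed below 3 residues; returning empty core")
                return ()
            continue
        eligible = [i - 1 for i in select_core(rmsf)]
        if eligible == core or tuple(eligible) in seen:
            return tuple(i + 1 for i in core)
        seen.add(tuple(eligible))
        core = eligible
    return tuple(i + 1 for i in core)


def internal_backbone_rmsd(ensemble: StructureEnsemble) -> float:
    """Mean pairwise B-RMSD over all unordered model pairs (ensemble spread)."""
    if ensemble.n_models < 2:
        return 0.0
    vals = []
    for a in range(ensemble.n_models):
        for b in range(a + 1, ensemble.n_models):
            vals.append(backbone_rmsd(ensemble.models[a], ensemble.models[b]))
    return float(np.mean(vals))


def _count_distance_violations(model: Model, restraints) -> tuple[int, float]:
    """(number of violated distance restraints, total violation magnitude)."""
    n_viol = 0
    total = 0.0
    for r in restraints:
        a = model[r.i - 1].atom(r.atom_kind)
        b = model[r.j - 1].atom(r.atom_kind)
        if a is None or b is None:
            continue
        d = float(np.linalg.norm(a - b))
        excess = max(0.0, d - r.upper) + max(0.0, r.lower - d)
        if excess > 1e-9:
            n_viol += 1
            total += excess
    return n_viol, total


def score_prediction(
    predicted: StructureEnsemble,
    reference: StructureEnsemble,
    prime_criterion: str = "lowest_energy",
    distance_restraints=None,
) -> EvaluationReport:
    """Score a predicted ensemble against the reference's first model.

    ``best_brmsd`` is the minimum over predicted models; the prime model is
    selected by ``prime_criterion``: ``lowest_energy`` uses ``model_scores``,
    ``least_violations`` counts violated distance restraints (ties broken by
    total violation magnitude, then model index) and requires
    ``distance_restraints``.
    """
    if predicted.sequence() != reference.sequence():
        raise ValueError("predicted and reference sequences differ")
    ref_model = reference.models[0]
    rmsds = [backbone_rmsd(m, ref_model) for m in predicted.models]
    core = rigid_core(reference)
    if core:
        rc_rmsds = [backbone_rmsd(m, ref_model, core) for m in predicted.models]
    else:
        rc_rmsds = rmsds

    if prime_criterion == "lowest_energy":
        if predicted.model_scores is None:
            raise ValueError("lowest_energy criterion requires model_scores")
        prime = int(np.argmin(predicted.model_scores))
    elif prime_criterion == "least_violations":
        if distance_restraints is None:
            raise ValueError("least_violations criterion requires distance_restraints")
        keys = [
            (*_count_distance_violations(m, distance_restraints), k)
            for k, m in enumerate(predicted.models)
        ]
        prime = min(keys)[2]
    else:
        raise ValueError(f"unknown prime criterion: {prime_criterion}")

    best_rc = float(min(rc_rmsds))
    return EvaluationReport(
        best_brmsd=float(min(rmsds)),
        prime_brmsd=float(rmsds[prime]),
        best_rc_brmsd=best_rc,
        prime_rc_brmsd=float(rc_rmsds[prime]),
        rigid_core=core,
        near_native=bool(best_rc < NEAR_NATIVE_CUTOFF),
        prime_criterion=prime_criterion,
        prime_model_index=prime,
    )
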