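"""Dataset curation and conversion of structures to training-target tensors.

Curation keeps peptides of 5-40 residues whose NMR ensemble is internally
consistent: the mean pairwise backbone RMSD over all model pairs (after
superposition) must not exceed 2.50 A.  Sequence-redundancy reduction
(CD-HIT at 0.9 identity) is an external preprocessing step; ``curate``
optionally accepts a precomputed list of cluster-representative ids.

Training targets mirror the network's three output heads: the CA-CA and CB-CB
distance matrices and the (cos, sin) of phi and psi, all placed at a frame
offset inside the fixed 50-position window, with masks marking which entries
are defined (occupied positions; non-glycine CB pairs; non-terminal angles).
Targets are taken from the first model of each ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .evaluate import internal_backbone_rmsd
from .featurize import FRAME
from .structures import StructureEnsemble, backbone_dihedrals, pairwise_distances

__all__ = [
    "MIN_LENGTH",
    "MAX_LENGTH",
    "MAX_INTERNAL_BRMSD",
    "TrainingTargets",
    "CurationRecord",
    "curate",
    "curation_report",
    "make_targets",
]

MIN_LENGTH = 5
MAX_LENGTH = 40
MAX_INTERNAL_BRMSD = 2.50  # A; ensembles spreading wider are excluded


@dataclass
class TrainingTargets:
    """Frame-placed regression targets for one peptide.

    ``mask_ca``/``mask_cb``/``mask_trig`` are the loss masks of the three
    heads: the pair mask M, M with glycine rows/columns removed, and the
    per-angle defined-ness mask (terminal phi/psi zeroed).
    Entries outside the masks are zero.
    """

    dca: np.ndarray  # (50, 50) A
    dcb: np.ndarray  # (50, 50) A
    trig: np.ndarray  # (50, 4): cos phi, sin phi, cos psi, sin psi
    m: np.ndarray  # (50,)
    M: np.ndarray  # (50, 50)
    offset: int
    mask_ca: np.ndarray = None
    mask_cb: np.ndarray = None
    mask_trig: np.ndarray = None


@dataclass
class CurationRecord:
    id: str
    length: int
    n_models: int
    internal_brmsd: float
    retained: bool
    reason: str  # "" | "length" | "ensemble_rmsd" | "redundancy"


def curate(
    ensembles: Iterable[StructureEnsemble],
    representatives: Optional[Sequence[str]] = None,
) -> tuple[list[StructureEnsemble], list[CurationRecord]]:
    """Apply the curation filters; returns (retained, per-record report).

    ``representatives``: optional ids of cluster representatives from an
    external redundancy reduction; when given, other ids are excluded with
    reason ``redundancy``.
    """
    kept: list[StructureEnsemble] = []
    report: list[CurationRecord] = []
    rep_set = set(representatives) if representatives is not None else None
    for ens in ensembles:
        n = len(ens.peptide.sequence)
        brmsd = internal_backbone_rmsd(ens)
        reason = ""
        if not MIN_LENGTH <= n <= MAX_LENGTH:
            reason = "length"
        elif ens.n_models > 1 and brmsd > MAX_INTERNAL_BRMSD:
            reason = "ensemble_rmsd"
        elif rep_set is not None and ens.peptide.id not in rep_set:
            reason = "redundancy"
        retained = reason == ""
        if retained:
            kept.append(ens)
        report.append(
            CurationRecord(
                id=ens.peptide.id,
                length=n,
                n_models=ens.n_models,
                internal_brmsd=brmsd,
                retained=retained,
                reason=reason,
            )
        )
    return kept, report


def curation_report(report: Sequence[CurationRecord]) -> str:
    """Tab-separated curation report."""
    lines = ["id\tlength\tn_models\tinternal_brmsd\tdecision\treason"]
    for r in report:
        lines.append(
            f"{r.id}\t{r.length}\t{r.n_models}\t{r.internal_brmsd:.3f}\t"
            f"{'retained' if r.retained else 'excluded'}\t{r.reason or '-'}"
        )
    return "\n".join(lines) + "\n"


def make_targets(ensemble: StructureEnsemble, offset: int) -> TrainingTargets:
    """Frame-placed targets from the ensemble's first model."""
    n = len(ensemble.peptide.sequence)
    if not 0 <= offset <= FRAME - n:
        raise ValueError(f"offset {offset} out of range for length {n}")
    model = ensemble.models[0]
    sl = slice(offset, offset + n)

    m = np.zeros(FRAME)
    m[sl] = 1.0
    M = np.outer(m, m)

    dca = np.zeros((FRAME, FRAME))
    dca[sl, sl] = pairwise_distances(model, "CA")

    dcb_block = pairwise_distances(model, "CB")  # NaN at glycine rows/cols
    cb_defined = np.isfinite(dcb_block)
    dcb = np.zeros((FRAME, FRAME))
    dcb[sl, sl] = np.where(cb_defined, dcb_block, 0.0)
    mask_cb = np.zeros((FRAME, FRAME))
    mask_cb[sl, sl] = cb_defined.astype(float)

    trig = np.zeros((FRAME, 4))
    mask_trig = np.zeros((FRAME, 4))
    for i, (phi, psi) in enumerate(backbone_dihedrals(model)):
        row = offset + i
        if phi is not None:
            trig[row, 0] = math.cos(math.radians(phi))
            trig[row, 1] = math.sin(math.radians(phi))
            mask_trig[row, 0:2] = 1.0
        if psi is not None:
            trig[row, 2] = math.cos(math.radians(psi))
            trig[row, 3] = math.sin(math.radians(psi))
            mask_trig[row, 2:4] = 1.0

    return TrainingTargets(
        dca=dca,
        dcb=dcb,
        trig=trig,
        m=m,
        M=M,
        offset=offset,
        mask_ca=M.copy(),
        mask_cb=mask_cb,
        mask_trig=mask_trig,
    )
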