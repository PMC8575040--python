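"""Peptide encoding for the restraint-predicting network.

Peptides live in a fixed input frame of length 50.  Each residue is described
by a one-hot code (via a learned embedding) and a 15-dimensional
physicochemical vector obtained by compressing a table of amino-acid property
scales (AAindex-style, 186 scales over the 20 natural amino acids):
standardize each scale, reduce to 15 principal components, then min-max each
component to [0, 1].  With the one-hot matrix P (50 x 21) and the property
matrix A (21 x 15), the per-position property block is S = P . A.

Because peptides are much shorter than the frame, each peptide is placed at a
frame offset: during training 20 randomly shifted copies are used per peptide
(frame-shift augmentation); at prediction time all 50 - n + 1 admissible
offsets are enumerated, and the network outputs are shifted back to the
peptide frame and averaged — the per-entry spread (population sd) across
frames and fold models is what later widths the restraint intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .structures import ONE_LETTER, PeptideRecord

__all__ = [
    "FRAME",
    "N_COMPONENTS",
    "N_RAW_SCALES",
    "TRAIN_SAMPLES_PER_PEPTIDE",
    "AA_ORDER",
    "EncodedSample",
    "PredictionStats",
    "reduce_property_scales",
    "property_matrix_to_csv",
    "property_matrix_from_csv",
    "read_raw_scales_csv",
    "encode_peptide",
    "augment",
    "n_predict_frames",
    "unshift_average",
]

FRAME = 50  # input frame length
N_COMPONENTS = 15  # retained principal components
N_RAW_SCALES = 186  # property scales in the raw table
TRAIN_SAMPLES_PER_PEPTIDE = 20  # frame-shifted copies per training peptide

#: Row order of the property matrix and the one-hot codebook: the 20 natural
#: amino acids alphabetically by one-letter code, then the "unknown" row.
AA_ORDER = ONE_LETTER  # "ACDEFGHIKLMNPQRSTVWY"
#: Integer codes: 0 = empty frame position, 1..20 = natural amino acids in
#: AA_ORDER, 22 = non-natural (kept for format compatibility; the pipeline
#: itself rejects non-natural residues).
UNKNOWN_CODE = 22


def aa_code(letter: str) -> int:
    idx = AA_ORDER.find(letter)
    if idx < 0:
        raise ValueError(f"invalid amino-acid letter {letter!r}")
    return idx + 1


@dataclass
class EncodedSample:
    """One frame-shifted network input for a peptide."""

    h: np.ndarray  # (50,) int codes
    C: np.ndarray  # (50, 50) cyclization matrix
    S: np.ndarray  # (50, 15) property block, = P . A
    m: np.ndarray  # (50,) occupancy mask
    M: np.ndarray  # (50, 50) pair mask, = outer(m, m)
    offset: int
    n: int  # peptide length


@dataclass
class PredictionStats:
    """Per-peptide prediction statistics in the peptide frame.

    Means and population standard deviations across all contributing network
    outputs (prediction frames x fold models).  Distance matrices are n x n
    and symmetric; undefined entries (glycine CB pairs, terminal phi/psi) are
    NaN.  Trig columns are (cos phi, sin phi, cos psi, sin psi).
    """

    dca_mean: np.ndarray
    dca_sd: np.ndarray
    dcb_mean: np.ndarray
    dcb_sd: np.ndarray
    trig_mean: np.ndarray  # (n, 4)
    trig_sd: np.ndarray

    @property
    def n(self) -> int:
        return self.dca_mean.shape[0]


# ---------------------------------------------------------------------------
# Property matrix
# ---------------------------------------------------------------------------

def reduce_property_scales(raw: np.ndarray) -> np.ndarray:
    """Compress a (21, n_scales) property table to the (21, 15) matrix A.

    Pipeline: drop zero-variance scales (with a warning), standardize each
    remaining scale over the 21 rows, PCA to 15 components, min-max each
    component to [0, 1].  The PCA sign convention is fixed (the
    largest-magnitude loading of each component is made positive) so the
    result is deterministic across runs.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != 21:
        raise ValueError("raw table must have 21 rows (20 amino acids + unknown)")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw table contains non-finite values")
    variances = raw.var(axis=0)
    keep = variances > 1e-12
    if not np.all(keep):
        import warnings

        warnings.warn(f"dropping {int((~keep).sum())} zero-variance scale(s)")
        raw = raw[:, keep]
    std = StandardScaler().fit_transform(raw)
    pca = PCA(n_components=N_COMPONENTS, svd_solver="full")
    try:
        comps = pca.fit_transform(std)
    except ValueError as exc:
        raise ValueError(f"fewer than {N_COMPONENTS} non-degenerate dimensions") from exc
    if np.any(pca.explained_variance_ < 1e-12):
        raise ValueError(f"fewer than {N_COMPONENTS} non-degenerate dimensions")
    # fixed sign convention: largest-|loading| coordinate of each component positive
    for k in range(comps.shape[1]):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, lead] < 0:
            comps[:, k] *= -1.0
    lo, hi = comps.min(axis=0), comps.max(axis=0)
    return (comps - lo) / (hi - lo)


def property_matrix_to_csv(A: np.ndarray) -> str:
    df = pd.DataFrame(
        A,
        index=list(AA_ORDER) + ["X"],
        columns=[f"PC{k + 1}" for k in range(A.shape[1])],
    )
    df.index.name = "aa"
    return df.to_csv(float_format="%.12g")


def property_matrix_from_csv(text: str) -> np.ndarray:
    df = pd.read_csv(io.StringIO(text), index_col="aa")
    if list(df.index) != list(AA_ORDER) + ["X"]:
        raise ValueError("property CSV rows must be the 20 amino acids then 'X'")
    return df.to_numpy(dtype=float)


def read_raw_scales_csv(text: str) -> np.ndarray:
    """Read an AAindex-style CSV (rows = scales, columns = amino acids) into
    the (21, n_scales) raw table; the unknown row is filled with column means."""
    df = pd.read_csv(io.StringIO(text), index_col=0)
    missing = [a for a in AA_ORDER if a not in df.columns]
    if missing:
        raise ValueError(f"scales CSV lacks amino-acid column(s): {missing}")
    table = df[list(AA_ORDER)].to_numpy(dtype=float).T  # (20, n_scales)
    unknown = table.mean(axis=0, keepdims=True)
    return np.vstack([table, unknown])


# ---------------------------------------------------------------------------
# Encoding and augmentation
# ---------------------------------------------------------------------------

def encode_peptide(record: PeptideRecord, A: np.ndarray, offset: int) -> EncodedSample:
    """Encode one peptide at one frame offset."""
    n = len(record)
    if not 0 <= offset <= FRAME - n:
        raise ValueError(f"offset {offset} out of range for length {n}")
    h = np.zeros(FRAME, dtype=np.int64)
    S = np.zeros((FRAME, A.shape[1]))
    m = np.zeros(FRAME)
    for k, aa in enumerate(record.sequence):
        code = aa_code(aa)
        h[offset + k] = code
        S[offset + k] = A[code - 1]
        m[offset + k] = 1.0
    C = np.zeros((FRAME, FRAME))
    for (i, j) in record.cyclic_bonds:
        a, b = offset + i - 1, offset + j - 1
        C[a, b] = C[b, a] = 1.0
    M = np.outer(m, m)
    return EncodedSample(h=h, C=C, S=S, m=m, M=M, offset=offset, n=n)


def n_predict_frames(n: int) -> int:
    return FRAME - n + 1


def augment(
    record: PeptideRecord, A: np.ndarray, mode: str, rng_seed: int = 0
) -> list[EncodedSample]:
    """Frame-shift augmentation.

    ``mode='train'``: 20 samples at offsets drawn uniformly (with replacement)
    from the admissible range, reproducible from ``rng_seed``.
    ``mode='predict'``: all 50 - n + 1 offsets, in order, deterministically.
    """
    n = len(record)
    max_off = FRAME - n
    if mode == "train":
        rng = np.random.default_rng(rng_seed)
        offsets = rng.integers(0, max_off + 1, size=TRAIN_SAMPLES_PER_PEPTIDE)
    elif mode == "predict":
        offsets = range(max_off + 1)
    else:
        raise ValueError("mode must be 'train' or 'predict'")
    return [encode_peptide(record, A, int(o)) for o in offsets]


# ---------------------------------------------------------------------------
# Un-shift averaging
# ---------------------------------------------------------------------------

def unshift_average(outputs: Sequence[tuple[int, dict]], n: int) -> PredictionStats:
    """Shift raw frame outputs back to the peptide frame and average.

    ``outputs`` is a sequence of ``(offset, raw)`` pairs where ``raw`` maps
    ``"dca"``/``"dcb"`` to (50, 50) arrays and ``"trig"`` to a (50, 4) array.
    Returns per-entry means and population standard deviations; distance
    matrices are symmetrized by averaging with their transpose and get a zero
    diagonal.
    """
    if not outputs:
        raise ValueError("no outputs to average")
    dca = np.empty((len(outputs), n, n))
    dcb = np.empty((len(outputs), n, n))
    trig = np.empty((len(outputs), n, 4))
    for k, (off, raw) in enumerate(outputs):
        sl = slice(off, off + n)
        dca[k] = raw["dca"][sl, sl]
        dcb[k] = raw["dcb"][sl, sl]
        trig[k] = raw["trig"][sl, :]
    # symmetrize each contribution before aggregating
    dca = 0.5 * (dca + dca.transpose(0, 2, 1))
    dcb = 0.5 * (dcb + dcb.transpose(0, 2, 1))
    stats = PredictionStats(
        dca_mean=dca.mean(axis=0),
        dca_sd=dca.std(axis=0),
        dcb_mean=dcb.mean(axis=0),
        dcb_sd=dcb.std(axis=0),
        trig_mean=trig.mean(axis=0),
        trig_sd=trig.std(axis=0),
    )
    for mat in (stats.dca_mean, stats.dca_sd, stats.dcb_mean, stats.dcb_sd):
        np.fill_diagonal(mat, 0.0)
    return stats
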