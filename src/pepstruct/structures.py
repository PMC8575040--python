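"""Peptide backbone structures: PDB I/O, geometry, and an ideal-geometry builder.

The package works with short peptides (5-40 residues) represented by their
backbone heavy atoms N, CA, C, O plus CB (absent for glycine).  Structures are
stored as plain numpy-backed records rather than a full PDB hierarchy: every
downstream stage (distance maps, dihedral targets, restraint energies, RMSD)
only needs these five atoms.

Coordinates are in Angstrom.  Residues are numbered 1..n externally (restraint
files, reports) and indexed 0..n-1 internally; PDB residue numbers are
renumbered on parse.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1, seq3

__all__ = [
    "BACKBONE_ATOMS",
    "PeptideRecord",
    "BackboneResidue",
    "StructureEnsemble",
    "PDBParseError",
    "GeometryError",
    "parse_pdb_models",
    "write_pdb_models",
    "dihedral_angle",
    "backbone_dihedrals",
    "pairwise_distances",
    "build_backbone",
]

#: Atoms used for all backbone-RMSD work.  The minimal set every experimental
#: model provides; O and CB are carried but not superposed on.
BACKBONE_ATOMS = ("N", "CA", "C")

ONE_LETTER = "ACDEFGHIKLMNPQRSTVWY"  # the 20 proteinogenic amino acids

# Ideal covalent internal coordinates (Engh-Huber-style, one self-consistent
# set; bond lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_C_CA_CB = 110.1
OMEGA_TRANS = 180.0
# Improper torsion N-C-CA-CB fixing CB chirality (L-amino acids).
IMPROPER_N_C_CA_CB = 122.6


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be interpreted as a single-chain peptide."""


class GeometryError(ValueError):
    """Raised on degenerate geometry (collinear points, undefined torsions)."""


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide sequence with optional cyclization bonds.

    ``cyclic_bonds`` holds 1-based residue index pairs joined by a covalent
    cycle (e.g. a disulfide bridge).
    """

    id: str
    sequence: str
    cyclic_bonds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        bad = set(self.sequence) - set(ONE_LETTER)
        if bad:
            raise ValueError(
                f"{self.id}: non-natural residue letter(s) {sorted(bad)}; "
                "only the 20 natural amino acids are supported"
            )
        n = len(self.sequence)
        for (i, j) in self.cyclic_bonds:
            if not (1 <= i <= n and 1 <= j <= n and i != j):
                raise ValueError(f"{self.id}: cyclization bond ({i},{j}) out of range for n={n}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class BackboneResidue:
    """Backbone heavy atoms of one residue; CB is None for glycine."""

    residue_index: int  # 1-based
    amino_acid: str  # one-letter code
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    CB: Optional[np.ndarray] = None

    def atom(self, name: str) -> Optional[np.ndarray]:
        return getattr(self, name)

    def atoms_present(self) -> list[str]:
        names = ["N", "CA", "C", "O"]
        if self.CB is not None:
            names.append("CB")
        return names


Model = list[BackboneResidue]


@dataclass
class StructureEnsemble:
    """An ordered set of models of the same peptide.

    ``model_scores`` optionally carries a per-model scalar (total energy or
    target-function value); lower is better.
    """

    peptide: PeptideRecord
    models: list[Model]
    model_scores: Optional[list[float]] = None

    def __post_init__(self):
        n = len(self.peptide.sequence)
        for k, model in enumerate(self.models):
            if len(model) != n:
                raise ValueError(
                    f"model {k + 1} has {len(model)} residues, sequence has {n}"
                )
        if self.model_scores is not None and len(self.model_scores) != len(self.models):
            raise ValueError("model_scores length does not match number of models")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def sequence(self) -> str:
        return self.peptide.sequence


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def parse_pdb_models(text: str, record_id: str = "peptide") -> StructureEnsemble:
    """Parse a (multi-model) PDB text into a :class:`StructureEnsemble`.

    Requirements: a single chain; every residue provides N, CA and C; altlocs
    are resolved to the highest-occupancy conformer; insertion codes are
    rejected.  Residues are renumbered 1..n in file order.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(record_id, io.StringIO(text))
    models_out: list[Model] = []
    sequence = None
    for model in structure:
        chains = list(model)
        if len(chains) != 1:
            raise PDBParseError(
                f"model {model.id + 1}: expected a single chain, found {len(chains)}"
            )
        residues_out: Model = []
        seq_letters = []
        for resno, residue in enumerate(
            (r for r in chains[0] if r.id[0] == " "), start=1
        ):
            het, _, icode = residue.id
            if icode.strip():
                raise PDBParseError(
                    f"model {model.id + 1}, residue {resno}: insertion codes unsupported"
                )
            aa = seq1(residue.get_resname(), undef_code="X")
            coords = {}
            for atom in residue:
                # DisorderedAtom already selects the highest-occupancy altloc
                coords[atom.get_name()] = np.array(atom.get_coord(), dtype=float)
            for required in ("N", "CA", "C"):
                if required not in coords:
                    raise PDBParseError(
                        f"model {model.id + 1}, residue {resno} "
                        f"({residue.get_resname()}): missing backbone atom {required}"
                    )
            cb = coords.get("CB") if aa != "G" else None
            residues_out.append(
                BackboneResidue(
                    residue_index=resno,
                    amino_acid=aa,
                    N=coords["N"],
                    CA=coords["CA"],
                    C=coords["C"],
                    O=coords.get("O", coords["C"].copy()),
                    CB=cb,
                )
            )
            seq_letters.append(aa)
        if not residues_out:
            continue
        model_seq = "".join(seq_letters)
        if sequence is None:
            sequence = model_seq
        elif model_seq != sequence:
            raise PDBParseError("models disagree on the residue sequence")
        models_out.append(residues_out)
    if not models_out:
        raise PDBParseError("no models with residues found")
    record = PeptideRecord(id=record_id, sequence=sequence)
    return StructureEnsemble(peptide=record, models=models_out)


def write_pdb_models(ensemble: StructureEnsemble, remarks: Sequence[str] = ()) -> str:
    """Serialize an ensemble as multi-model PDB text.

    Occupancy 1.00, B-factor 0.00, element column filled; one MODEL/ENDMDL
    block per model even for single-model ensembles.  ``remarks`` are emitted
    as REMARK lines before the first model; per-model scores, if present, are
    written as ``REMARK   3 MODEL k SCORE`` lines.
    """
    lines = []
    for r in remarks:
        lines.append(f"REMARK   3 {r}")
    if ensemble.model_scores is not None:
        for k, s in enumerate(ensemble.model_scores, start=1):
            lines.append(f"REMARK   3 MODEL {k} SCORE {s:.6f}")
    serial = 1
    for k, model in enumerate(ensemble.models, start=1):
        lines.append(f"MODEL     {k:4d}")
        for res in model:
            res3 = seq3(res.amino_acid).upper()
            for name in res.atoms_present():
                xyz = res.atom(name)
                elem = name[0]
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}{res3:>4s} A{res.residue_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {elem:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention (right-handed); an eclipsed (cis) arrangement gives
    0 degrees.  Raises :class:`GeometryError` if three consecutive points are
    collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
        raise GeometryError("collinear points: torsion undefined")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = math.degrees(math.atan2(y, x))
    # torsion of the eclipsed arrangement is 180 under the normal-vector
    # formula above if measured between planes; atan2(y, x) as built is the
    # standard convention with cis = 0 already.
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_dihedrals(model: Model) -> list[tuple[Optional[float], Optional[float]]]:
    """Per-residue (phi, psi) in degrees; phi undefined at the first residue,
    psi at the last (returned as None)."""
    if len(model) < 2:
        raise ValueError("need at least 2 residues for backbone dihedrals")
    out: list[tuple[Optional[float], Optional[float]]] = []
    for i, res in enumerate(model):
        phi = psi = None
        if i > 0:
            phi = dihedral_angle(model[i - 1].C, res.N, res.CA, res.C)
        if i < len(model) - 1:
            psi = dihedral_angle(res.N, res.CA, res.C, model[i + 1].N)
        out.append((phi, psi))
    return out


def pairwise_distances(model: Model, atom_kind: str) -> np.ndarray:
    """Symmetric n x n matrix of atom_kind-atom_kind distances (Angstrom).

    Entries involving a residue lacking the atom (glycine CB) are NaN.
    """
    if atom_kind not in ("CA", "CB"):
        raise ValueError("atom_kind must be 'CA' or 'CB'")
    n = len(model)
    coords = np.full((n, 3), np.nan)
    for i, res in enumerate(model):
        a = res.atom(atom_kind)
        if a is not None:
            coords[i] = a
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    np.fill_diagonal(d, np.where(np.isnan(coords[:, 0]), np.nan, 0.0))
    return d


# ---------------------------------------------------------------------------
# Ideal-geometry builder
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position D with |C-D| = bond, angle(B,C,D) and
    torsion(A,B,C,D) as given."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("degenerate reference frame in atom placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


AngleList = Sequence[tuple[Optional[float], Optional[float]]]


def build_backbone(sequence: str, angles: AngleList) -> Model:
    """Construct a backbone with ideal covalent geometry from (phi, psi) lists.

    Undefined (None) angles default to 180 degrees (extended); omega is fixed
    trans.  CB is placed by the standard tetrahedral construction for every
    residue except glycine.  The construction round-trips:
    ``backbone_dihedrals(build_backbone(seq, a))`` recovers ``a`` to ~1e-6 deg.
    """
    n = len(sequence)
    bad = set(sequence) - set(ONE_LETTER)
    if bad:
        raise ValueError(f"invalid amino-acid letter(s): {sorted(bad)}")
    if len(angles) != n:
        raise ValueError(f"need {n} (phi, psi) pairs, got {len(angles)}")
    phi = [180.0 if a[0] is None else float(a[0]) for a in angles]
    psi = [180.0 if a[1] is None else float(a[1]) for a in angles]

    Ns = np.zeros((n, 3))
    CAs = np.zeros((n, 3))
    Cs = np.zeros((n, 3))
    # seed frame for residue 1
    Ns[0] = (0.0, 0.0, 0.0)
    CAs[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    Cs[0] = CAs[0] + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        Ns[i] = _place_atom(Ns[i - 1], CAs[i - 1], Cs[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CAs[i] = _place_atom(CAs[i - 1], Cs[i - 1], Ns[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        Cs[i] = _place_atom(Cs[i - 1], Ns[i], CAs[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])

    model: Model = []
    for i, aa in enumerate(sequence):
        if i < n - 1:
            # carbonyl O anti to the next amide N
            O = _place_atom(Ns[i + 1], CAs[i], Cs[i], BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            O = _place_atom(Ns[i], CAs[i], Cs[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        CB = None
        if aa != "G":
            CB = _place_atom(Ns[i], Cs[i], CAs[i], BOND_CA_CB, ANGLE_C_CA_CB, IMPROPER_N_C_CA_CB)
        model.append(
            BackboneResidue(
                residue_index=i + 1,
                amino_acid=aa,
                N=Ns[i],
                CA=CAs[i],
                C=Cs[i],
                O=O,
                CB=CB,
            )
        )
    return model


def model_coords(model: Model, atom_names: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
    """Stack the requested atoms of all residues into an (n_atoms, 3) array.

    Atoms a residue lacks (glycine CB) are skipped.
    """
    rows = []
    for res in model:
        for name in atom_names:
            a = res.atom(name)
            if a is not None:
                rows.append(a)
    return np.array(rows, dtype=float)


def copy_model(model: Model) -> Model:
    return [
        BackboneResidue(
            residue_index=r.residue_index,
            amino_acid=r.amino_acid,
            N=r.N.copy(),
            CA=r.CA.copy(),
            C=r.C.copy(),
            O=r.O.copy(),
            CB=None if r.CB is None else r.CB.copy(),
        )
        for r in model
    ]
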