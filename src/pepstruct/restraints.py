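"""Distance and dihedral restraints, and NMR-style restraint file dialects.

Network predictions give, per residue pair, a mean and standard deviation of
the CA-CA and CB-CB distance, and per backbone torsion a mean/sd of its cosine
and sine.  These become interval restraints:

* distance bounds  [mean - sd, mean + sd], lower clamped at 0;
* dihedral bounds  angle +/- 15 deg, where the angle is atan2(mean sin,
  mean cos), emitted only when both sd(cos) and sd(sin) are below 0.10.

For an n-residue peptide this nominally yields 2n(n-1) distance restraints —
each unordered pair contributes a CA and a CB restraint in both orientations.
Unique restraints are stored once with symmetrized bounds; the
dual-orientation count is reported alongside (``nominal_distance_count``).
At most 2(n-1) dihedral restraints exist (phi and psi for the residues where
they are defined).

Writers emit XPLOR-NIH ``.tbl`` and CYANA ``.upl``/``.lol``/``.aco`` dialects;
matching parsers are included for round-trip checks.  Restraint intervals are
represented unwrapped (a 180 deg angle gives bounds [165, 195]); the energy
code evaluates angular deviation on the circle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio.SeqUtils import seq3

__all__ = [
    "DIHEDRAL_SD_CUTOFF",
    "DIHEDRAL_HALF_WIDTH",
    "DistanceRestraint",
    "DihedralRestraint",
    "RestraintSet",
    "derive_distance_restraints",
    "derive_dihedral_restraints",
    "derive_restraints",
    "write_xplor",
    "parse_xplor",
    "write_cyana",
    "parse_cyana",
]

DIHEDRAL_SD_CUTOFF = 0.10  # on sd of cos and sin; strict <
DIHEDRAL_HALF_WIDTH = 15.0  # deg; bounds are mean +/- 15


@dataclass(frozen=True)
class DistanceRestraint:
    atom_kind: str  # CA | CB
    i: int  # 1-based, i < j
    j: int
    lower: float  # A
    upper: float

    def __post_init__(self):
        if self.atom_kind not in ("CA", "CB"):
            raise ValueError("atom_kind must be CA or CB")
        if not self.i < self.j:
            raise ValueError("require i < j")
        if self.lower < 0 or self.lower > self.upper:
            raise ValueError("require 0 <= lower <= upper")


@dataclass(frozen=True)
class DihedralRestraint:
    residue: int  # 1-based
    angle: str  # PHI | PSI
    lower: float  # deg, unwrapped; upper - lower == 30
    upper: float

    def __post_init__(self):
        if self.angle not in ("PHI", "PSI"):
            raise ValueError("angle must be PHI or PSI")
        if abs((self.upper - self.lower) - 2 * DIHEDRAL_HALF_WIDTH) > 1e-9:
            raise ValueError("dihedral interval width must be 30 deg")

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass
class RestraintSet:
    distances: list[DistanceRestraint]
    dihedrals: list[DihedralRestraint]
    n: int  # peptide length

    @property
    def nominal_distance_count(self) -> int:
        """Dual-orientation accounting: each stored unique pair counts twice,
        giving 2n(n-1) for a glycine-free peptide."""
        return 2 * len(self.distances)

    def __eq__(self, other):
        if not isinstance(other, RestraintSet):
            return NotImplemented

        def key(rs):
            return (
                sorted((r.atom_kind, r.i, r.j, round(r.lower, 6), round(r.upper, 6)) for r in rs.distances),
                sorted((r.angle, r.residue, round(r.lower, 6), round(r.upper, 6)) for r in rs.dihedrals),
                rs.n,
            )

        return key(self) == key(other)


# ---------------------------------------------------------------------------
# Derivation from prediction statistics
# ---------------------------------------------------------------------------

def derive_distance_restraints(stats) -> list[DistanceRestraint]:
    """Distance restraints [mean - sd, mean + sd] from prediction statistics.

    ``stats`` is a :class:`~pepstruct.featurize.PredictionStats`.  One CA and
    one CB restraint per unique residue pair i < j; glycine CB pairs are
    skipped (their entries are NaN in the CB matrices).
    """
    out: list[DistanceRestraint] = []
    n = stats.n
    for kind, mean, sd in (
        ("CA", stats.dca_mean, stats.dca_sd),
        ("CB", stats.dcb_mean, stats.dcb_sd),
    ):
        for i in range(n):
            for j in range(i + 1, n):
                m, s = mean[i, j], sd[i, j]
                if not (np.isfinite(m) and np.isfinite(s)):
                    continue
                out.append(
                    DistanceRestraint(
                        atom_kind=kind,
                        i=i + 1,
                        j=j + 1,
                        lower=max(0.0, float(m - s)),
                        upper=float(m + s),
                    )
                )
    return out


def derive_dihedral_restraints(
    stats, sd_cutoff: float = DIHEDRAL_SD_CUTOFF
) -> list[DihedralRestraint]:
    """Dihedral restraints angle +/- 15 deg where both trig sds pass the cutoff.

    The angle is recovered as atan2(mean sin, mean cos).  Columns of the trig
    block are (cos phi, sin phi, cos psi, sin psi).
    """
    out: list[DihedralRestraint] = []
    n = stats.n
    for r in range(n):
        for angle, (ci, si) in (("PHI", (0, 1)), ("PSI", (2, 3))):
            mc, ms = stats.trig_mean[r, ci], stats.trig_mean[r, si]
            sc, ss = stats.trig_sd[r, ci], stats.trig_sd[r, si]
            if not (np.isfinite(mc) and np.isfinite(ms)):
                continue
            if not (sc < sd_cutoff and ss < sd_cutoff):
                continue
            if abs(mc) < 1e-12 and abs(ms) < 1e-12:
                warnings.warn(
                    f"residue {r + 1} {angle}: mean cos and sin both zero; "
                    "direction undefined, restraint skipped"
                )
                continue
            center = math.degrees(math.atan2(ms, mc))
            out.append(
                DihedralRestraint(
                    residue=r + 1,
                    angle=angle,
                    lower=center - DIHEDRAL_HALF_WIDTH,
                    upper=center + DIHEDRAL_HALF_WIDTH,
                )
            )
    return out


def derive_restraints(stats, sd_cutoff: float = DIHEDRAL_SD_CUTOFF) -> RestraintSet:
    return RestraintSet(
        distances=derive_distance_restraints(stats),
        dihedrals=derive_dihedral_restraints(stats, sd_cutoff),
        n=stats.n,
    )


def _sorted_distances(rs: RestraintSet) -> list[DistanceRestraint]:
    # deterministic ordering: CA block then CB block, row-major
    return sorted(rs.distances, key=lambda r: (r.atom_kind, r.i, r.j))


def _sorted_dihedrals(rs: RestraintSet) -> list[DihedralRestraint]:
    return sorted(rs.dihedrals, key=lambda r: (r.residue, r.angle))


# ---------------------------------------------------------------------------
# XPLOR-NIH .tbl dialect
# ---------------------------------------------------------------------------

_PHI_ATOMS = ((-1, "C"), (0, "N"), (0, "CA"), (0, "C"))
_PSI_ATOMS = ((0, "N"), (0, "CA"), (0, "C"), (1, "N"))


def write_xplor(rs: RestraintSet) -> tuple[str, str]:
    """Render (distance .tbl text, dihedral .tbl text).

    Distance lines: ``assign (resid I and name K) (resid J and name K)
    D DMINUS DPLUS`` with D the bound midpoint.  Dihedral lines use the four
    standard phi/psi atoms, force constant 1.0, exponent 2, half-range 15.0.
    """
    dist_lines = ["! distance restraints"]
    for r in _sorted_distances(rs):
        d = 0.5 * (r.lower + r.upper)
        dist_lines.append(
            f"assign (resid {r.i} and name {r.atom_kind}) "
            f"(resid {r.j} and name {r.atom_kind}) "
            f"{d:.3f} {d - r.lower:.3f} {r.upper - d:.3f}"
        )
    dihe_lines = ["! dihedral restraints"]
    for r in _sorted_dihedrals(rs):
        atoms = _PHI_ATOMS if r.angle == "PHI" else _PSI_ATOMS
        sel = " ".join(
            f"(resid {r.residue + off} and name {name})" for off, name in atoms
        )
        dihe_lines.append(f"assign {sel} 1.0 {r.center:.3f} {DIHEDRAL_HALF_WIDTH:.1f} 2")
    return "\n".join(dist_lines) + "\n", "\n".join(dihe_lines) + "\n"


def parse_xplor(distance_tbl: str, dihedral_tbl: str, n: int) -> RestraintSet:
    """Parse the dialect emitted by :func:`write_xplor` back to a RestraintSet."""
    import re

    distances = []
    pat_d = re.compile(
        r"assign \(resid (\d+) and name (\w+)\) \(resid (\d+) and name (\w+)\) "
        r"([-\d.]+) ([-\d.]+) ([-\d.]+)"
    )
    for line in distance_tbl.splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = pat_d.fullmatch(line)
        if not m:
            raise ValueError(f"unparseable XPLOR distance line: {line!r}")
        i, kind, j, kind2, d, dminus, dplus = m.groups()
        if kind != kind2:
            raise ValueError(f"mixed atom kinds in line: {line!r}")
        d, dminus, dplus = float(d), float(dminus), float(dplus)
        distances.append(
            DistanceRestraint(kind, int(i), int(j), lower=d - dminus, upper=d + dplus)
        )
    dihedrals = []
    pat_a = re.compile(
        r"assign \(resid (\d+) and name (\w+)\)(?: \(resid \d+ and name \w+\)){3} "
        r"[-\d.]+ ([-\d.]+) [-\d.]+ \d+"
    )
    for line in dihedral_tbl.splitlines():
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        m = pat_a.fullmatch(line)
        if not m:
            raise ValueError(f"unparseable XPLOR dihedral line: {line!r}")
        resid1, name1, center = m.groups()
        # PHI starts at C of the previous residue; PSI starts at N of its own
        if name1 == "C":
            residue, angle = int(resid1) + 1, "PHI"
        else:
            residue, angle = int(resid1), "PSI"
        c = float(center)
        dihedrals.append(
            DihedralRestraint(
                residue, angle, lower=c - DIHEDRAL_HALF_WIDTH, upper=c + DIHEDRAL_HALF_WIDTH
            )
        )
    return RestraintSet(distances=distances, dihedrals=dihedrals, n=n)


# ---------------------------------------------------------------------------
# CYANA .upl / .lol / .aco dialect
# ---------------------------------------------------------------------------

def write_cyana(rs: RestraintSet, sequence: str) -> tuple[str, str, str]:
    """Render (.upl, .lol, .aco) texts.

    Distance lines: ``I RES3 ATOM J RES3 ATOM DIST`` (upper bounds in .upl,
    lower in .lol, 2 decimals); torsion lines: ``I RES3 ANGLE LOWER UPPER``.
    """
    res3 = [seq3(a).upper() for a in sequence]
    upl = ["# upper distance limits"]
    lol = ["# lower distance limits"]
    for r in _sorted_distances(rs):
        stem = (
            f"{r.i:>3d} {res3[r.i - 1]} {r.atom_kind:<2s} "
            f"{r.j:>3d} {res3[r.j - 1]} {r.atom_kind:<2s}"
        )
        upl.append(f"{stem} {r.upper:8.2f}")
        lol.append(f"{stem} {r.lower:8.2f}")
    aco = ["# torsion angle restraints"]
    for r in _sorted_dihedrals(rs):
        aco.append(
            f"{r.residue:>3d} {res3[r.residue - 1]} {r.angle:<3s} "
            f"{r.lower:8.2f} {r.upper:8.2f}"
        )
    return "\n".join(upl) + "\n", "\n".join(lol) + "\n", "\n".join(aco) + "\n"


def parse_cyana(upl: str, lol: str, aco: str, n: int) -> RestraintSet:
    """Parse the dialect emitted by :func:`write_cyana` back to a RestraintSet."""

    def data_lines(text):
        for line in text.splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                yield line.split()

    uppers = {}
    for f in data_lines(upl):
        uppers[(f[2], int(f[0]), int(f[3]))] = float(f[6])
    distances = []
    for f in data_lines(lol):
        key = (f[2], int(f[0]), int(f[3]))
        if key not in uppers:
            raise ValueError(f"lower bound without matching upper: {key}")
        distances.append(
            DistanceRestraint(key[0], key[1], key[2], lower=float(f[6]), upper=uppers[key])
        )
    dihedrals = [
        DihedralRestraint(int(f[0]), f[2], lower=float(f[3]), upper=float(f[4]))
        for f in data_lines(aco)
    ]
    return RestraintSet(distances=distances, dihedrals=dihedrals, n=n)
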