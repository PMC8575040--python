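"""Restrained structure calculation: torsion-space simulated annealing plus
Cartesian minimization under flat-bottom restraint potentials.

The original protocol hands the predicted restraints to XPLOR-NIH torsion
angle dynamics; re-implementing full TAD is out of proportion for this
package, so the engine performs Metropolis Monte-Carlo annealing in
(phi, psi) torsion space under the same temperature schedule — a
protocol-equivalent stand-in, not a claim of XPLOR-NIH parity.  Each of the
(default 100) independent runs starts from the preliminary structure built
from the predicted dihedral angles, randomly perturbed, cools from 2025 K to
25 K in 25 K decrements, accepting moves with probability exp(-dE/T), and is
finished by gradient-based Cartesian minimization with harmonic tethers
keeping bond lengths, bond angles and peptide-bond planarity at their ideal
values.  Models are ranked by their final total restraint energy.

Energy model (flat-bottom, zero inside all bounds):

* distance:  w_d * (max(0, d - upper)^2 + max(0, lower - d)^2)   [A^2]
* dihedral:  w_a * excess^2 where excess is the angular distance (deg) from
  theta to the restraint interval, measured on the circle; w_a converts
  deg^2 to rad^2
* steric:    w_s * max(0, r_min - r)^2 over non-bonded backbone-atom pairs
  (bond-graph separation >= 3), r_min = 2.8 A
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.distance import cdist

from .featurize import PredictionStats
from .restraints import DistanceRestraint, RestraintSet
from .structures import (
    ANGLE_C_CA_CB,
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_N_CA,
    IMPROPER_N_C_CA_CB,
    Model,
    PeptideRecord,
    StructureEnsemble,
    build_backbone,
    copy_model,
)

__all__ = [
    "AnnealSchedule",
    "EnergyWeights",
    "EnergyBreakdown",
    "load_config",
    "initial_structure",
    "restraint_energy",
    "anneal",
    "minimize_cartesian",
]

STERIC_RMIN = 2.8  # A
SS_BOND_BOUNDS = (3.0, 4.5)  # A, CB-CB for cyclization bonds
_BIG = 1e6  # effectively unbounded upper limit


@dataclass
class AnnealSchedule:
    """Cooling schedule: t_init -> t_final in t_step decrements.

    ``tolerance_factor`` mirrors the XPLOR-NIH annealing-stage parameter; it
    is carried for configuration compatibility but unused by this engine.
    """

    t_init: float = 2025.0
    t_final: float = 25.0
    t_step: float = 25.0
    steps_per_temperature: int = 50
    tolerance_factor: float = 100.0

    def temperatures(self) -> np.ndarray:
        if not self.t_init > self.t_final > 0:
            raise ValueError("require t_init > t_final > 0")
        n = round((self.t_init - self.t_final) / self.t_step)
        if abs(self.t_init - self.t_final - n * self.t_step) > 1e-9:
            raise ValueError("t_step must divide t_init - t_final")
        return self.t_init - self.t_step * np.arange(n + 1)


@dataclass
class EnergyWeights:
    w_d: float = 1.0  # A^-2
    w_a: float = (math.pi / 180.0) ** 2  # deg^-2 (rad^2-equivalent scaling)
    w_s: float = 4.0
    # geometry tethers (Cartesian minimization only)
    w_bond: float = 100.0  # A^-2
    w_angle: float = 50.0  # rad^-2
    w_planar: float = 10.0  # rad^-2, omega and CB-chirality torsion tethers


@dataclass
class EnergyBreakdown:
    distance_violation: float
    dihedral_violation: float
    steric: float

    @property
    def total(self) -> float:
        return self.distance_violation + self.dihedral_violation + self.steric


def load_config(text: str) -> tuple[AnnealSchedule, EnergyWeights]:
    """Parse schedule and weight overrides from JSON or ``key=value`` lines.

    Recognized keys are the field names of :class:`AnnealSchedule` and
    :class:`EnergyWeights`; unknown keys raise.  Lines starting with ``#``
    are comments in the key=value form.
    """
    import json

    text = text.strip()
    if text.startswith("{"):
        entries = json.loads(text)
    else:
        entries = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if not _:
                raise ValueError(f"expected key=value, got {line!r}")
            entries[key.strip()] = float(value)
    schedule = AnnealSchedule()
    weights = EnergyWeights()
    for key, value in entries.items():
        if hasattr(schedule, key):
            setattr(schedule, key, type(getattr(schedule, key))(value))
        elif hasattr(weights, key):
            setattr(weights, key, float(value))
        else:
            raise ValueError(f"unknown config key {key!r}")
    return schedule, weights


# ---------------------------------------------------------------------------
# Flat atom representation and the energy context
# ---------------------------------------------------------------------------

def _atom_layout(model: Model):
    """Flat atom index map: list of (res_idx, atom_name) and lookup dict."""
    names = []
    index = {}
    for i, res in enumerate(model):
        for name in res.atoms_present():
            index[(i, name)] = len(names)
            names.append((i, name))
    return names, index


def _flatten(model: Model) -> np.ndarray:
    return np.array(
        [res.atom(name) for i, res in enumerate(model) for name in res.atoms_present()]
    )


def _unflatten(model: Model, coords: np.ndarray) -> Model:
    out = copy_model(model)
    k = 0
    for res in out:
        for name in res.atoms_present():
            res.atom(name)[:] = coords[k]
            k += 1
    return out


class _EnergyContext:
    """Precompiled vectorized energy terms for one sequence + restraint set.

    Pair terms are (i, j, lower, upper, weight); torsion terms are
    (quadruple, center_deg, half_width_deg, weight) evaluated flat-bottomed on
    the circle (half_width 0 gives a harmonic); angle terms are (triple,
    target_rad, weight) harmonics.  Restraint terms and geometry tethers are
    kept separate so the Monte-Carlo stage can use restraints only.
    """

    def __init__(self, model: Model, rs: RestraintSet, weights: EnergyWeights):
        n = len(model)
        if rs.n != n:
            raise ValueError(f"restraint set is for n={rs.n}, model has {n} residues")
        self.weights = weights
        names, index = _atom_layout(model)
        self.n_atoms = len(names)
        self.index = index

        # --- distance restraints
        pi, pj, lo, up = [], [], [], []
        for r in rs.distances:
            if r.lower > r.upper:
                raise ValueError("restraint with lower > upper")
            a = index.get((r.i - 1, r.atom_kind))
            b = index.get((r.j - 1, r.atom_kind))
            if a is None or b is None:  # glycine CB
                continue
            pi.append(a)
            pj.append(b)
            lo.append(r.lower)
            up.append(r.upper)
        self.dist_i = np.array(pi, dtype=int)
        self.dist_j = np.array(pj, dtype=int)
        self.dist_lo = np.array(lo)
        self.dist_up = np.array(up)

        # --- dihedral restraints
        quads, centers, halfs = [], [], []
        for r in rs.dihedrals:
            i = r.residue - 1
            if r.angle == "PHI":
                if i == 0:
                    continue
                quad = [(i - 1, "C"), (i, "N"), (i, "CA"), (i, "C")]
            else:
                if i == n - 1:
                    continue
                quad = [(i, "N"), (i, "CA"), (i, "C"), (i + 1, "N")]
            quads.append([index[q] for q in quad])
            centers.append(r.center)
            halfs.append(0.5 * (r.upper - r.lower))
        self.tors_quads = np.array(quads, dtype=int).reshape(-1, 4)
        self.tors_center = np.array(centers)
        self.tors_half = np.array(halfs)

        # --- steric pairs: bond-graph separation >= 3
        adj = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)

        def bond(a, b):
            if a in index and b in index:
                adj[index[a], index[b]] = adj[index[b], index[a]] = True

        for i in range(n):
            bond((i, "N"), (i, "CA"))
            bond((i, "CA"), (i, "C"))
            bond((i, "C"), (i, "O"))
            bond((i, "CA"), (i, "CB"))
            if i + 1 < n:
                bond((i, "C"), (i + 1, "N"))
        # exclude 1-2, 1-3 and 1-4 pairs: 1-4 distances within the planar
        # peptide group (e.g. O(i)-CA(i+1) at 2.77 A) are fixed by covalent
        # geometry and must not register as clashes
        adj2 = adj @ adj
        near = adj | adj2 | (adj2 @ adj)
        np.fill_diagonal(near, True)
        iu, ju = np.triu_indices(self.n_atoms, k=1)
        keep = ~near[iu, ju]
        self.steric_i = iu[keep]
        self.steric_j = ju[keep]

        # --- geometry tethers (pair: bonds; angle triples; torsion tethers)
        gi, gj, gr = [], [], []
        for i in range(n):
            for (a, b, r0) in (
                ((i, "N"), (i, "CA"), BOND_N_CA),
                ((i, "CA"), (i, "C"), BOND_CA_C),
                ((i, "C"), (i, "O"), BOND_C_O),
                ((i, "CA"), (i, "CB"), BOND_CA_CB),
            ):
                if a in index and b in index:
                    gi.append(index[a])
                    gj.append(index[b])
                    gr.append(r0)
            if i + 1 < n:
                gi.append(index[(i, "C")])
                gj.append(index[(i + 1, "N")])
                gr.append(BOND_C_N)
        self.bond_i = np.array(gi, dtype=int)
        self.bond_j = np.array(gj, dtype=int)
        self.bond_r0 = np.array(gr)

        triples, targets = [], []
        for i in range(n):
            cand = [
                ((i, "N"), (i, "CA"), (i, "C"), ANGLE_N_CA_C),
                ((i, "CA"), (i, "C"), (i, "O"), ANGLE_CA_C_O),
                ((i, "C"), (i, "CA"), (i, "CB"), ANGLE_C_CA_CB),
            ]
            if i + 1 < n:
                cand += [
                    ((i, "CA"), (i, "C"), (i + 1, "N"), ANGLE_CA_C_N),
                    ((i, "C"), (i + 1, "N"), (i + 1, "CA"), ANGLE_C_N_CA),
                ]
            for (a, b, c, t) in cand:
                if a in index and b in index and c in index:
                    triples.append((index[a], index[b], index[c]))
                    targets.append(math.radians(t))
        self.angle_triples = np.array(triples, dtype=int).reshape(-1, 3)
        self.angle_target = np.array(targets)

        tquads, tcenters = [], []
        for i in range(n - 1):  # omega tether: CA(i)-C(i)-N(i+1)-CA(i+1) at 180
            tquads.append(
                [index[(i, "CA")], index[(i, "C")], index[(i + 1, "N")], index[(i + 1, "CA")]]
            )
            tcenters.append(180.0)
        for i in range(n):  # CB chirality tether: N-C-CA-CB at +122.6
            if (i, "CB") in index:
                tquads.append(
                    [index[(i, "N")], index[(i, "C")], index[(i, "CA")], index[(i, "CB")]]
                )
                tcenters.append(IMPROPER_N_C_CA_CB)
        self.geo_quads = np.array(tquads, dtype=int).reshape(-1, 4)
        self.geo_center = np.array(tcenters)

    # -- evaluation -------------------------------------------------------

    def restraint_terms(self, coords: np.ndarray) -> EnergyBreakdown:
        w = self.weights
        e_d = 0.0
        if len(self.dist_i):
            d = np.linalg.norm(coords[self.dist_i] - coords[self.dist_j], axis=1)
            over = np.maximum(0.0, d - self.dist_up)
            under = np.maximum(0.0, self.dist_lo - d)
            e_d = w.w_d * float(np.sum(over**2) + np.sum(under**2))
        e_a = 0.0
        if len(self.tors_quads):
            theta = _torsion(coords, self.tors_quads)
            delta = _wrap(theta - self.tors_center)
            excess = np.maximum(0.0, np.abs(delta) - self.tors_half)
            e_a = w.w_a * float(np.sum(excess**2))
        e_s = 0.0
        if len(self.steric_i):
            r = np.linalg.norm(coords[self.steric_i] - coords[self.steric_j], axis=1)
            e_s = w.w_s * float(np.sum(np.maximum(0.0, STERIC_RMIN - r) ** 2))
        return EnergyBreakdown(e_d, e_a, e_s)

    def restraint_energy(self, coords: np.ndarray) -> float:
        return self.restraint_terms(coords).total

    def total_energy_grad(self, coords: np.ndarray):
        """(restraint + geometry-tether energy, gradient) for minimization."""
        w = self.weights
        g = np.zeros_like(coords)
        e = 0.0
        # flat-bottom distances
        if len(self.dist_i):
            e += _pair_flat(coords, g, self.dist_i, self.dist_j, self.dist_lo, self.dist_up, w.w_d)
        # steric
        if len(self.steric_i):
            zeros = np.full(len(self.steric_i), STERIC_RMIN)
            e += _pair_flat(coords, g, self.steric_i, self.steric_j, zeros,
                            np.full(len(self.steric_i), _BIG), w.w_s)
        # bonds (harmonic = flat bottom of zero width)
        e += _pair_flat(coords, g, self.bond_i, self.bond_j, self.bond_r0, self.bond_r0, w.w_bond)
        # dihedral restraints
        if len(self.tors_quads):
            e += _torsion_flat(coords, g, self.tors_quads, self.tors_center, self.tors_half, w.w_a)
        # geometry torsion tethers (harmonic)
        if len(self.geo_quads):
            zeros = np.zeros(len(self.geo_quads))
            e += _torsion_flat(coords, g, self.geo_quads, self.geo_center, zeros,
                               w.w_planar * (math.pi / 180.0) ** 2)
        # bond-angle harmonics
        e += _angle_harmonic(coords, g, self.angle_triples, self.angle_target, w.w_angle)
        return e, g


def _wrap(deg):
    """Wrap angles (deg) to (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def _torsion(coords, quads):
    """Vectorized torsion angles (deg) for an array of atom quadruples."""
    p = coords[quads]  # (K, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2, axis=1) / np.maximum(nb2, 1e-12)
    return np.degrees(np.arctan2(y, x))


def _pair_flat(coords, g, ai, aj, lo, up, w):
    """Accumulate flat-bottom pair energy into g; returns the energy."""
    dvec = coords[ai] - coords[aj]
    d = np.linalg.norm(dvec, axis=1)
    d_safe = np.maximum(d, 1e-9)
    over = np.maximum(0.0, d - up)
    under = np.maximum(0.0, lo - d)
    e = w * float(np.sum(over**2) + np.sum(under**2))
    coef = 2.0 * w * (over - under) / d_safe  # dE/dd * 1/d
    gi = coef[:, None] * dvec
    np.add.at(g, ai, gi)
    np.add.at(g, aj, -gi)
    return e


def _angle_harmonic(coords, g, triples, target, w):
    p = coords[triples]  # (K, 3, 3)
    u = p[:, 0] - p[:, 1]
    v = p[:, 2] - p[:, 1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    theta = np.arccos(cos)
    sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
    diff = theta - target
    e = w * float(np.sum(diff**2))
    dEdt = 2.0 * w * diff
    dA = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
    dC = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
    np.add.at(g, triples[:, 0], dEdt[:, None] * dA)
    np.add.at(g, triples[:, 2], dEdt[:, None] * dC)
    np.add.at(g, triples[:, 1], dEdt[:, None] * (-dA - dC))
    return e


def _torsion_flat(coords, g, quads, center, half, w):
    """Flat-bottom circular torsion energy + gradient accumulation.

    Energies are w * excess^2 with excess in degrees; gradients converted
    accordingly.
    """
    p = coords[quads]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2, axis=1) / np.maximum(nb2, 1e-12)
    theta = np.degrees(np.arctan2(y, x))
    delta = _wrap(theta - center)
    excess = np.maximum(0.0, np.abs(delta) - half)
    e = w * float(np.sum(excess**2))
    active = excess > 0
    if not np.any(active):
        return e
    # dtheta/dx in rad/A (standard rigid-rotation formulas)
    n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
    n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
    F1 = (-(nb2 / n1sq))[:, None] * n1
    F4 = (nb2 / n2sq)[:, None] * n2
    t = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
    s = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
    G1 = F1
    G2 = -(1.0 + t) * F1 + s * F4
    G3 = t * F1 - (1.0 + s) * F4
    G4 = F4
    # dE/dtheta_deg, chain to rad
    dEdt = 2.0 * w * excess * np.sign(delta) * (180.0 / math.pi)
    for col, G in zip(range(4), (G1, G2, G3, G4)):
        np.add.at(g, quads[active, col], dEdt[active, None] * G[active])
    return e


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def predicted_angles(source, n: int) -> list[tuple[Optional[float], Optional[float]]]:
    """Per-residue (phi, psi) from prediction statistics or a restraint set.

    Angles without a prediction (or whose restraint was filtered out) are
    None.
    """
    phi = [None] * n
    psi = [None] * n
    if isinstance(source, PredictionStats):
        for i in range(n):
            for angle, (ci, si), store in (("PHI", (0, 1), phi), ("PSI", (2, 3), psi)):
                mc, ms = source.trig_mean[i, ci], source.trig_mean[i, si]
                if np.isfinite(mc) and np.isfinite(ms) and (abs(mc) > 1e-12 or abs(ms) > 1e-12):
                    store[i] = math.degrees(math.atan2(ms, mc))
    elif isinstance(source, RestraintSet):
        for r in source.dihedrals:
            (phi if r.angle == "PHI" else psi)[r.residue - 1] = _wrap(r.center).item()
    elif source is not None:
        raise TypeError("source must be PredictionStats, RestraintSet or None")
    return list(zip(phi, psi))


def initial_structure(record: PeptideRecord, source=None) -> Model:
    """Preliminary ideal-geometry structure from predicted dihedral angles.

    Residues without predictions are extended (180 deg); with no source at
    all the chain is fully extended.
    """
    return build_backbone(record.sequence, predicted_angles(source, len(record)))


def _with_ss_bond_restraints(record: PeptideRecord, rs: RestraintSet) -> RestraintSet:
    """Add CB-CB distance restraints for the record's cyclization bonds."""
    if not record.cyclic_bonds:
        return rs
    extra = []
    existing = {(r.atom_kind, r.i, r.j) for r in rs.distances}
    for (i, j) in record.cyclic_bonds:
        a, b = min(i, j), max(i, j)
        if ("CB", a, b) not in existing:
            extra.append(DistanceRestraint("CB", a, b, *SS_BOND_BOUNDS))
    return RestraintSet(distances=rs.distances + extra, dihedrals=rs.dihedrals, n=rs.n)


def restraint_energy(model: Model, rs: RestraintSet, weights: Optional[EnergyWeights] = None) -> EnergyBreakdown:
    """Flat-bottom restraint energy of a model (zero inside all bounds)."""
    ctx = _EnergyContext(model, rs, weights or EnergyWeights())
    return ctx.restraint_terms(_flatten(model))


def minimize_cartesian(
    model: Model,
    rs: RestraintSet,
    weights: Optional[EnergyWeights] = None,
    max_iters: int = 300,
) -> Model:
    """Gradient descent (L-BFGS) on restraint energy plus geometry tethers."""
    weights = weights or EnergyWeights()
    ctx = _EnergyContext(model, rs, weights)
    x0 = _flatten(model)

    def fun(x):
        e, g = ctx.total_energy_grad(x.reshape(-1, 3))
        if not np.isfinite(e) or not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite energy/gradient in minimization")
        return e, g.ravel()

    e0 = fun(x0.ravel())[0]
    res = scipy_minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                         options={"maxiter": max_iters})
    if res.fun <= e0:
        return _unflatten(model, res.x.reshape(-1, 3))
    return copy_model(model)  # descent contract: never return a worse model


class _TorsionSampler:
    """Pivot-move machinery: rotate everything downstream of a phi/psi bond."""

    def __init__(self, model: Model):
        self.n = len(model)
        names, index = _atom_layout(model)
        self.index = index
        self.moves = []  # (axis_a_idx, axis_b_idx, moved_idx_array)
        n_atoms = len(names)
        for i in range(self.n):
            downstream = [
                k for k, (ri, nm) in enumerate(names)
                if ri > i or (ri == i and nm in ("C", "O", "CB"))
            ]
            self.moves.append((index[(i, "N")], index[(i, "CA")],
                               np.array(downstream, dtype=int)))  # phi_i
            downstream = [
                k for k, (ri, nm) in enumerate(names)
                if ri > i or (ri == i and nm == "O")
            ]
            self.moves.append((index[(i, "CA")], index[(i, "C")],
                               np.array(downstream, dtype=int)))  # psi_i

    def rotate(self, coords: np.ndarray, move_idx: int, delta_deg: float) -> np.ndarray:
        a_idx, b_idx, moved = self.moves[move_idx]
        axis = coords[b_idx] - coords[a_idx]
        axis = axis / np.linalg.norm(axis)
        ang = math.radians(delta_deg)
        c, s = math.cos(ang), math.sin(ang)
        v = coords[moved] - coords[b_idx]
        # Rodrigues rotation
        rotated = (v * c + np.cross(axis, v) * s
                   + np.outer(v @ axis, axis) * (1.0 - c))
        out = coords.copy()
        out[moved] = rotated + coords[b_idx]
        return out


def anneal(
    record: PeptideRecord,
    rs: RestraintSet,
    n_structures: int = 100,
    schedule: Optional[AnnealSchedule] = None,
    seed: int = 0,
    weights: Optional[EnergyWeights] = None,
    stats: Optional[PredictionStats] = None,
    initial_perturbation: float = 30.0,
    max_move: float = 60.0,
    minimize_iters: int = 300,
) -> StructureEnsemble:
    """Fold a peptide into a ranked ensemble under a restraint set.

    ``n_structures`` independent Monte-Carlo runs (fully reproducible given
    ``seed``), each followed by Cartesian minimization; the returned ensemble
    is sorted by ascending total restraint energy with ``model_scores``
    populated.  Dihedral angles for the preliminary structure come from
    ``stats`` when given, else from the restraint set's dihedral centers.
    Cyclization bonds of the record are enforced as CB-CB distance restraints
    in [3.0, 4.5] A.
    """
    schedule = schedule or AnnealSchedule()
    weights = weights or EnergyWeights()
    for r in rs.distances:
        if r.lower > r.upper:
            raise ValueError(f"restraint with lower > upper: {r}")
    rs = _with_ss_bond_restraints(record, rs)
    base = initial_structure(record, stats if stats is not None else rs)
    ctx = _EnergyContext(base, rs, weights)
    sampler = _TorsionSampler(base)
    temperatures = schedule.temperatures()
    n_moves = len(sampler.moves)

    seeds = np.random.SeedSequence(seed).spawn(n_structures)
    models: list[Model] = []
    scores: list[float] = []
    base_coords = _flatten(base)
    for run in range(n_structures):
        rng = np.random.default_rng(seeds[run])
        coords = base_coords.copy()
        # randomized initial torsion perturbation
        for mv in range(n_moves):
            coords = sampler.rotate(coords, mv, rng.normal(0.0, initial_perturbation))
        energy = ctx.restraint_energy(coords)
        for T in temperatures:
            width = max_move * math.sqrt(T / schedule.t_init)
            for _ in range(schedule.steps_per_temperature):
                mv = int(rng.integers(n_moves))
                delta = rng.normal(0.0, width)
                cand = sampler.rotate(coords, mv, delta)
                e_new = ctx.restraint_energy(cand)
                if e_new <= energy or rng.random() < math.exp(-(e_new - energy) / T):
                    coords, energy = cand, e_new
        model = minimize_cartesian(_unflatten(base, coords), rs, weights,
                                   max_iters=minimize_iters)
        models.append(model)
        scores.append(ctx.restraint_energy(_flatten(model)))

    order = np.argsort(scores, kind="stable")
    ensemble = StructureEnsemble(
        peptide=record,
        models=[models[k] for k in order],
        model_scores=[float(scores[k]) for k in order],
    )
    return ensemble
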