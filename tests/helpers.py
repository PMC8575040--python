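"""Independent test oracles, kept free of the implementation under test."""

import numpy as np


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion characteristic matrix.

    Independent of the SVD/rotation-based route used by the package.
    """
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    M = B0.T @ A0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    ga = float(np.sum(A0 * A0))
    gb = float(np.sum(B0 * B0))
    return float(np.sqrt(max(0.0, ga + gb - 2.0 * lam_max) / len(A)))


def brute_force_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle by explicit plane-normal construction (degrees)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    axis = (p3 - p2) / np.linalg.norm(p3 - p2)
    cos = float(np.clip(n1 @ n2, -1.0, 1.0))
    sign = np.sign(np.cross(n1, n2) @ axis) or 1.0
    return float(np.degrees(np.arccos(cos)) * sign)


def random_rigid_transform(rng):
    """Random proper rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=5.0, size=3)
    return R, t


def scale_to_rc_rmsd(reference_ensemble, target_rmsd, seed=0, tol=1e-4):
    """Construct a single-model ensemble at a prescribed rigid-core B-RMSD.

    Adds a smooth low-frequency deformation to the reference's first model and
    bisects its amplitude until the RC B-RMSD matches ``target_rmsd``.
    """
    from pepstruct.evaluate import backbone_rmsd, rigid_core
    from pepstruct.structures import StructureEnsemble, copy_model

    base = reference_ensemble.models[0]
    core = rigid_core(reference_ensemble)
    n = len(base)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    direction = np.stack(
        [np.sin(2.0 * np.pi * np.arange(n) / n * (k + 1) + phase[k]) for k in range(3)],
        axis=1,
    )

    def deformed(amp):
        model = copy_model(base)
        for i, res in enumerate(model):
            for name in res.atoms_present():
                res.atom(name)[:] += amp * direction[i]
        return model

    lo, hi = 0.0, 50.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        r = backbone_rmsd(deformed(mid), base, core)
        if r < target_rmsd:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    model = deformed(0.5 * (lo + hi))
    return StructureEnsemble(
        peptide=reference_ensemble.peptide, models=[model], model_scores=[0.0]
    )
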