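import numpy as np
import pytest

from pepstruct import anneal as an
from pepstruct import synthetic as sy
from pepstruct.evaluate import backbone_rmsd
from pepstruct.restraints import DistanceRestraint, RestraintSet
from pepstruct.structures import PeptideRecord, backbone_dihedrals, build_backbone

FAST = an.AnnealSchedule(steps_per_temperature=10)


def circ_diff(a, b):
    """Smallest angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestSchedule:
    def test_default_temperature_ladder(self):
        temps = an.AnnealSchedule().temperatures()
        assert temps[0] == 2025.0
        assert temps[-1] == 25.0
        assert np.all(np.diff(temps) == -25.0)

    def test_step_must_divide_range(self):
        with pytest.raises(ValueError, match="divide"):
            an.AnnealSchedule(t_init=2000.0, t_final=25.0, t_step=150.0).temperatures()


class TestLoadConfig:
    def test_key_value_form(self):
        schedule, weights = an.load_config(
            "# comment\nt_init = 1000\nsteps_per_temperature = 5\nw_d = 2.5\n"
        )
        assert schedule.t_init == 1000.0
        assert schedule.steps_per_temperature == 5
        assert weights.w_d == 2.5
        assert schedule.t_final == 25.0  # untouched defaults

    def test_json_form(self):
        schedule, weights = an.load_config('{"t_step": 50, "w_s": 1.0}')
        assert schedule.t_step == 50.0
        assert weights.w_s == 1.0

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown config key"):
            an.load_config("bogus = 1\n")


class TestInitialStructure:
    def test_round_trip_from_restraint_centers(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        record = helix12.peptide
        model = an.initial_structure(record, rs)
        for i, (phi, psi) in enumerate(backbone_dihedrals(model)):
            if phi is not None:
                assert phi == pytest.approx(-57.0, abs=1e-6)
            if psi is not None:
                assert psi == pytest.approx(-47.0, abs=1e-6)

    def test_no_source_gives_extended_chain(self):
        record = PeptideRecord(id="x", sequence="ACDEF")
        model = an.initial_structure(record)
        for phi, psi in backbone_dihedrals(model):
            if phi is not None:
                assert circ_diff(phi, 180.0) < 1e-6
            if psi is not None:
                assert circ_diff(psi, 180.0) < 1e-6

    def test_partial_predictions_fill_gaps_extended(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        partial = RestraintSet(
            distances=rs.distances,
            dihedrals=[r for r in rs.dihedrals if r.residue != 5],
            n=rs.n,
        )
        model = an.initial_structure(helix12.peptide, partial)
        angles = backbone_dihedrals(model)
        assert circ_diff(angles[4][0], 180.0) < 1e-6
        assert angles[5][0] == pytest.approx(-57.0, abs=1e-6)


class TestRestraintEnergy:
    def test_flat_bottom_zero_inside_bounds(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        eb = an.restraint_energy(helix12.models[0], rs)
        assert eb.distance_violation == 0.0
        assert eb.dihedral_violation == 0.0
        assert eb.steric == 0.0
        assert eb.total == 0.0

    def test_single_pair_violation_quadratic(self):
        model = build_backbone("AAAAA", [(180.0, 180.0)] * 5)
        d13 = float(np.linalg.norm(model[0].CA - model[2].CA))
        rs = RestraintSet([DistanceRestraint("CA", 1, 3, 0.0, d13 - 1.0)], [], n=5)
        eb = an.restraint_energy(model, rs)
        assert eb.distance_violation == pytest.approx(1.0, rel=1e-9)  # (d-(d-1))^2

    def test_mismatched_lengths_rejected(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        short = build_backbone("AAAAA", [(180.0, 180.0)] * 5)
        with pytest.raises(ValueError, match="n="):
            an.restraint_energy(short, rs)

    def test_total_is_sum_of_components(self, mixed16):
        rs = sy.oracle_restraints(mixed16, dist_slack=0.1)
        perturbed = an._unflatten(
            mixed16.models[0],
            an._flatten(mixed16.models[0]) + np.random.default_rng(0).normal(0, 0.6, (len(an._flatten(mixed16.models[0])), 3)),
        )
        eb = an.restraint_energy(perturbed, rs)
        assert eb.total == pytest.approx(eb.distance_violation + eb.dihedral_violation + eb.steric)
        assert eb.distance_violation > 0


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, strand10):
        rs = sy.oracle_restraints(strand10, dist_slack=0.2)
        ctx = an._EnergyContext(strand10.models[0], rs, an.EnergyWeights())
        rng = np.random.default_rng(1)
        x = an._flatten(strand10.models[0]) + rng.normal(0, 0.4, size=(50, 3))
        _, g = ctx.total_energy_grad(x)
        eps = 1e-6
        for k in rng.integers(0, x.shape[0], size=12):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[k, d] += eps
                xm[k, d] -= eps
                num = (ctx.total_energy_grad(xp)[0] - ctx.total_energy_grad(xm)[0]) / (2 * eps)
                assert g[k, d] == pytest.approx(num, rel=1e-4, abs=1e-4)


class TestMinimizeCartesian:
    def test_descent_contract(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.3)
        rng = np.random.default_rng(2)
        start = an._unflatten(
            helix12.models[0],
            an._flatten(helix12.models[0]) + rng.normal(0, 0.5, (60, 3)),
        )
        e_before = an.restraint_energy(start, rs).total
        out = an.minimize_cartesian(start, rs)
        e_after = an.restraint_energy(out, rs).total
        assert e_after <= e_before
        assert e_before > 0

    def test_already_minimal_structure_unchanged_energy(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        out = an.minimize_cartesian(helix12.models[0], rs)
        assert an.restraint_energy(out, rs).total == pytest.approx(0.0, abs=1e-9)

    def test_violations_reduced_on_perturbed_helix(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.25)
        rng = np.random.default_rng(3)
        start = an._unflatten(
            helix12.models[0],
            an._flatten(helix12.models[0]) + rng.normal(0, 0.4, (60, 3)),
        )
        before = an.restraint_energy(start, rs)
        after = an.restraint_energy(an.minimize_cartesian(start, rs), rs)
        assert after.distance_violation < before.distance_violation


class TestAnneal:
    def test_ensemble_size_and_ranking(self, strand10):
        rs = sy.oracle_restraints(strand10, dist_slack=0.5)
        out = an.anneal(strand10.peptide, rs, n_structures=4, schedule=FAST, seed=5)
        assert out.n_models == 4
        assert out.model_scores == sorted(out.model_scores)

    def test_bitwise_determinism(self, strand10):
        rs = sy.oracle_restraints(strand10, dist_slack=0.5)
        a = an.anneal(strand10.peptide, rs, n_structures=3, schedule=FAST, seed=9)
        b = an.anneal(strand10.peptide, rs, n_structures=3, schedule=FAST, seed=9)
        assert a.model_scores == b.model_scores
        for ma, mb in zip(a.models, b.models):
            assert np.array_equal(an._flatten(ma), an._flatten(mb))

    def test_invalid_bounds_rejected_before_start(self, strand10):
        rs = sy.oracle_restraints(strand10, dist_slack=0.5)
        bad = RestraintSet(
            distances=rs.distances + [DistanceRestraint.__new__(DistanceRestraint)],
            dihedrals=[],
            n=rs.n,
        )
        # craft an invalid restraint bypassing __post_init__
        object.__setattr__(bad.distances[-1], "atom_kind", "CA")
        object.__setattr__(bad.distances[-1], "i", 1)
        object.__setattr__(bad.distances[-1], "j", 2)
        object.__setattr__(bad.distances[-1], "lower", 5.0)
        object.__setattr__(bad.distances[-1], "upper", 4.0)
        with pytest.raises(ValueError, match="lower > upper"):
            an.anneal(strand10.peptide, bad, n_structures=1, schedule=FAST, seed=0)

    def test_cyclization_bond_added_as_cb_restraint(self):
        record = PeptideRecord(id="cyc", sequence="CAAAAAAC", cyclic_bonds=((1, 8),))
        rs = RestraintSet([], [], n=8)
        out = an._with_ss_bond_restraints(record, rs)
        assert len(out.distances) == 1
        r = out.distances[0]
        assert (r.atom_kind, r.i, r.j) == ("CB", 1, 8)
        assert (r.lower, r.upper) == an.SS_BOND_BOUNDS

    def test_oracle_restraint_recovery_on_helix(self, helix12):
        """Tight oracle restraints pull the annealer back to the source fold."""
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        out = an.anneal(helix12.peptide, rs, n_structures=5, seed=7)
        best = min(backbone_rmsd(m, helix12.models[0]) for m in out.models)
        assert best < 1.0
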