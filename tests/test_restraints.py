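import math

import numpy as np
import pytest

from pepstruct import restraints as rst
from pepstruct import synthetic as sy
from pepstruct.anneal import restraint_energy
from pepstruct.featurize import PredictionStats
from pepstruct.structures import backbone_dihedrals, pairwise_distances


def _stats(n, dca=8.0, sd=0.5, trig_sd=0.05, rng=None):
    """Uniform synthetic prediction statistics for an n-mer."""
    dca_mean = np.full((n, n), dca)
    np.fill_diagonal(dca_mean, 0.0)
    trig_mean = np.tile([1.0, 0.0, 0.0, 1.0], (n, 1))
    trig_mean[0, 0:2] = np.nan
    trig_mean[n - 1, 2:4] = np.nan
    return PredictionStats(
        dca_mean=dca_mean,
        dca_sd=np.full((n, n), sd),
        dcb_mean=dca_mean.copy(),
        dcb_sd=np.full((n, n), sd),
        trig_mean=trig_mean,
        trig_sd=np.full((n, 4), trig_sd),
    )


class TestDeriveDistanceRestraints:
    def test_count_law_for_10mer(self):
        out = rst.derive_distance_restraints(_stats(10))
        assert len(out) == 90  # unique pairs: 45 CA + 45 CB
        rs = rst.RestraintSet(out, [], n=10)
        assert rs.nominal_distance_count == 2 * 10 * 9

    def test_bounds_are_mean_plus_minus_sd(self):
        out = rst.derive_distance_restraints(_stats(5, dca=6.0, sd=0.5))
        r = next(x for x in out if (x.atom_kind, x.i, x.j) == ("CA", 1, 2))
        assert r.lower == pytest.approx(5.5) and r.upper == pytest.approx(6.5)

    def test_lower_bound_clamped_at_zero(self):
        out = rst.derive_distance_restraints(_stats(5, dca=1.0, sd=3.0))
        assert all(r.lower == 0.0 for r in out)
        assert all(r.upper == pytest.approx(4.0) for r in out)

    def test_glycine_pairs_skipped(self):
        stats = _stats(6)
        stats.dcb_mean[2, :] = np.nan
        stats.dcb_mean[:, 2] = np.nan
        out = rst.derive_distance_restraints(stats)
        cb = [r for r in out if r.atom_kind == "CB"]
        assert len(cb) == 10  # C(5,2) pairs among the 5 non-glycine residues
        assert not any(r.i == 3 or r.j == 3 for r in cb)


class TestDeriveDihedralRestraints:
    def test_emitted_with_15_degree_half_width(self):
        out = rst.derive_dihedral_restraints(_stats(6, trig_sd=0.05))
        phi2 = next(r for r in out if (r.residue, r.angle) == (2, "PHI"))
        # mean cos 1, mean sin 0 -> angle 0, bounds [-15, +15]
        assert phi2.lower == pytest.approx(-15.0) and phi2.upper == pytest.approx(15.0)

    def test_sd_cutoff_excludes(self):
        stats = _stats(6, trig_sd=0.05)
        stats.trig_sd[2, 0] = 0.12  # sd(cos phi) above the 0.10 cutoff
        out = rst.derive_dihedral_restraints(stats)
        assert not any(r.residue == 3 and r.angle == "PHI" for r in out)
        assert any(r.residue == 3 and r.angle == "PSI" for r in out)

    def test_count_law_max_2_n_minus_1(self):
        n = 9
        out = rst.derive_dihedral_restraints(_stats(n, trig_sd=0.01))
        assert len(out) == 2 * (n - 1)

    def test_angle_180_gives_unwrapped_bounds(self):
        stats = _stats(5, trig_sd=0.01)
        stats.trig_mean[2, 0] = -1.0  # cos phi
        stats.trig_mean[2, 1] = 0.0
        out = rst.derive_dihedral_restraints(stats)
        phi3 = next(r for r in out if (r.residue, r.angle) == (3, "PHI"))
        assert phi3.lower == pytest.approx(165.0) and phi3.upper == pytest.approx(195.0)

    def test_zero_direction_skipped_with_warning(self):
        stats = _stats(5, trig_sd=0.01)
        stats.trig_mean[2, 0] = 0.0
        stats.trig_mean[2, 1] = 0.0
        with pytest.warns(UserWarning, match="direction undefined"):
            out = rst.derive_dihedral_restraints(stats)
        assert not any(r.residue == 3 and r.angle == "PHI" for r in out)

    def test_every_interval_width_is_30(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        assert all(r.upper - r.lower == pytest.approx(30.0) for r in rs.dihedrals)


class TestWriters:
    def _single_ca_set(self):
        return rst.RestraintSet(
            distances=[rst.DistanceRestraint("CA", 2, 9, 4.5, 6.1)],
            dihedrals=[],
            n=10,
        )

    def test_xplor_distance_line_format(self):
        dist, _ = rst.write_xplor(self._single_ca_set())
        assert "assign (resid 2 and name CA) (resid 9 and name CA) 5.300 0.800 0.800" in dist

    def test_cyana_line_formats(self):
        rs = rst.RestraintSet(
            distances=[rst.DistanceRestraint("CA", 2, 9, 4.5, 6.1)],
            dihedrals=[rst.DihedralRestraint(3, "PHI", -72.0, -42.0)],
            n=10,
        )
        upl, lol, aco = rst.write_cyana(rs, "A" * 10)
        assert ["2", "ALA", "CA", "9", "ALA", "CA", "6.10"] in [l.split() for l in upl.splitlines()]
        assert ["2", "ALA", "CA", "9", "ALA", "CA", "4.50"] in [l.split() for l in lol.splitlines()]
        assert ["3", "ALA", "PHI", "-72.00", "-42.00"] in [l.split() for l in aco.splitlines()]

    def test_empty_set_gives_header_only(self):
        dist, dihe = rst.write_xplor(rst.RestraintSet([], [], n=5))
        assert dist.startswith("!") and len(dist.splitlines()) == 1
        assert dihe.startswith("!") and len(dihe.splitlines()) == 1

    def test_xplor_round_trip_byte_identical(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        dist1, dihe1 = rst.write_xplor(rs)
        back = rst.parse_xplor(dist1, dihe1, n=rs.n)
        dist2, dihe2 = rst.write_xplor(back)
        assert dist1 == dist2 and dihe1 == dihe2

    def test_cyana_round_trip_byte_identical(self, helix12):
        seq = helix12.sequence()
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        texts1 = rst.write_cyana(rs, seq)
        back = rst.parse_cyana(*texts1, n=rs.n)
        texts2 = rst.write_cyana(back, seq)
        assert texts1 == texts2

    def test_cyana_round_trip_preserves_restraint_set(self, helix12):
        rs = sy.oracle_restraints(helix12, dist_slack=0.5)
        upl, lol, aco = rst.write_cyana(rs, helix12.sequence())
        back = rst.parse_cyana(upl, lol, aco, n=rs.n)
        # bounds survive to the writer's 2-decimal precision
        orig = sorted((r.atom_kind, r.i, r.j) for r in rs.distances)
        new = sorted((r.atom_kind, r.i, r.j) for r in back.distances)
        assert orig == new
        assert len(back.dihedrals) == len(rs.dihedrals)


class TestOracleConsistency:
    def test_zero_sd_restraints_bracket_true_geometry(self, mixed16):
        """Restraints derived from exact statistics contain the true values."""
        model = mixed16.models[0]
        n = len(model)
        dca = pairwise_distances(model, "CA")
        trig = np.full((n, 4), np.nan)
        for i, (phi, psi) in enumerate(backbone_dihedrals(model)):
            if phi is not None:
                trig[i, 0:2] = math.cos(math.radians(phi)), math.sin(math.radians(phi))
            if psi is not None:
                trig[i, 2:4] = math.cos(math.radians(psi)), math.sin(math.radians(psi))
        stats = PredictionStats(
            dca_mean=dca, dca_sd=np.full((n, n), 0.3),
            dcb_mean=pairwise_distances(model, "CB"), dcb_sd=np.full((n, n), 0.3),
            trig_mean=trig, trig_sd=np.zeros((n, 4)),
        )
        rs = rst.derive_restraints(stats)
        for r in rs.distances:
            true = (dca if r.atom_kind == "CA" else stats.dcb_mean)[r.i - 1, r.j - 1]
            assert r.lower <= true <= r.upper
        assert restraint_energy(model, rs).distance_violation == 0.0
        assert restraint_energy(model, rs).dihedral_violation == 0.0
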