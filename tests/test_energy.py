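"""Coulomb/LJ pair energies, group decomposition, charge bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surfbind as sb
from surfbind.energy import COULOMB_CONSTANT
from conftest import frame, make_atom
from oracles import coulomb_formula, lj_formula


class TestCoulombPair:
    def test_defining_constant(self):
        assert sb.coulomb_pair(1.0, 1.0, 1.0, "plain_cutoff", r_c=1.2) == (
            pytest.approx(138.935458)
        )

    def test_reaction_field_zero_vanishes_at_cutoff(self):
        assert sb.coulomb_pair(0.7, -0.4, 1.0, "reaction_field_zero",
                               r_c=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_reaction_field_zero_continuous_at_cutoff(self):
        below = sb.coulomb_pair(1.0, 1.0, 1.0 - 1e-9, "reaction_field_zero",
                                r_c=1.0)
        beyond = sb.coulomb_pair(1.0, 1.0, 1.0 + 1e-9, "reaction_field_zero",
                                 r_c=1.0)
        assert abs(below) < 1e-8
        assert beyond == 0.0

    @settings(deadline=None, max_examples=100)
    @given(
        qi=st.floats(-2, 2), qj=st.floats(-2, 2),
        r=st.floats(0.05, 1.5),
        scheme=st.sampled_from(["plain_cutoff", "reaction_field_zero"]),
    )
    def test_matches_hand_coded_formula(self, qi, qj, r, scheme):
        ours = sb.coulomb_pair(qi, qj, r, scheme, r_c=1.0)
        ref = coulomb_formula(qi, qj, r, scheme, 1.0)
        assert ours == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sb.coulomb_pair(1.0, 1.0, 0.0)


class TestLJPair:
    def test_unit_coefficients_cancel_at_unit_distance(self):
        assert sb.lj_pair(1.0, 1.0, 1.0, 1.0, 1.0, r_c=None) == pytest.approx(0.0)

    def test_minimum_position(self):
        c6, c12 = 2.5e-3, 2.5e-6
        r_min = (2.0 * c12 / c6) ** (1.0 / 6.0)
        r = np.linspace(0.8 * r_min, 1.2 * r_min, 2001)
        v = sb.lj_pair(c6, c6, c12, c12, r, r_c=None)
        assert r[np.argmin(v)] == pytest.approx(r_min, rel=1e-3)

    @settings(deadline=None, max_examples=100)
    @given(
        c6i=st.floats(1e-4, 5e-3), c6j=st.floats(1e-4, 5e-3),
        c12i=st.floats(1e-7, 5e-6), c12j=st.floats(1e-7, 5e-6),
        r=st.floats(0.2, 1.4),
    )
    def test_matches_hand_coded_formula(self, c6i, c6j, c12i, c12j, r):
        ours = sb.lj_pair(c6i, c6j, c12i, c12j, r, r_c=1.0)
        ref = lj_formula(c6i, c6j, c12i, c12j, r, 1.0)
        assert ours == pytest.approx(ref, rel=1e-12, abs=1e-15)


class TestGroupInteractionEnergy:
    def test_two_atom_system_equals_single_pair(self):
        atoms = [
            make_atom(1, charge=0.5, c6=1e-3, c12=1e-6, group="head",
                      resname="LIG", chain="B"),
            make_atom(2, charge=-0.3, c6=2e-3, c12=2e-6, group="protein"),
        ]
        system = sb.MolecularSystem(atoms=atoms)
        f = frame([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]])  # 0.6 nm
        cfg = sb.AnalysisConfig()
        ge = sb.group_interaction_energy(f, system, "head", "protein", cfg)
        assert ge.e_coulomb == pytest.approx(
            sb.coulomb_pair(0.5, -0.3, 0.6, cfg.electrostatics_scheme,
                            cfg.coulomb_cutoff)
        )
        assert ge.e_lj == pytest.approx(
            sb.lj_pair(1e-3, 2e-3, 1e-6, 2e-6, 0.6, cfg.coulomb_cutoff)
        )

    def test_additivity_over_ligand_partition(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=21))
        cfg = sb.AnalysisConfig()
        whole = sb.group_interaction_energy(f, system, "ligand",
                                            "surrounding", cfg)
        parts = [
            sb.group_interaction_energy(f, system, g, "surrounding", cfg)
            for g in ("head", "tail")
        ]
        assert whole.e_coulomb == pytest.approx(
            sum(p.e_coulomb for p in parts), rel=1e-10, abs=1e-10
        )
        assert whole.e_lj == pytest.approx(
            sum(p.e_lj for p in parts), rel=1e-10, abs=1e-10
        )

    def test_random_partition_additivity(self):
        """Energy is additive over any disjoint split of the ligand."""
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=22))
        cfg = sb.AnalysisConfig()
        lig = np.flatnonzero(system.ligand_mask)
        sur = np.flatnonzero(system.group_mask("protein", "water"))
        whole = sb.group_interaction_energy(f, system, lig, sur, cfg)
        rng = np.random.default_rng(22)
        for _ in range(20):
            pick = rng.random(lig.size) < 0.5
            a, b = lig[pick], lig[~pick]
            if a.size == 0 or b.size == 0:
                continue
            ea = sb.group_interaction_energy(f, system, a, sur, cfg)
            eb = sb.group_interaction_energy(f, system, b, sur, cfg)
            assert ea.total + eb.total == pytest.approx(
                whole.total, rel=1e-10, abs=1e-10
            )

    def test_symmetry(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=23))
        cfg = sb.AnalysisConfig()
        ab = sb.group_interaction_energy(f, system, "ligand", "surrounding", cfg)
        ba = sb.group_interaction_energy(f, system, "surrounding", "ligand", cfg)
        assert ab.e_coulomb == pytest.approx(ba.e_coulomb, rel=1e-12)
        assert ab.e_lj == pytest.approx(ba.e_lj, rel=1e-12)

    def test_overlapping_groups_rejected(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=24))
        lig = np.flatnonzero(system.ligand_mask)
        with pytest.raises(ValueError, match="overlap"):
            sb.group_interaction_energy(f, system, lig, lig)


class TestEnergyTimeseries:
    def test_static_trajectory(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=30))
        traj = sb.gen_jitter_trajectory(system, f, sigma=0.0, n_frames=10,
                                        seed=0)
        series = sb.energy_timeseries(traj)
        single = sb.group_interaction_energy(f, system, "ligand",
                                             "surrounding",
                                             sb.AnalysisConfig())
        assert series.mean_coulomb == pytest.approx(single.e_coulomb)
        assert series.sem_coulomb == pytest.approx(0.0, abs=1e-12)

    def test_window_restricts_frames(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=31))
        traj = sb.gen_jitter_trajectory(system, f, sigma=0.05, n_frames=100,
                                        seed=1, stride=1.0)
        cfg = sb.AnalysisConfig(analysis_window=(40.0, 100.0))
        mask = traj.window_mask(cfg.analysis_window)
        assert mask.sum() == 60
        series = sb.energy_timeseries(traj, config=cfg)
        np.testing.assert_allclose(
            series.mean_coulomb, series.e_coulomb[mask].mean()
        )

    def test_jittered_mean_near_reference_value(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=32))
        traj = sb.gen_jitter_trajectory(system, f, sigma=0.02, n_frames=200,
                                        seed=2)
        series = sb.energy_timeseries(traj)
        ref = sb.group_interaction_energy(
            f, system, "ligand", "surrounding", sb.AnalysisConfig()
        )
        assert abs(series.mean_lj - ref.e_lj) <= 2.0 * max(series.sem_lj, 1e-9) + 0.3

    def test_empty_window_rejected(self):
        system, f = sb.gen_toy_complex(sb.ToyComplexSpec(seed=33))
        traj = sb.gen_jitter_trajectory(system, f, sigma=0.0, n_frames=5,
                                        seed=0)
        cfg = sb.AnalysisConfig(analysis_window=(1e6, 2e6))
        with pytest.raises(ValueError, match="window"):
            sb.energy_timeseries(traj, config=cfg)


def ligand_system(head_qs, alpha_qs, tail_qs):
    atoms = []
    serial = 1
    for qs, grp in ((head_qs, "head"), (alpha_qs, "alpha"), (tail_qs, "tail")):
        for q in qs:
            atoms.append(
                make_atom(serial, name=f"L{serial}", resname="LIG", chain="B",
                          charge=q, group=grp)
            )
            serial += 1
    return sb.MolecularSystem(atoms=atoms)


class TestChargeBookkeeping:
    def test_bound_sds_grouping(self):
        """Bound anionic surfactant: head -1.242, alpha +0.418, bare tail
        -0.019 -> alpha+tail +0.399 and net -0.843."""
        system = ligand_system([-0.6, -0.642], [0.418], [-0.019])
        gc = sb.group_charge_sums(system)
        assert gc.head == pytest.approx(-1.242)
        assert gc.tail_with_alpha == pytest.approx(0.399)
        assert gc.net == pytest.approx(-0.843)

    def test_free_sds_net_minus_one(self):
        system = ligand_system([-1.258], [0.300], [-0.042])
        gc = sb.group_charge_sums(system)
        assert gc.net == pytest.approx(-1.0)

    def test_alpha_in_head_convention_preserves_net(self):
        system = ligand_system([-1.242], [0.418], [-0.019])
        default = sb.group_charge_sums(system)
        huibers = sb.group_charge_sums(system, alpha_in_head=True)
        assert huibers.head == pytest.approx(default.head + default.alpha)
        assert huibers.net == pytest.approx(default.net)

    def test_zero_charges(self):
        system = ligand_system([0.0], [0.0], [0.0])
        gc = sb.group_charge_sums(system)
        assert (gc.head, gc.alpha, gc.tail_with_alpha, gc.net) == (0, 0, 0, 0)

    def test_ungrouped_ligand_atom_rejected(self):
        system = ligand_system([-1.0], [], [0.2])
        atoms = list(system.atoms) + [
            make_atom(99, name="L99", resname="LIG", chain="B", group="other")
        ]
        with pytest.raises(ValueError, match="ungrouped"):
            sb.group_charge_sums(sb.MolecularSystem(atoms=atoms))

    @pytest.mark.parametrize(
        "free_net,bound_net,magnitude",
        [(-1.0, -0.843, 0.157), (0.0, 0.078, 0.078), (-0.5, -0.5, 0.0)],
    )
    def test_charge_transfer(self, free_net, bound_net, magnitude):
        free = sb.GroupCharges(free_net, 0.0, 0.0, free_net)
        bound = sb.GroupCharges(bound_net, 0.0, 0.0, bound_net)
        assert sb.charge_transfer(free, bound).magnitude == pytest.approx(
            magnitude
        )


class TestChargeEnergyScaling:
    def test_zwitterionic_head_feature(self):
        """|q| feature of an oppositely charged double head is the mean of
        the absolute sub-head charges."""
        assert sb.head_charge_magnitude(-0.971, 0.649) == pytest.approx(0.810)
        assert sb.head_charge_magnitude(-1.242) == pytest.approx(1.242)

    def test_collinear_points_perfect_correlation(self):
        pts = [(0.2, -10.0), (0.5, -25.0), (1.0, -50.0)]
        fit = sb.charge_energy_scaling(pts)
        assert abs(fit.r_value) == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-50.0)

    def test_noisy_regression_recovers_slope(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0.1, 1.3, size=30)
        y = -80.0 * x + 5.0 + rng.normal(0, 2.0, size=30)
        fit = sb.charge_energy_scaling(np.column_stack([x, y]))
        assert fit.slope == pytest.approx(-80.0, abs=4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            sb.charge_energy_scaling([(0.1, 1.0), (0.2, 2.0)])

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sb.charge_energy_scaling([(0.5, 1.0), (0.5, 2.0), (0.5, 3.0)])
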