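"""Contact detection, hydrogen bonds, bifurcation bookkeeping, bridges."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surfbind as sb
from conftest import frame, make_atom


def two_atom_system():
    atoms = [
        make_atom(1, "CD1", "C", "LEU", 7, "A", group="protein"),
        make_atom(2, "C1", "C", "LIG", 1, "B", group="tail"),
    ]
    return sb.MolecularSystem(atoms=atoms)


class TestContacts:
    def test_single_pair_within_cutoff(self):
        system = two_atom_system()
        f = frame([[0.0, 0.0, 0.0], [3.4, 0.0, 0.0]])
        contacts = sb.binding_site_residues(f, system, cutoff=3.5)
        assert len(contacts) == 1
        c = contacts[0]
        assert (c.residue_name, c.residue_index) == ("LEU", 7)
        assert c.min_distance == pytest.approx(3.4)

    def test_beyond_cutoff_empty(self):
        system = two_atom_system()
        f = frame([[0.0, 0.0, 0.0], [3.6, 0.0, 0.0]])
        assert sb.binding_site_residues(f, system, cutoff=3.5) == []

    def test_hydrogens_excluded(self):
        atoms = [
            make_atom(1, "HD1", "H", "LEU", 7, "A", group="protein"),
            make_atom(2, "C1", "C", "LIG", 1, "B", group="tail"),
        ]
        system = sb.MolecularSystem(atoms=atoms)
        f = frame([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert sb.binding_site_residues(f, system) == []

    def test_no_ligand_is_error(self):
        atoms = [make_atom(1, group="protein")]
        system = sb.MolecularSystem(atoms=atoms)
        with pytest.raises(ValueError, match="ligand"):
            sb.binding_site_residues(frame([[0, 0, 0]]), system)

    def test_minimum_image_wraps(self):
        system = two_atom_system()
        f = frame([[0.5, 0.0, 0.0], [29.5, 0.0, 0.0]],
                  box=np.array([30.0, 30.0, 30.0]))
        contacts = sb.binding_site_residues(f, system, cutoff=3.5)
        assert contacts and contacts[0].min_distance == pytest.approx(1.0)


class TestHBondDetection:
    def test_linear_geometry_is_regular_bond(self, donor_acceptor_system):
        f = frame([[0, 0, 0], [0.96, 0, 0], [2.9, 0, 0], [9, 9, 9]])
        bonds = sb.detect_hbonds(f, donor_acceptor_system)
        assert len(bonds) == 1
        b = bonds[0]
        assert (b.donor, b.hydrogen, b.acceptor) == (0, 1, 2)
        assert b.kind == "regular"
        assert b.distance == pytest.approx(2.9)
        assert b.angle == pytest.approx(0.0, abs=1e-9)

    def test_bent_geometry_rejected(self, donor_acceptor_system):
        # acceptor at 45 degrees off the O-H axis, still 2.9 A away
        a = 2.9 / np.sqrt(2.0)
        f = frame([[0, 0, 0], [0.96, 0, 0], [a, a, 0], [9, 9, 9]])
        assert sb.detect_hbonds(f, donor_acceptor_system) == []

    def test_shared_hydrogen_both_bifurcated(self, donor_acceptor_system):
        f = frame([[0, 0, 0], [0.96, 0, 0], [2.9, 0.4, 0], [2.9, -0.4, 0]])
        bonds = sb.detect_hbonds(f, donor_acceptor_system)
        assert len(bonds) == 2
        assert all(b.kind == "bifurcated" for b in bonds)

    def test_distance_only_mode_skips_angle(self, donor_acceptor_system):
        a = 2.9 / np.sqrt(2.0)
        f = frame([[0, 0, 0], [0.96, 0, 0], [a, a, 0], [9, 9, 9]])
        cfg = sb.AnalysisConfig(distance_only=True)
        bonds = sb.detect_hbonds(f, donor_acceptor_system, cfg)
        assert len(bonds) == 1
        assert bonds[0].angle is None

    def test_no_donors_is_error(self):
        system = sb.MolecularSystem(atoms=[make_atom(1, element="O")],
                                    acceptors=[0])
        with pytest.raises(ValueError, match="donor"):
            sb.detect_hbonds(frame([[0, 0, 0]]), system)


class TestHBondTotals:
    @pytest.mark.parametrize(
        "bifurcated,regular,total", [(3, 1, 7), (1, 3, 5), (2, 1, 5), (0, 0, 0)]
    )
    def test_totals(self, bifurcated, regular, total):
        assert sb.hbond_totals(bifurcated, regular) == total

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sb.hbond_totals(-1, 0)

    @settings(deadline=None, max_examples=100)
    @given(b=st.integers(0, 50), r=st.integers(0, 50))
    def test_counting_identity(self, b, r):
        total = sb.hbond_totals(b, r)
        assert total >= max(2 * b, r)
        assert (total - r) % 2 == 0
        assert total == 2 * b + r


class TestHBondSeries:
    def test_static_bond_all_on(self, donor_acceptor_system):
        f0 = frame([[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0], [9, 9, 9]])
        frames = [
            sb.Frame(time=2.0 * i, coordinates=f0.coordinates.copy())
            for i in range(10)
        ]
        traj = sb.Trajectory(system=donor_acceptor_system, frames=frames)
        series = sb.hbond_series(traj)
        assert series.matrix.shape == (1, 10)
        assert series.matrix.all()
        assert series.mean_length == pytest.approx(2.8)

    def test_telegraph_driven_geometry_matches_states(self):
        """Displacing the acceptor beyond the cutoff when the telegraph is
        off makes the detected series reproduce the telegraph exactly."""
        spec = sb.TelegraphSpec(k_off=0.05, k_on=0.05, dt=1.0,
                                n_steps=2000, seed=8)
        states = sb.gen_telegraph_series(spec)
        atoms = [
            make_atom(1, "OD", "O", "LIG", 1, "B", group="head"),
            make_atom(2, "HD", "H", "LIG", 1, "B", group="head"),
            make_atom(3, "OA", "O", "SER", 1, "A", group="protein"),
        ]
        system = sb.MolecularSystem(atoms=atoms, donors=[(0, 1)], acceptors=[2])
        frames = [
            sb.Frame(
                time=float(i),
                coordinates=np.array(
                    [[0, 0, 0], [0.96, 0, 0],
                     [2.9 if on else 6.0, 0.0, 0.0]]
                ),
            )
            for i, on in enumerate(states)
        ]
        traj = sb.Trajectory(system=system, frames=frames)
        series = sb.hbond_series(traj)
        np.testing.assert_array_equal(series.matrix[0], states)
        assert abs(series.occupancy - 0.5) < 0.05

    def test_length_distribution_mean_from_raw_samples(self,
                                                       donor_acceptor_system):
        f0 = frame([[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0], [9, 9, 9]])
        traj = sb.Trajectory(
            system=donor_acceptor_system,
            frames=[sb.Frame(time=float(i), coordinates=f0.coordinates.copy())
                    for i in range(3)],
        )
        series = sb.hbond_series(traj)
        edges, counts = series.length_distribution(bin_width=0.1)
        assert counts.sum() == 3
        assert series.mean_length == pytest.approx(2.8)


class TestWaterBridges:
    def _bridge_system(self):
        atoms = [
            make_atom(1, "O", "O", "SER", 3, "A", group="protein"),
            make_atom(2, "O1", "O", "LIG", 1, "B", group="head"),
            make_atom(3, "OW", "O", "SOL", 1, "W", group="water"),
            make_atom(4, "HW1", "H", "SOL", 1, "W", group="water"),
            make_atom(5, "HW2", "H", "SOL", 1, "W", group="water"),
        ]
        return sb.MolecularSystem(
            atoms=atoms, donors=[(2, 3), (2, 4)], acceptors=[0, 1, 2]
        )

    def test_bridging_water_found(self):
        # water donates one H toward the protein O and one toward ligand O
        system = self._bridge_system()
        f = frame(
            [
                [2.8, 0.0, 0.0],     # protein O
                [-2.8, 0.0, 0.0],    # ligand O
                [0.0, 0.0, 0.0],     # OW
                [0.96, 0.0, 0.0],    # HW1 -> protein
                [-0.96, 0.0, 0.0],   # HW2 -> ligand
            ]
        )
        bridges = sb.water_bridges(f, system)
        assert bridges == [
            sb.WaterBridge(protein_atom=0, water_residue=1, ligand_atom=1)
        ]

    def test_water_far_from_ligand_no_bridge(self):
        system = self._bridge_system()
        f = frame(
            [[2.8, 0, 0], [-8.0, 0, 0], [0, 0, 0], [0.96, 0, 0], [-0.96, 0, 0]]
        )
        assert sb.water_bridges(f, system) == []


class TestWatersNearGroup:
    def _system_with_waters(self, water_dist):
        atoms = [make_atom(1, "O1", "O", "LIG", 1, "B", group="head")]
        coords = [[0.0, 0.0, 0.0]]
        serial = 2
        for w in range(4):
            for j, (n, e) in enumerate(
                [("OW", "O"), ("HW1", "H"), ("HW2", "H")]
            ):
                atoms.append(
                    make_atom(serial, n, e, "SOL", w + 1, "W", group="water")
                )
                angle = 2 * np.pi * w / 4
                base = [water_dist * np.cos(angle), water_dist * np.sin(angle), 0]
                coords.append([base[0] + 0.3 * j, base[1], base[2]])
                serial += 1
        system = sb.MolecularSystem(atoms=atoms)
        traj = sb.Trajectory(
            system=system,
            frames=[
                sb.Frame(time=float(t), coordinates=np.array(coords))
                for t in range(5)
            ],
        )
        return traj

    def test_four_close_waters_average_four(self):
        traj = self._system_with_waters(3.0)
        counts, avg = sb.waters_near_group(traj, "head", cutoff_nm=0.35)
        assert avg == pytest.approx(4.0)
        assert counts.tolist() == [4] * 5

    def test_distant_waters_count_zero(self):
        traj = self._system_with_waters(6.0)
        counts, avg = sb.waters_near_group(traj, "head", cutoff_nm=0.35)
        assert avg == 0.0
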