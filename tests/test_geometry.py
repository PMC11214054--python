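import numpy as np
import pytest

from mdgate.core import MDGateError, SelectionSpec, Structure, Trajectory, domain, select
from mdgate import geometry as geo
from mdgate import io as mio
from mdgate.synthetic import (DimerToyConfig, HelixConfig, TelegraphConfig,
                              gen_dimer_toy, gen_kinked_helix,
                              gen_salt_bridge_series)
from conftest import apply_rigid, random_rigid


def tip_structure(dist=22.0):
    return Structure(names=["CA", "CA"], elements=["C", "C"], resids=[362, 201],
                     resnames=["ASP", "GLU"], chains=["A", "A"],
                     positions=[[0.0, 0, 0], [dist, 0, 0]])


class TestCoreGateDistance:
    def test_constructed_distance(self):
        s = tip_structure(22.0)
        traj = Trajectory(topology=s, coordinates=np.tile(s.positions, (3, 1, 1)))
        ds = geo.core_gate_distance(traj, "A")
        assert np.allclose(ds.values, 22.0)
        assert "362" in ds.label and "201" in ds.label

    def test_initial_model_fragment(self, transporter_fragment):
        top = mio.read_structure(transporter_fragment)
        traj = Trajectory(topology=top, coordinates=top.positions[None])
        assert geo.core_gate_distance(traj, "A").values[0] == pytest.approx(22.0, abs=1.0)

    def test_missing_residue_errors(self, simple_structure):
        traj = Trajectory(topology=simple_structure,
                          coordinates=simple_structure.positions[None])
        with pytest.raises(MDGateError, match="362"):
            geo.core_gate_distance(traj, "A")

    def test_invariant_under_rigid_motion(self, rng):
        s = tip_structure(17.3)
        coords = np.tile(s.positions, (5, 1, 1))
        for f in range(5):
            coords[f] = apply_rigid(coords[f], *random_rigid(rng))
        traj = Trajectory(topology=s, coordinates=coords)
        assert np.allclose(geo.core_gate_distance(traj, "A").values, 17.3, atol=1e-8)


class TestDimerFrame:
    def test_axes_for_x_separated_coms(self):
        pos = np.array([[5.0, 0, 0], [-5.0, 0, 0]])
        frame = geo.dimer_frame(pos, [0], [1])
        assert np.allclose(frame.x_axis, [1, 0, 0])
        assert np.allclose(frame.y_axis, [0, 1, 0])
        assert np.allclose(frame.z_axis, [0, 0, 1])
        assert np.allclose(frame.origin, [0, 0, 0])

    def test_z_component_projected_out(self):
        pos = np.array([[5.0, 3.0, 7.0], [-5.0, 3.0, 7.0]])
        frame = geo.dimer_frame(pos, [0], [1])
        assert np.allclose(frame.x_axis, [1, 0, 0])
        assert np.allclose(frame.y_axis, [0, 1, 0])

    def test_degenerate_orientation_errors(self):
        pos = np.array([[0.0, 0, 5.0], [0.0, 0, -5.0]])
        with pytest.raises(MDGateError, match="degenerate dimer orientation"):
            geo.dimer_frame(pos, [0], [1])

    def test_orthonormal_right_handed_on_random_configs(self, rng):
        for _ in range(200):
            pos = rng.normal(0, 20, (6, 3))
            try:
                frame = geo.dimer_frame(pos, [0, 1, 2], [3, 4, 5])
            except MDGateError:
                continue
            assert np.allclose(np.cross(frame.x_axis, frame.y_axis), frame.z_axis,
                               atol=1e-8)


class TestStasComTrace:
    def domains(self, top):
        return {(c, d): select(top, SelectionSpec(domain=domain(d, c)))
                for c in "AB" for d in ("STAS", "TM")}

    def test_mirror_symmetric_dimer(self):
        traj, _ = gen_dimer_toy(DimerToyConfig(seed=1))
        d = self.domains(traj.topology)
        trace = geo.stas_com_trace(traj, d[("A", "STAS")], d[("B", "STAS")],
                                   d[("A", "TM")], d[("B", "TM")], unit_masses=True)
        assert np.allclose(trace.y_A, -trace.y_B, atol=1e-9)

    def test_constructed_y_displacement(self):
        cfg = DimerToyConfig(seed=2, stas_center_a=(6.0, 4.0, -15.0),
                             stas_center_b=(-6.0, -5.0, -15.0), n_frames=3)
        traj, _ = gen_dimer_toy(cfg)
        d = self.domains(traj.topology)
        trace = geo.stas_com_trace(traj, d[("A", "STAS")], d[("B", "STAS")],
                                   d[("A", "TM")], d[("B", "TM")], unit_masses=True)
        assert np.allclose(trace.y_A, 4.0, atol=1e-9)

    def test_invariant_under_rigid_rotation_of_frames(self, rng):
        traj, _ = gen_dimer_toy(DimerToyConfig(seed=3, drift_per_frame=(0.1, 0.3, 0.0),
                                               n_frames=5))
        d = self.domains(traj.topology)
        args = (d[("A", "STAS")], d[("B", "STAS")], d[("A", "TM")], d[("B", "TM")])
        base = geo.stas_com_trace(traj, *args, unit_masses=True)
        # rotations about the membrane normal keep the frame self-consistent
        moved = traj.coordinates.copy()
        for f in range(len(moved)):
            ang = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                            [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
            moved[f] = moved[f] @ rot.T + rng.normal(0, 5, 3)
        traj2 = Trajectory(topology=traj.topology, coordinates=moved)
        rotated = geo.stas_com_trace(traj2, *args, unit_masses=True)
        assert np.allclose(rotated.y_A, base.y_A, atol=1e-8)
        assert np.allclose(rotated.y_B, base.y_B, atol=1e-8)

    def test_drift_recovered(self):
        cfg = DimerToyConfig(seed=4, drift_per_frame=(0.0, 0.5, 0.0), n_frames=9)
        traj, truth = gen_dimer_toy(cfg)
        d = self.domains(traj.topology)
        trace = geo.stas_com_trace(traj, d[("A", "STAS")], d[("B", "STAS")],
                                   d[("A", "TM")], d[("B", "TM")], unit_masses=True)
        assert trace.y_A.iloc[-1] - trace.y_A.iloc[0] == pytest.approx(4.0, abs=1e-9)


class TestDihedrals:
    def test_analytic_35_degree_twist(self):
        p0, p1, p2 = np.array([1.0, 0, 0]), np.zeros(3), np.array([0.0, 0, 1.0])
        results = []
        for sign in (+1, -1):
            a = np.radians(sign * 35.0)
            # rotate the p0 direction about the central bond by the target angle
            p3 = p2 + np.array([np.cos(a), -np.sin(a), 0.0])
            results.append(geo.dihedral(p0, p1, p2, p3)[0])
        assert results[0] == pytest.approx(35.0, abs=1e-6) or \
            results[1] == pytest.approx(35.0, abs=1e-6)

    def test_matches_reference_implementation(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals
        p = rng.normal(size=(50, 4, 3))
        ours = geo.dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        ref = np.degrees(calc_dihedrals(p[:, 0], p[:, 1], p[:, 2], p[:, 3]))
        assert np.allclose(ours, ref, atol=1e-4)

    def test_collinear_atoms_rejected(self):
        line = [np.array([float(i), 0, 0]) for i in range(4)]
        with pytest.raises(MDGateError, match="collinear"):
            geo.dihedral(*line)

    def test_ideal_helix_phi_psi(self):
        traj, truth = gen_kinked_helix(HelixConfig(n_residues=10))
        ds = geo.backbone_dihedrals(traj, [("B", 442), ("B", 443)], "both")
        for s in ds:
            assert s.phi[0] == pytest.approx(truth["phi"], abs=1e-6)
            assert s.psi[0] == pytest.approx(truth["psi"], abs=1e-6)

    def test_terminal_residue_errors_by_name(self):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=5, start_resid=100))
        with pytest.raises(MDGateError, match="residue 100"):
            geo.backbone_dihedrals(traj, [("B", 100)], "phi")

    def test_range_convention(self, rng):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=8))
        ds = geo.backbone_dihedrals(traj, [("B", 441)], "both")[0]
        for v in (ds.phi, ds.psi):
            assert np.all((v > -180.0) & (v <= 180.0))


class TestKinkAngle:
    def test_straight_helix_below_3_degrees(self):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=15))
        assert geo.kink_angle(traj, "B", 445).values[0] < 3.0

    @pytest.mark.parametrize("bend", [10.0, 30.0, 60.0])
    def test_constructed_bend_recovered(self, bend):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=15, kink_residue=445,
                                               kink_angle=bend))
        assert geo.kink_angle(traj, "B", 445).values[0] == pytest.approx(bend, abs=3.0)

    def test_jittered_bend_recovered_in_the_mean(self):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=15, kink_residue=445,
                                               kink_angle=30.0, jitter_sigma=0.2,
                                               n_frames=50, seed=8))
        assert geo.kink_angle(traj, "B", 445).values.mean() == pytest.approx(30.0, abs=3.0)

    def test_invariant_under_rotation(self, rng):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=15, kink_residue=445,
                                               kink_angle=30.0))
        base = geo.kink_angle(traj, "B", 445).values[0]
        rot, trans = random_rigid(rng)
        traj2 = Trajectory(topology=traj.topology,
                           coordinates=apply_rigid(traj.coordinates[0], rot, trans)[None])
        assert geo.kink_angle(traj2, "B", 445).values[0] == pytest.approx(base, abs=1e-8)

    def test_insufficient_span_errors(self):
        traj, _ = gen_kinked_helix(HelixConfig(n_residues=8))
        with pytest.raises(MDGateError, match="need >= 4"):
            geo.kink_angle(traj, "B", 439)


class TestSaltBridges:
    def two_atom_traj(self, dist):
        top = Structure(names=["NZ", "OD1"], elements=["N", "O"],
                        resids=[458, 709], resnames=["LYS", "ASP"],
                        chains=["B", "A"],
                        positions=[[0.0, 0, 0], [dist, 0, 0]])
        return Trajectory(topology=top, coordinates=np.tile(top.positions, (4, 1, 1)))

    def test_fixed_pair_distance(self):
        ds = geo.salt_bridge_distance(self.two_atom_traj(3.0), [0], [1])
        assert np.allclose(ds.values, 3.0)

    def test_telegraph_duty_cycle_recovered(self):
        cfg = TelegraphConfig(duty_cycle=0.4, n_frames=5000, seed=6)
        traj, truth = gen_salt_bridge_series(cfg)
        ds = geo.salt_bridge_distance(traj, [0], [1])
        frac = np.mean(ds.values < 4.0)
        assert frac == pytest.approx(truth["duty_cycle"], abs=1e-12)
        half = 2.576 * np.sqrt(0.4 * 0.6 / cfg.n_frames)
        assert abs(frac - 0.4) < half

    def test_group_selection_is_pairwise_minimum(self, rng):
        top = Structure(names=["NZ", "OD1", "OD2"], elements=["N", "O", "O"],
                        resids=[458, 709, 709], resnames=["LYS", "ASP", "ASP"],
                        chains=["B", "A", "A"],
                        positions=[[0.0, 0, 0], [5.0, 0, 0], [3.5, 0, 0]])
        traj = Trajectory(topology=top, coordinates=np.tile(top.positions, (2, 1, 1)))
        group = geo.salt_bridge_distance(traj, [0], [1, 2])
        d1 = geo.salt_bridge_distance(traj, [0], [1])
        d2 = geo.salt_bridge_distance(traj, [0], [2])
        assert np.allclose(group.values, np.minimum(d1.values, d2.values))

    def test_detect_single_contact(self):
        contacts = geo.detect_salt_bridges(self.two_atom_traj(3.2).topology)
        assert len(contacts) == 1
        c = contacts[0]
        assert (c.donor_atom, c.acceptor_atom) == ("NZ", "OD1")
        assert c.distance == pytest.approx(3.2)

    def test_boundary_distance_excluded(self):
        assert geo.detect_salt_bridges(self.two_atom_traj(4.0).topology) == []

    def test_interface_pairs_detected(self):
        """Cross-chain core–STAS contacts: D362(A)–K685(B) and D364(A)–K560(B)
        placed at 3 Å are found, and nothing else."""
        top = Structure(
            names=["OD1", "NZ", "OD2", "NZ", "NZ"],
            elements=["O", "N", "O", "N", "N"],
            resids=[362, 685, 364, 560, 458],
            resnames=["ASP", "LYS", "ASP", "LYS", "LYS"],
            chains=["A", "B", "A", "B", "B"],
            positions=[[0.0, 0, 0], [3.0, 0, 0],
                       [20.0, 0, 0], [20.0, 3.0, 0],
                       [50.0, 50.0, 50.0]])
        contacts = geo.detect_salt_bridges(top)
        pairs = {((c.donor_chain, c.donor_resid), (c.acceptor_chain, c.acceptor_resid))
                 for c in contacts}
        assert pairs == {(("B", 685), ("A", 362)), (("B", 560), ("A", 364))}


class TestRmsdProfile:
    def test_identical_frames_zero(self, simple_structure):
        traj = Trajectory(topology=simple_structure,
                          coordinates=np.tile(simple_structure.positions, (4, 1, 1)))
        assert np.allclose(geo.rmsd_profile(traj, [0, 1, 2]), 0.0, atol=1e-10)

    def test_rigid_motion_removed(self, rng):
        base = rng.normal(size=(10, 3))
        top = Structure(names=["CA"] * 10, elements=["C"] * 10,
                        resids=np.arange(1, 11), resnames=["GLY"] * 10,
                        chains=["A"] * 10, positions=base)
        coords = np.stack([base, apply_rigid(base, *random_rigid(rng))])
        traj = Trajectory(topology=top, coordinates=coords)
        assert geo.rmsd_profile(traj, np.arange(10))[1] == pytest.approx(0.0, abs=1e-8)

    def test_noise_level_recovered(self, rng):
        """Per-atom Gaussian noise σ gives RMSD ≈ σ√3 at 100 atoms."""
        sigma = 0.5
        base = rng.normal(0, 10, size=(100, 3))
        noisy = base + rng.normal(0, sigma, base.shape)
        top = Structure(names=["CA"] * 100, elements=["C"] * 100,
                        resids=np.arange(1, 101), resnames=["GLY"] * 100,
                        chains=["A"] * 100, positions=base)
        traj = Trajectory(topology=top, coordinates=np.stack([base, noisy]))
        rmsd = geo.rmsd_profile(traj, np.arange(100))[1]
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.10)
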