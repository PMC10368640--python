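import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import brute_force_min_rmsd
from phenodyn.synthetic_traj import (
    ContactSwitchSpec,
    FluctuationSpec,
    expected_rmsf,
    generate_contact_trajectory,
    generate_harmonic_trajectory,
)
from phenodyn.traj_io import select_atoms
from phenodyn.traj_stats import (
    RMSFProfile,
    call_fluctuation_clusters,
    detect_equilibration,
    dissociation_frequency,
    kabsch_superpose,
    pair_distance_series,
    rmsd_series,
    rmsf_profile,
)


class TestKabsch:
    def test_identity_on_equal_sets(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-12
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        theta = np.pi / 2
        rot90 = np.array([[np.cos(theta), -np.sin(theta), 0],
                          [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = pts @ rot90.T + np.array([3.0, -2.0, 7.0])
        _, _, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-10

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            a = rng.normal(size=(10, 3)) * 3
            b = rng.normal(size=(10, 3)) * 3
            _, _, rmsd_nm = kabsch_superpose(a, b)
            oracle_ang = brute_force_min_rmsd(a, b, seed=trial)
            assert rmsd_nm * 10 == pytest.approx(oracle_ang, abs=1e-6)

    def test_rotation_is_proper_even_for_reflected_input(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        mirrored = pts * np.array([1, 1, -1])
        rot, _, _ = kabsch_superpose(mirrored, pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_minimized_never_exceeds_unaligned(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            raw = 0.1 * np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert rmsd <= raw + 1e-12

    def test_degenerate_collinear_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSDSeries:
    def test_constant_trajectory_is_zero(self, tiny_structure):
        from phenodyn.traj_io import Trajectory

        coords = tiny_structure.coordinates()
        traj = Trajectory(topology=tiny_structure, frames=np.stack([coords] * 4))
        sel = select_atoms(traj, "name CA")
        series = rmsd_series(traj, sel)
        assert np.allclose(series.values, 0.0)

    def test_harmonic_steady_state_matches_closed_form(self, small_topology):
        s = 0.08
        spec = FluctuationSpec(reference=small_topology, sigma_per_residue=s,
                               n_frames=2000, seed=9)
        traj = generate_harmonic_trajectory(spec)
        sel = select_atoms(traj, "name N,CA,C,O")
        series = rmsd_series(traj, sel)
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)  # reference frame
        assert np.mean(series.values[1:]) == pytest.approx(s * np.sqrt(3), rel=0.03)


class TestEquilibration:
    def test_flat_series_equilibrates_immediately(self):
        assert detect_equilibration(np.full(200, 0.3), window=10) == 0

    def test_step_detected_within_one_window(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t_true = int(rng.integers(50, 150))
            series = np.concatenate([np.full(t_true, 0.1), np.full(300 - t_true, 0.5)])
            t_eq = detect_equilibration(series, window=10, tol=0.02)
            assert t_true - 1 <= t_eq <= t_true + 10

    def test_monotone_ramp_falls_back_to_one_fifth(self, caplog):
        series = np.linspace(0, 5.0, 300)  # slope ≫ tol/window
        t_eq = detect_equilibration(series, window=10, tol=0.02)
        assert t_eq == 60


class TestRMSF:
    def test_constant_trajectory_zero_profile(self, tiny_structure):
        from phenodyn.traj_io import Trajectory

        coords = tiny_structure.coordinates()
        traj = Trajectory(topology=tiny_structure, frames=np.stack([coords] * 5))
        prof = rmsf_profile(traj, select_atoms(traj, "name CA"))
        assert np.allclose(prof.values, 0.0)

    def test_recovers_sigma_profile_and_peak_location(self, topology):
        sigma = {r: (0.2 if r[0] == "A" and 80 <= r[1] <= 96 else 0.05)
                 for r in topology.residues()}
        spec = FluctuationSpec(reference=topology, sigma_per_residue=sigma,
                               n_frames=3000, seed=10)
        traj = generate_harmonic_trajectory(spec)
        prof = rmsf_profile(traj, select_atoms(traj, "name CA"))
        exp = expected_rmsf(spec)
        measured = prof.as_dict()
        rel = [abs(measured[r] - exp[r]) / exp[r] for r in exp]
        assert max(rel) < 0.05

    def test_rigid_motion_removed_by_superposition(self, small_topology):
        common = dict(reference=small_topology, sigma_per_residue=0.1,
                      n_frames=400, seed=12)
        plain = generate_harmonic_trajectory(FluctuationSpec(**common))
        moved = generate_harmonic_trajectory(
            FluctuationSpec(**common, rigid_motion=True))
        sel = select_atoms(plain, "name CA")
        p1 = rmsf_profile(plain, sel)
        p2 = rmsf_profile(moved, sel)
        assert np.abs(p1.values - p2.values).max() < 1e-6

    def test_mean_structure_reference_not_larger_on_average(self, small_topology):
        spec = FluctuationSpec(reference=small_topology, sigma_per_residue=0.1,
                               n_frames=500, seed=13)
        traj = generate_harmonic_trajectory(spec)
        sel = select_atoms(traj, "name CA")
        first = rmsf_profile(traj, sel, reference_mode="first-frame")
        mean = rmsf_profile(traj, sel, reference_mode="mean-structure")
        assert mean.values.mean() <= first.values.mean()

    def test_multiple_atoms_per_residue_rejected(self, small_topology):
        spec = FluctuationSpec(reference=small_topology, sigma_per_residue=0.1,
                               n_frames=10, seed=0)
        traj = generate_harmonic_trajectory(spec)
        with pytest.raises(ValueError, match="per-residue"):
            rmsf_profile(traj, select_atoms(traj, "name N,CA"))


def _profile(values, start_res=57):
    residues = [("A", start_res + i) for i in range(len(values))]
    return RMSFProfile(residues=residues, values=np.asarray(values, float),
                       window=(0, 1))


class TestClusterCalling:
    def test_flat_low_profile_is_empty(self):
        assert len(call_fluctuation_clusters(_profile([0.05] * 40))) == 0

    def test_single_high_interval_called_exactly(self):
        vals = np.full(200, 0.05)
        vals[80 - 57 : 97 - 57] = 0.35
        cs = call_fluctuation_clusters(_profile(vals))
        assert cs.intervals("high") == [(80, 96)]

    def test_one_residue_gap_is_merged(self):
        vals = np.full(40, 0.05)
        vals[10:15] = 0.35
        vals[15] = 0.05  # single quiet residue
        vals[16:20] = 0.35
        cs = call_fluctuation_clusters(_profile(vals))
        assert cs.intervals("high") == [(67, 76)]

    def test_moderate_band_called_separately(self):
        vals = np.full(40, 0.02)
        vals[5:12] = 0.15
        cs = call_fluctuation_clusters(_profile(vals))
        assert cs.intervals("moderate") == [(62, 68)]
        assert cs.intervals("high") == []

    def test_misordered_tiers_rejected(self):
        with pytest.raises(ValueError):
            call_fluctuation_clusters(_profile([0.1] * 10), high_thr=0.15,
                                      moderate_band=(0.1, 0.2))


class TestPairDistance:
    def test_three_four_five_triangle(self, tiny_structure):
        from phenodyn.traj_io import AtomRecord, Structure, Trajectory

        atoms = [
            AtomRecord(1, "CA", "GLY", "A", 1, np.array([0.0, 0.0, 0.0])),
            AtomRecord(2, "CA", "GLU", "B", 2, np.array([3.0, 4.0, 0.0])),
        ]
        s = Structure(atoms=atoms)
        traj = Trajectory(topology=s, frames=s.coordinates()[None])
        a = select_atoms(traj, "chain A")
        b = select_atoms(traj, "chain B")
        series = pair_distance_series(traj, a, b)
        assert series.values[0] == pytest.approx(0.5)

    def test_mixture_mean_matches_occupancy(self, small_topology):
        base = FluctuationSpec(reference=small_topology, sigma_per_residue=0.02,
                               n_frames=5000, seed=21)
        contact = ContactSwitchSpec(group_a="chain A and resid 62 and name CA",
                                    group_b="chain B", p_unbind=0.05, p_rebind=0.20,
                                    unbound_offset=0.8, seed=22)
        traj, states = generate_contact_trajectory(base, contact)
        a = select_atoms(traj, "chain A and resid 62 and name CA")
        b = select_atoms(traj, "chain B and resid 968 and name CA")
        series = pair_distance_series(traj, a, b)
        d0 = series.values[0]
        expected = d0 + states.mean() * 0.8  # offset along the pair axis
        assert series.mean == pytest.approx(expected, abs=0.03)

    def test_min_heavy_atom_bounded_by_ca_ca(self, small_topology):
        from phenodyn.traj_io import Trajectory

        traj = Trajectory(topology=small_topology,
                          frames=small_topology.coordinates()[None])
        a_ca = select_atoms(traj, "chain A and resid 62 and name CA")
        b_ca = select_atoms(traj, "chain B and resid 968 and name CA")
        a_all = select_atoms(traj, "chain A and resid 62")
        b_all = select_atoms(traj, "chain B and resid 968")
        ca = pair_distance_series(traj, a_ca, b_ca)
        mh = pair_distance_series(traj, a_all, b_all, mode="min-heavy-atom")
        assert mh.values[0] <= ca.values[0]

    def test_ca_mode_requires_single_atoms(self, small_topology):
        from phenodyn.traj_io import Trajectory

        traj = Trajectory(topology=small_topology,
                          frames=small_topology.coordinates()[None])
        a = select_atoms(traj, "chain A and resid 62")
        b = select_atoms(traj, "chain B and resid 968 and name CA")
        with pytest.raises(ValueError, match="exactly one atom"):
            pair_distance_series(traj, a, b)


class TestDissociation:
    def _series(self, values):
        from phenodyn.traj_stats import DistanceSeries

        return DistanceSeries(values=np.asarray(values, float), pair="x", mode="ca-ca")

    def test_constant_series_never_dissociates(self):
        res = dissociation_frequency(self._series([0.7] * 50))
        assert res.frequency == 0.0
        assert res.alternates == {0.3: 0.0, 0.5: 0.0}

    def test_one_of_three_frames_beyond_threshold(self):
        res = dissociation_frequency(self._series([0.7, 1.3, 0.7]), threshold=0.4)
        assert res.frequency == pytest.approx(1 / 3)
        assert res.n_dissociated == 1

    @given(hst.lists(hst.floats(min_value=0.0, max_value=3.0), min_size=3, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_frequency_non_increasing_in_threshold(self, values):
        series = self._series(values)
        freqs = [dissociation_frequency(series, threshold=t).frequency
                 for t in (0.3, 0.4, 0.5)]
        assert freqs[0] >= freqs[1] >= freqs[2]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            dissociation_frequency(self._series([1.0, 1.0]), threshold=0.0)
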