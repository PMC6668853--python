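import numpy as np
import pytest

from stepfold import dmd_engine as E
from stepfold.forcefield import (Constraint, InteractionTable, StepPotential,
                                 square_well)
from stepfold.model_io import MolecularSystem, Residue


def two_bead_system(d=3.8):
    return MolecularSystem(
        atom_names=["CA", "CA"], elements=["C", "C"],
        formal_charges=np.zeros(2, dtype=int), masses=np.full(2, 12.0),
        coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
        residue_index=np.array([0, 1]),
        residues=[Residue("ALA", "A", 1), Residue("ALA", "A", 2)],
        bonds=[(0, 1)])


def bonded_pair_table(d=3.8, tol=0.05):
    return InteractionTable(
        n_atoms=2, atom_types=["C", "C"],
        constraints=[Constraint(0, 1, d * (1 - tol), d * (1 + tol), "bond")])


class TestNextEventTime:
    def test_head_on_hard_core(self):
        t = E.next_event_time([2.0, 0, 0], [-1.0, 0, 0], 1.0, "inward")
        assert t == pytest.approx(1.0)

    def test_receding_pair_no_event(self):
        assert E.next_event_time([2.0, 0, 0], [1.0, 0, 0], 1.0, "inward") is None

    def test_outward_wall(self):
        t = E.next_event_time([1.0, 0, 0], [1.0, 0, 0], 3.0, "outward")
        assert t == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_dense_scan(self, seed):
        rng = np.random.default_rng(seed)
        dx = rng.normal(scale=2.0, size=3)
        dv = rng.normal(size=3)
        radius = float(np.linalg.norm(dx)) * 0.6
        t = E.next_event_time(dx, dv, radius, "inward")
        ts = np.linspace(0, 20, 2_000_001)
        r = np.linalg.norm(dx[None, :] + np.outer(ts, dv), axis=1)
        hits = np.where(np.diff(np.sign(r - radius)) < 0)[0]
        if t is None:
            assert len(hits) == 0 or r[hits[0]] > radius
        else:
            assert abs(t - ts[hits[0]]) < 1e-4  # scan resolution
            # refine against the quadratic directly
            a = dx @ dx - radius ** 2
            assert abs(np.linalg.norm(dx + t * dv) - radius) < 1e-9

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            E.next_event_time([1, 0, 0], [0, 0, 1], -1.0)


class TestResolveStepCrossing:
    def test_zero_step_crosses_unchanged(self):
        v = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        out, crossed = E.resolve_step_crossing((1.0, 1.0), [1.0, 0, 0],
                                               v.copy(), 0.0)
        assert crossed
        np.testing.assert_allclose(out, v)

    def test_entering_well_speeds_up(self):
        """Equal masses, head-on closing speed 2, well depth 1: the closed
        form gives v_rel' = sqrt(v_rel^2 - 2 dU / mu) with mu = 0.5."""
        v = np.array([[-1.0, 0, 0], [1.0, 0, 0]])  # closing at |v_rel| = 2
        out, crossed = E.resolve_step_crossing((1.0, 1.0), [1.0, 0, 0],
                                               v.copy(), -1.0)
        assert crossed
        v_rel = out[0] - out[1]
        expected = np.sqrt(2.0 ** 2 - 2 * (-1.0) / 0.5)
        assert np.linalg.norm(v_rel) == pytest.approx(expected)

    def test_reflection_conserves_kinetic_energy(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(2, 3))
        masses = (2.0, 5.0)
        dx = np.array([1.3, -0.2, 0.4])
        # force approach so the barrier test is meaningful
        ke_in = 0.5 * masses[0] * v[0] @ v[0] + 0.5 * masses[1] * v[1] @ v[1]
        out, crossed = E.resolve_step_crossing(masses, dx, v.copy(), 1e9)
        assert not crossed
        ke_out = (0.5 * masses[0] * out[0] @ out[0]
                  + 0.5 * masses[1] * out[1] @ out[1])
        assert ke_out == pytest.approx(ke_in, rel=1e-12)

    def test_momentum_conserved(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(2, 3))
        masses = (3.0, 7.0)
        p_in = masses[0] * v[0] + masses[1] * v[1]
        out, _ = E.resolve_step_crossing(masses, [1.0, 0.5, -0.3], v.copy(),
                                         -0.7)
        p_out = masses[0] * out[0] + masses[1] * out[1]
        np.testing.assert_allclose(p_out, p_in, atol=1e-12)


class TestRunDmd:
    def test_energy_conservation_two_beads(self):
        system = two_bead_system()
        traj, state = E.run_dmd(system, bonded_pair_table(tol=0.02), 0.6,
                                7000.0, seed=5, thermostat=False,
                                frame_interval=1.0)
        assert traj.metadata["events"] >= 10_000
        total = traj.potential_energies + traj.kinetic_energies
        assert np.max(np.abs(total - total[0])) <= 1e-7

    def test_equipartition_under_thermostat(self, go_wt):
        _, system, table = go_wt
        T = 0.6
        traj, _ = E.run_dmd(system, table, T, 3000.0, seed=8,
                            thermostat=True, frame_interval=1.0)
        ke = traj.kinetic_energies[traj.n_frames // 5:]
        per_dof = ke / (3 * system.n_atoms)
        # standard error from block means (30 blocks)
        blocks = np.array_split(per_dof, 30)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(per_dof.mean() - T / 2) < 3 * se + 1e-3

    def test_determinism(self, go_wt):
        _, system, table = go_wt
        t1, s1 = E.run_dmd(system, table, 0.5, 200.0, seed=12)
        t2, s2 = E.run_dmd(system, table, 0.5, 200.0, seed=12)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(s1.velocities, s2.velocities)
        assert t1.metadata["events"] == t2.metadata["events"]

    def test_no_hard_core_violations_in_frames(self, go_wt):
        _, system, table = go_wt
        traj, _ = E.run_dmd(system, table, 0.7, 500.0, seed=3)
        compiled = E.CompiledTable(table)
        for f in range(0, traj.n_frames, 50):
            # initial_shells raises on any hard-core violation
            compiled.initial_shells(traj.coords[f])

    def test_running_pe_matches_recompute(self, go_wt):
        _, system, table = go_wt
        traj, state = E.run_dmd(system, table, 0.6, 300.0, seed=21)
        compiled = E.CompiledTable(table)
        _, pe = compiled.initial_shells(state.positions)
        assert pe == pytest.approx(state.potential_energy, abs=1e-6)
        for f in (0, traj.n_frames // 2, traj.n_frames - 1):
            _, pe_f = compiled.initial_shells(traj.coords[f])
            assert pe_f == pytest.approx(traj.potential_energies[f], abs=1e-6)

    def test_time_reversibility_two_body(self):
        system = two_bead_system()
        table = bonded_pair_table()
        _, fwd = E.run_dmd(system, table, 0.6, 50.0, seed=4,
                           thermostat=False)
        back = E.SimState.make(fwd.positions.copy(), -fwd.velocities,
                               fwd.masses, 0.0, fwd.potential_energy, 0)
        _, rev = E.run_dmd(system, table, 0.6, 50.0, seed=4,
                           thermostat=False, state=back)
        # with the center of mass at rest the reversed run retraces the
        # trajectory back to the starting configuration
        np.testing.assert_allclose(rev.positions, system.coords, atol=1e-6)

    def test_overlap_detection_names_pair(self):
        system = two_bead_system(d=1.0)
        table = InteractionTable(n_atoms=2, atom_types=["C", "C"],
                                 pair_overrides={(0, 1): square_well(2.0, 4.0, -1.0)})
        with pytest.raises(E.InitializationError, match="0 and 1"):
            E.run_dmd(system, table, 0.5, 10.0, seed=1)

    def test_bad_length(self, go_wt):
        _, system, table = go_wt
        with pytest.raises(ValueError):
            E.run_dmd(system, table, 0.5, -1.0, seed=1)


def test_staged_equilibration_keeps_structure_valid(go_pair):
    wt, variant, site = go_pair
    system = variant.to_system()
    table = variant.interaction_table()
    state = E.staged_equilibration(system, table, seed=6)
    compiled = E.CompiledTable(table)
    compiled.initial_shells(state.positions)  # no overlap, no breach
    assert state.kinetic_energy > 0


def test_trajectory_output_files(tmp_path, go_wt):
    _, system, table = go_wt
    traj, _ = E.run_dmd(system, table, 0.5, 50.0, seed=2, frame_interval=5.0)
    E.write_energy_table(traj, tmp_path / "energies.txt")
    E.write_trajectory_pdb(traj, system, tmp_path / "traj.pdb")
    energies = np.loadtxt(tmp_path / "energies.txt", usecols=(1,))
    assert len(energies) == traj.n_frames
    text = (tmp_path / "traj.pdb").read_text()
    assert text.count("MODEL") == traj.n_frames
    assert text.count("ENDMDL") == traj.n_frames
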