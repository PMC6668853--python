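import numpy as np
import pytest

from stepfold import synthetic_data as S
from stepfold.forcefield import compute_energy, native_contacts
from stepfold.model_io import dihedral


class TestTwoState:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            S.make_two_state(0.0, 2.0, 0, 5)
        with pytest.raises(ValueError):
            S.make_two_state(2.0, 1.0, 1, 5)

    def test_low_temperature_limit_ground_only(self):
        system, sampler = S.make_two_state(0.0, 2.0, 1, 50)
        draws = sampler(0.01, 5000, 3)
        assert np.all(draws == 0.0)

    def test_sampler_matches_boltzmann_weights(self):
        system, sampler = S.make_two_state(0.0, 2.0, 1, 50)
        T, n = 1.0, 100_000
        draws = sampler(T, n, 11)
        p1 = system.excited_probability(T)
        observed = np.mean(draws == 2.0)
        sigma = np.sqrt(p1 * (1 - p1) / n)
        assert abs(observed - p1) < 3 * sigma

    def test_closed_forms_match_direct_summation(self):
        system, _ = S.make_two_state(-1.0, 3.0, 2, 30)
        for T in (0.3, 1.0, 4.0):
            z = 2 * np.exp(1.0 / T) + 30 * np.exp(-3.0 / T)
            mean = (2 * np.exp(1.0 / T) * (-1.0)
                    + 30 * np.exp(-3.0 / T) * 3.0) / z
            e2 = (2 * np.exp(1.0 / T) * 1.0
                  + 30 * np.exp(-3.0 / T) * 9.0) / z
            assert system.partition_function(T) == pytest.approx(z, rel=1e-12)
            assert system.mean_energy(T) == pytest.approx(mean, rel=1e-12)
            assert system.cv(T) == pytest.approx((e2 - mean ** 2) / T ** 2,
                                                 rel=1e-12)

    def test_cv_peak_matches_grid_maximization(self):
        system, _ = S.make_two_state(0.0, 2.0, 1, 50)
        T_opt, cv_opt = system.cv_peak()
        grid = np.linspace(0.01, 5.0, 200_001)
        cv = system.cv(grid)
        k = int(np.argmax(cv))
        assert abs(grid[k] - T_opt) <= grid[1] - grid[0]
        assert cv[k] == pytest.approx(cv_opt, rel=1e-6)


class TestGoPeptide:
    def test_determinism(self):
        a = S.make_go_peptide(16, "hairpin", 0.6, 3)[0]
        b = S.make_go_peptide(16, "hairpin", 0.6, 3)[0]
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.contacts == b.contacts

    @pytest.mark.parametrize("fold", ["hairpin", "helix"])
    def test_fold_templates_buildable(self, fold):
        peptide, system, table = S.make_go_peptide(16, fold, 0.6, 1)
        assert system.n_residues == 16
        assert len(peptide.contacts) > 0
        assert all(j - i >= 3 for i, j in peptide.contacts)

    def test_contact_recount_matches(self):
        peptide, system, table = S.make_go_peptide(20, "hairpin", 0.6, 4)
        brute = [(i, j) for i in range(20) for j in range(i + 3, 20)
                 if np.linalg.norm(peptide.positions[i]
                                   - peptide.positions[j]) <= peptide.cutoff]
        assert sorted(peptide.contacts) == brute
        assert sorted(native_contacts(table)) == brute

    def test_native_energy_is_contact_sum(self, go_wt):
        peptide, system, table = go_wt
        e = compute_energy(system.coords, table)
        assert e == pytest.approx(-peptide.eps * len(peptide.contacts))

    def test_too_few_residues(self):
        with pytest.raises(ValueError):
            S.make_go_peptide(6)

    def test_unknown_fold(self):
        with pytest.raises(ValueError):
            S.make_go_peptide(16, "sheet")

    def test_pdb_fixture_round_trip(self, tmp_path, go_wt):
        from stepfold.forcefield import InteractionTable
        from stepfold.model_io import read_pdb
        peptide, system, table = go_wt
        paths = S.write_go_fixture(peptide, tmp_path)
        back = read_pdb(paths["pdb"])
        assert back.n_residues == peptide.n_residues
        np.testing.assert_allclose(back.coords, peptide.positions, atol=2e-3)
        table_back = InteractionTable.from_text(paths["table"].read_text())
        assert set(table_back.pair_overrides) == set(table.pair_overrides)


class TestModifiedVariant:
    def test_null_modification_identical_energies(self, go_wt):
        peptide, system, table = go_wt
        null = S.make_modified_variant(peptide, 5, 0.0, 0.0)
        t2 = null.interaction_table()
        for key, pot in table.pair_overrides.items():
            assert t2.pair_overrides[key].energies == pytest.approx(
                pot.energies)
        assert compute_energy(system.coords, t2) == pytest.approx(
            compute_energy(system.coords, table))

    def test_only_site_wells_change(self, go_pair):
        wt, variant, site = go_pair
        t_wt = wt.interaction_table()
        t_var = variant.interaction_table()
        changed = [key for key in t_wt.pair_overrides
                   if not np.allclose(t_wt.pair_overrides[key].energies,
                                      t_var.pair_overrides[key].energies)]
        assert all(site in key for key in changed)
        assert len(changed) == wt.contact_degree(site)

    def test_ground_state_raised_by_weakening(self, go_pair):
        wt, variant, site = go_pair
        e_wt = compute_energy(wt.to_system().coords, wt.interaction_table())
        e_var = compute_energy(variant.to_system().coords,
                               variant.interaction_table())
        _, dr, de = variant.modified_site
        expected_raise = de * wt.eps * wt.contact_degree(site)
        assert e_var - e_wt == pytest.approx(expected_raise, rel=1e-9)

    def test_site_annotated_in_system(self, go_pair):
        _, variant, site = go_pair
        system = variant.to_system()
        assert system.residues[site].name == "MOD"
        assert system.formal_charges[site] == 1

    def test_invalid_arguments(self, go_wt):
        peptide, _, _ = go_wt
        with pytest.raises(ValueError):
            S.make_modified_variant(peptide, 99)
        with pytest.raises(ValueError):
            S.make_modified_variant(peptide, 5, 0.3, 1.0)
        with pytest.raises(ValueError):
            S.make_modified_variant(peptide, 5, -0.1, 0.5)

    def test_default_site_is_core(self, go_wt):
        peptide, _, _ = go_wt
        site = S.default_modified_site(peptide)
        degrees = [peptide.contact_degree(i)
                   for i in range(peptide.n_residues)]
        assert degrees[site] == max(degrees)
        assert 2 <= site <= peptide.n_residues - 3


def test_deeper_wells_raise_melting_temperature(go_wt):
    """REMD + WHAM: doubling ε moves the major C_V peak up (fixed seeds,
    fixed ladder)."""
    from stepfold.remd import ReplicaLadder, run_remd
    from stepfold.thermo_wham import EnergyHistogramSet, melting_profile

    ladder = ReplicaLadder((0.45, 0.49, 0.53, 0.57, 0.61, 0.66, 0.71, 0.77),
                           exchange_interval=50.0)
    grid = np.linspace(0.35, 0.95, 241)
    majors = {}
    for eps in (0.5, 1.0):
        peptide, system, table = S.make_go_peptide(20, "hairpin", eps, 0)
        trajs, _ = run_remd(system, table, ladder, 2500.0, 13,
                            frame_interval=2.0)
        samples, temps = [], []
        for T in sorted(trajs):
            pe = trajs[T].potential_energies
            samples.append(pe[len(pe) // 5:])
            temps.append(T)
        profile = melting_profile(
            EnergyHistogramSet.from_samples(samples, temps), grid)
        assert profile.major_peak is not None
        majors[eps] = profile.major_peak
    assert majors[1.0] > majors[0.5]


class TestPeptideBuilder:
    def test_residue_and_atom_counts(self):
        system = S.build_peptide(["GLY", "SER", "GLY"])
        assert system.n_residues == 3
        assert system.n_atoms == 4 + 6 + 4

    def test_backbone_geometry(self):
        system = S.build_peptide(["GLY", "GLY", "GLY"], phi=-60, psi=-45)
        r2 = system.find_residue("A", 2)
        n = system.coords[system.atom_index(r2, "N")]
        ca = system.coords[system.atom_index(r2, "CA")]
        c = system.coords[system.atom_index(r2, "C")]
        assert np.linalg.norm(ca - n) == pytest.approx(1.458, abs=1e-6)
        assert np.linalg.norm(c - ca) == pytest.approx(1.525, abs=1e-6)
        cp = system.coords[system.atom_index(system.find_residue("A", 1), "C")]
        assert dihedral(cp, n, ca, c) == pytest.approx(-60.0, abs=1e-6)

    def test_peptide_bonds_present(self):
        system = S.build_peptide(["GLY", "SER", "GLY"])
        c1 = system.atom_index(system.find_residue("A", 1), "C")
        n2 = system.atom_index(system.find_residue("A", 2), "N")
        assert (min(c1, n2), max(c1, n2)) in system.bonds


class TestPackedCore:
    def test_structure(self, packed_core):
        assert packed_core.residues[-1].name == "OBS"
        obstacles = packed_core.residue_atoms(packed_core.n_residues - 1)
        assert len(obstacles) == 2

    def test_serine_escape_channel_open(self, packed_core):
        """The wild-type serine has a rotamer that clears the obstacles by
        more than a contact distance."""
        ridx = packed_core.find_residue("A", 2)
        og = packed_core.coords[packed_core.atom_index(ridx, "OG")]
        from stepfold.model_io import build_sidechain, builtin_template
        backbone = {nm: packed_core.coords[packed_core.atom_index(ridx, nm)]
                    for nm in ("N", "CA", "C", "O")}
        open_og = build_sidechain(builtin_template("SER"), backbone,
                                  chi=[-60.0])["OG"]
        obstacles = [packed_core.coords[i] for i in
                     packed_core.residue_atoms(packed_core.n_residues - 1)]
        dists = [np.linalg.norm(open_og - o) for o in obstacles]
        assert min(dists) > 3.2
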