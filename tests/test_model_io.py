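import numpy as np
import pytest

from stepfold import model_io as M
from stepfold.forcefield import build_go_model, compute_energy
from stepfold.synthetic_data import build_peptide, make_go_peptide

from conftest import merge_systems

PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.760   1.200  1.00  0.00           C
ATOM      6  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.030   1.581   0.000  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.530   3.680   1.210  1.00  0.00           C
ATOM     11  N   ALA A   3       6.214   3.812   0.000  1.00  0.00           N
ATOM     12  CA  ALA A   3       7.673   3.810   0.000  1.00  0.00           C
ATOM     13  C   ALA A   3       8.224   5.230   0.000  1.00  0.00           C
ATOM     14  O   ALA A   3       7.467   6.200   0.000  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.215   3.050   1.200  1.00  0.00           C
END
"""

PDB_WATER = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


class TestReadPdb:
    def test_counts_from_fixture(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3RES)
        system = M.read_pdb(p)
        assert system.n_residues == 3
        assert system.n_atoms == 15
        assert [r.seq for r in system.residues] == [1, 2, 3]

    def test_waters_only_raises(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(PDB_WATER)
        with pytest.raises(M.EmptyStructureError):
            M.read_pdb(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            M.read_pdb(tmp_path / "nope.pdb")

    def test_round_trip(self, tmp_path):
        p = tmp_path / "in.pdb"
        p.write_text(PDB_3RES)
        first = M.read_pdb(p)
        out = tmp_path / "out.pdb"
        M.write_pdb(first, out)
        second = M.read_pdb(out)
        assert second.atom_names == first.atom_names
        assert [r.seq for r in second.residues] == [r.seq for r in first.residues]
        np.testing.assert_allclose(second.coords, first.coords, atol=1.5e-3)
        # writing again reproduces identical bytes (idempotent format)
        out2 = tmp_path / "out2.pdb"
        M.write_pdb(second, out2)
        assert out.read_text() == out2.read_text()

    def test_ca_trace_bonds_consecutive(self, tmp_path):
        _, system, _ = make_go_peptide(10, "hairpin", 0.6, 1)
        p = tmp_path / "trace.pdb"
        M.write_pdb(system, p, write_conect=False)
        back = M.read_pdb(p)
        assert back.bonds == [(i, i + 1) for i in range(9)]

    def test_conect_bonds_preserved(self, tmp_path):
        system = build_peptide(["GLY", "SER", "GLY"])
        p = tmp_path / "pep.pdb"
        M.write_pdb(system, p)
        back = M.read_pdb(p)
        assert set(back.bonds) == set(system.bonds)


class TestTemplates:
    def test_bmaa_template(self):
        tpl = M.bmaa_template()
        assert tpl.n_chi == 2
        assert tpl.net_charge == 1
        assert tpl.heavy_sidechain_count() == 3

    def test_builtin_templates_self_consistent(self):
        for name in ("SER", "ALA", "LYS", "BMAA", "GLY"):
            tpl = M.builtin_template(name)
            placeable = {a for a, *_ in tpl.internal} | set(M.BACKBONE_ATOMS)
            assert {a for a, _, _ in tpl.atoms} <= placeable
            assert tpl.n_chi == len(tpl.chi_atoms)

    def test_unknown_template_raises(self):
        with pytest.raises(KeyError):
            M.builtin_template("XYZ")

    def test_chi_angle_honoured(self):
        tpl = M.builtin_template("SER")
        backbone = {"N": np.zeros(3), "CA": np.array([1.458, 0, 0]),
                    "C": np.array([2.0, 1.42, 0]), "O": np.array([1.25, 2.39, 0])}
        for chi in (-60.0, 60.0, 175.0):
            placed = M.build_sidechain(tpl, backbone, chi=[chi])
            measured = M.dihedral(placed["N"], placed["CA"], placed["CB"],
                                  placed["OG"])
            assert abs(measured - chi) < 1e-6


class TestSubstitution:
    def test_identity_substitution(self, tripeptide):
        out = M.substitute_residue(tripeptide, "A", 2, M.builtin_template("SER"))
        assert out.n_atoms == tripeptide.n_atoms
        assert out.n_residues == tripeptide.n_residues
        assert set(out.bonds) == set(tripeptide.bonds)

    def test_identity_substitution_preserves_energy(self, tripeptide):
        """Same template, same χ: identical geometry, identical energy."""
        from stepfold.forcefield import InteractionTable, topology_pairs

        out = M.substitute_residue(tripeptide, "A", 2,
                                   M.builtin_template("SER"), chi=[60.0])

        def energy(system):
            p12, p13, p14 = topology_pairs(system.n_atoms, system.bonds)
            table = InteractionTable(
                n_atoms=system.n_atoms,
                atom_types=list(system.elements),
                exclusions=p12 | p13 | p14)
            return compute_energy(system.coords, table)

        assert energy(out) == pytest.approx(energy(tripeptide), abs=1e-9)

    def test_bmaa_substitution_counts(self, tripeptide):
        chain_b = build_peptide(["GLY", "SER", "GLY"], chain="B")
        two = merge_systems(tripeptide, chain_b)
        ser = M.builtin_template("SER")
        bmaa = M.bmaa_template()
        out = M.substitute_residue(two, "A", 2, bmaa)
        delta = len(bmaa.sidechain_atoms) - len(ser.sidechain_atoms)
        a_before = sum(1 for i in range(two.n_atoms)
                       if two.residues[two.residue_index[i]].chain == "A")
        a_after = sum(1 for i in range(out.n_atoms)
                      if out.residues[out.residue_index[i]].chain == "A")
        b_after = sum(1 for i in range(out.n_atoms)
                      if out.residues[out.residue_index[i]].chain == "B")
        assert a_after - a_before == delta
        assert b_after == chain_b.n_atoms
        assert out.n_residues == two.n_residues

    def test_only_target_residue_changes(self, tripeptide):
        out = M.substitute_residue(tripeptide, "A", 2, M.bmaa_template())
        for res_seq in (1, 3):
            ridx_in = tripeptide.find_residue("A", res_seq)
            ridx_out = out.find_residue("A", res_seq)
            atoms_in = tripeptide.residue_atoms(ridx_in)
            atoms_out = out.residue_atoms(ridx_out)
            names_in = [tripeptide.atom_names[i] for i in atoms_in]
            names_out = [out.atom_names[i] for i in atoms_out]
            assert names_in == names_out
            np.testing.assert_array_equal(tripeptide.coords[atoms_in],
                                          out.coords[atoms_out])

    def test_backbone_retained_and_peptide_links(self, tripeptide):
        out = M.substitute_residue(tripeptide, "A", 2, M.bmaa_template())
        ridx = out.find_residue("A", 2)
        for name in ("N", "CA", "C", "O"):
            i_old = tripeptide.atom_index(tripeptide.find_residue("A", 2), name)
            i_new = out.atom_index(ridx, name)
            np.testing.assert_array_equal(tripeptide.coords[i_old],
                                          out.coords[i_new])
        kinds = {k for k, _, _ in out.special_constraints}
        assert "peptide" in kinds

    def test_missing_residue_raises(self, tripeptide):
        with pytest.raises(M.ResidueNotFoundError):
            M.substitute_residue(tripeptide, "A", 99, M.bmaa_template())

    def test_incomplete_backbone_raises(self, tripeptide):
        broken = tripeptide.copy()
        ridx = broken.find_residue("A", 2)
        keep = [i for i in range(broken.n_atoms)
                if not (broken.residue_index[i] == ridx
                        and broken.atom_names[i] == "O")]
        import numpy as _np
        broken = M.MolecularSystem(
            atom_names=[broken.atom_names[i] for i in keep],
            elements=[broken.elements[i] for i in keep],
            formal_charges=broken.formal_charges[keep],
            masses=broken.masses[keep],
            coords=broken.coords[keep],
            residue_index=broken.residue_index[keep],
            residues=broken.residues,
            bonds=[])
        with pytest.raises(M.IncompleteBackboneError):
            M.substitute_residue(broken, "A", 2, M.bmaa_template())


def test_special_constraint_detection():
    """Two sulfur atoms of CYS residues within 2.5 Å register a disulfide;
    a zinc next to a nitrogen registers a metal link."""
    import numpy as np

    coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [6.0, 0, 0], [6.0, 2.0, 0]])
    system = M.MolecularSystem(
        atom_names=["SG", "SG", "ZN", "N"],
        elements=["S", "S", "ZN", "N"],
        formal_charges=np.zeros(4, dtype=int),
        masses=np.ones(4),
        coords=coords,
        residue_index=np.array([0, 1, 2, 3]),
        residues=[M.Residue("CYS", "A", 1), M.Residue("CYS", "A", 2),
                  M.Residue("ZN", "A", 3), M.Residue("GLY", "A", 4)])
    found = M.detect_special_constraints(system)
    kinds = sorted(k for k, _, _ in found)
    assert kinds == ["disulfide", "metal"]
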