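import numpy as np
import pytest

from stepfold.synthetic_data import (build_peptide, make_go_peptide,
                                     make_modified_variant,
                                     make_packed_core_fixture,
                                     default_modified_site)


@pytest.fixture(scope="session")
def go_wt():
    peptide, system, table = make_go_peptide(20, "hairpin", 0.6, 0)
    return peptide, system, table


@pytest.fixture(scope="session")
def go_pair(go_wt):
    peptide, _, _ = go_wt
    site = default_modified_site(peptide)
    variant = make_modified_variant(peptide, site)
    return peptide, variant, site


@pytest.fixture(scope="session")
def packed_core():
    return make_packed_core_fixture()


@pytest.fixture(scope="session")
def tripeptide():
    return build_peptide(["GLY", "SER", "GLY"])


def merge_systems(a, b):
    """Concatenate two MolecularSystems (distinct chains) into one."""
    from stepfold.model_io import MolecularSystem

    n = a.n_atoms
    nres = a.n_residues
    return MolecularSystem(
        atom_names=a.atom_names + b.atom_names,
        elements=a.elements + b.elements,
        formal_charges=np.concatenate([a.formal_charges, b.formal_charges]),
        masses=np.concatenate([a.masses, b.masses]),
        coords=np.vstack([a.coords, b.coords]),
        residue_index=np.concatenate([a.residue_index, b.residue_index + nres]),
        residues=a.residues + b.residues,
        bonds=a.bonds + [(i + n, j + n) for i, j in b.bonds],
        special_constraints=(a.special_constraints +
                             [(k, i + n, j + n)
                              for k, i, j in b.special_constraints]),
    )
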