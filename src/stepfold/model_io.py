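"""Molecular model container, PDB input/output, residue templates and point
substitution.

The in-memory model (:class:`MolecularSystem`) is deliberately small: flat
numpy coordinate/mass arrays plus per-atom residue bookkeeping, a symmetric
duplicate-free bond list, and a list of *special constraints* (disulfide
bridges, metal--ligand links, regenerated peptide links) that downstream
force-field construction turns into infinite square wells.

Residue templates describe side chains in internal coordinates (bond length,
bond angle, torsion) so that a point substitution can graft a new side chain
onto an existing backbone.  The torsion field of an internal-coordinate line
may be a literal angle or a symbolic ``chi<k>`` reference resolved at build
time; this is how a library rotamer or a staggered seed conformation is
applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MolecularSystem",
    "ResidueTemplate",
    "EmptyStructureError",
    "ResidueNotFoundError",
    "IncompleteBackboneError",
    "read_pdb",
    "write_pdb",
    "substitute_residue",
    "bmaa_template",
    "load_template",
    "builtin_template",
    "place_atom",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3"}

# PDB columns hold 3-character residue names; longer internal names map to a
# 3-character code on write and back on read
_PDB_RESNAME_ALIASES = {"BMAA": "BMA"}
_PDB_RESNAME_REVERSE = {v: k for k, v in _PDB_RESNAME_ALIASES.items()}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "CU": 63.546, "ZN": 65.38, "FE": 55.845,
    "MG": 24.305, "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45,
    "X": 12.011,
}

# single-bond covalent radii (Å) for distance-based bond inference
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "SE": 1.20, "CU": 1.32, "ZN": 1.22, "FE": 1.32, "MG": 1.41,
    "CA": 1.76, "NA": 1.66, "K": 2.03, "CL": 1.02,
}

_METAL_ELEMENTS = {"CU", "ZN", "FE", "MG", "CA", "NA", "K", "MN", "NI", "CO"}


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no usable atoms after filtering."""


class ResidueNotFoundError(KeyError):
    """Raised when a (chain, residue number) address does not exist."""


class IncompleteBackboneError(ValueError):
    """Raised when a substitution site lacks one of the N/CA/C/O anchors."""


@dataclass
class Residue:
    name: str
    chain: str
    seq: int


@dataclass
class MolecularSystem:
    """Atoms, coordinates and topology of one molecular model.

    Attributes
    ----------
    atom_names, elements : per-atom identifier strings.
    formal_charges : integer formal charge per atom.
    masses : atomic masses, amu.
    coords : Cartesian coordinates, Å, shape (n_atoms, 3).
    residue_index : index into ``residues`` per atom.
    residues : ordered residue records (3-letter name, chain id, 1-based
        author sequence number, as read from the PDB).
    bonds : sorted, duplicate-free list of 0-based atom index pairs.
    special_constraints : list of ``(kind, i, j)`` with kind in
        {"disulfide", "metal", "peptide"}.
    """

    atom_names: list[str]
    elements: list[str]
    formal_charges: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    residue_index: np.ndarray
    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    special_constraints: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        n = self.n_atoms
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.residue_index) != n:
            raise ValueError("residue_index length mismatch")
        seen = set()
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        keys = {(r.chain, r.seq) for r in self.residues}
        if len(keys) != len(self.residues):
            raise ValueError("duplicate (chain, seq) residue address")

    def residue_atoms(self, ridx: int) -> np.ndarray:
        return np.where(self.residue_index == ridx)[0]

    def find_residue(self, chain: str, seq: int) -> int:
        for idx, res in enumerate(self.residues):
            if res.chain == chain and res.seq == seq:
                return idx
        raise ResidueNotFoundError(f"residue {chain}:{seq} not found")

    def atom_index(self, ridx: int, name: str) -> int | None:
        for i in self.residue_atoms(ridx):
            if self.atom_names[i] == name:
                return int(i)
        return None

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atom_names=list(self.atom_names),
            elements=list(self.elements),
            formal_charges=self.formal_charges.copy(),
            masses=self.masses.copy(),
            coords=self.coords.copy(),
            residue_index=self.residue_index.copy(),
            residues=[replace(r) for r in self.residues],
            bonds=list(self.bonds),
            special_constraints=list(self.special_constraints),
        )


@dataclass
class ResidueTemplate:
    """Internal-coordinate description of one residue type.

    ``internal`` holds one entry per placeable atom:
    ``(atom, ref1, ref2, ref3, bond Å, angle deg, torsion)`` where the
    torsion is either a float (degrees) or the string ``"chi<k>"`` (1-based).
    ``chi_atoms`` lists the four atom names defining each χ torsion, in
    order χ1, χ2, ...
    """

    name: str
    atoms: list[tuple[str, str, int]]  # (name, element, formal charge)
    bonds: list[tuple[str, str]]
    internal: list[tuple[str, str, str, str, float, float, object]]
    chi_atoms: list[tuple[str, str, str, str]]
    net_charge: int

    @property
    def n_chi(self) -> int:
        return len(self.chi_atoms)

    @property
    def sidechain_atoms(self) -> list[tuple[str, str, int]]:
        return [a for a in self.atoms if a[0] not in BACKBONE_ATOMS]

    def heavy_sidechain_count(self) -> int:
        return sum(1 for n, e, _ in self.sidechain_atoms if e.upper() != "H")


# ---------------------------------------------------------------------------
# geometry: NeRF atom placement from internal coordinates
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given reference positions A, B, C so that |CD| = bond,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion (natural extension
    reference frame construction)."""
    theta = math.radians(angle_deg)
    phi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear references: pick any perpendicular
        ref = np.array([1.0, 0.0, 0.0]) if abs(bc[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        n = np.cross(ref, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# template files
# ---------------------------------------------------------------------------

def load_template(path_or_text) -> ResidueTemplate:
    """Parse a plain-text residue template with [atoms], [bonds], [chi] and
    [internal] sections."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    name = "UNK"
    net_charge = 0
    section = None
    atoms: list[tuple[str, str, int]] = []
    bonds: list[tuple[str, str]] = []
    chi: list[tuple[str, str, str, str]] = []
    internal: list = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].lower()
            continue
        parts = line.split()
        if section is None:
            if parts[0].lower() == "name":
                name = parts[1]
            elif parts[0].lower() == "net_charge":
                net_charge = int(parts[1])
        elif section == "atoms":
            atoms.append((parts[0], parts[1], int(parts[2]) if len(parts) > 2 else 0))
        elif section == "bonds":
            bonds.append((parts[0], parts[1]))
        elif section == "chi":
            chi.append(tuple(parts[:4]))  # type: ignore[arg-type]
        elif section == "internal":
            tors: object
            try:
                tors = float(parts[6])
            except ValueError:
                tors = parts[6]
            internal.append((parts[0], parts[1], parts[2], parts[3],
                             float(parts[4]), float(parts[5]), tors))
    tpl = ResidueTemplate(name=name, atoms=atoms, bonds=bonds,
                          internal=internal, chi_atoms=chi, net_charge=net_charge)
    if tpl.n_chi != sum(1 for e in internal if isinstance(e[6], str)):
        # each symbolic chi reference must correspond to a declared chi
        syms = {e[6] for e in internal if isinstance(e[6], str)}
        for s in syms:
            k = int(str(s).removeprefix("chi"))
            if not 1 <= k <= tpl.n_chi:
                raise ValueError(f"template {name}: undefined torsion symbol {s}")
    return tpl


def builtin_template(name: str) -> ResidueTemplate:
    """Load one of the packaged residue templates (SER, ALA, LYS, BMAA)."""
    fname = f"{name.lower()}.tpl"
    ref = resources.files("stepfold.data").joinpath(fname)
    if not ref.is_file():
        raise KeyError(f"no built-in template named {name!r}")
    return load_template(ref.read_text())


def bmaa_template() -> ResidueTemplate:
    """β-methylamino-L-alanine: serine's size class plus an N-methyl group.

    Side chain is CB–Nγ(H)–Cγ(methyl) with the secondary amine protonated,
    giving two χ torsions and a net formal charge of +1 carried on Nγ.
    Geometry uses standard amino-acid bond lengths and tetrahedral angles
    (Cβ–N 1.47 Å, N–C 1.47 Å).
    """
    return builtin_template("BMAA")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_of(atom) -> str:
    el = (atom.element or "").strip().upper()
    if not el:
        nm = atom.get_name().strip()
        el = "".join(ch for ch in nm if ch.isalpha())[:1].upper()
    return el or "X"


def read_pdb(path, *, keep_waters: bool = False,
             infer_bonds: bool = True) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    All chains are kept; author residue numbering is preserved.  Alternate
    locations other than blank/'A' are dropped, waters are skipped unless
    ``keep_waters``.  Bonds come from CONECT records when present, otherwise
    from covalent-radius distance inference (consecutive Cα for single-bead
    chains).  Disulfide and metal--ligand pairs are detected by distance and
    stored as special constraints.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read PDB file {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))

    atom_names: list[str] = []
    elements: list[str] = []
    charges: list[int] = []
    coords: list[np.ndarray] = []
    residue_index: list[int] = []
    residues: list[Residue] = []
    serial_map: dict[int, int] = {}

    model = next(structure.get_models())
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if not keep_waters and resname in _WATER_NAMES:
                continue
            het, seq, icode = res.get_id()
            ridx = None
            for atom in res:
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                if ridx is None:
                    ridx = len(residues)
                    residues.append(Residue(
                        _PDB_RESNAME_REVERSE.get(resname, resname),
                        chain.id.strip() or "A", int(seq)))
                atom_names.append(atom.get_name().strip())
                elements.append(_element_of(atom))
                charges.append(0)
                coords.append(np.asarray(atom.get_coord(), dtype=float))
                residue_index.append(ridx)
                serial = atom.get_serial_number()
                if serial is not None:
                    serial_map[int(serial)] = len(atom_names) - 1

    if not atom_names:
        raise EmptyStructureError(f"{path}: no atoms after filtering")

    masses = np.array([ELEMENT_MASSES.get(e, ELEMENT_MASSES["X"]) for e in elements])
    system = MolecularSystem(
        atom_names=atom_names,
        elements=elements,
        formal_charges=np.array(charges, dtype=int),
        masses=masses,
        coords=np.vstack(coords),
        residue_index=np.array(residue_index, dtype=int),
        residues=residues,
    )

    conect = _parse_conect(path, serial_map)
    if conect:
        system.bonds = conect
    elif infer_bonds:
        system.bonds = _infer_bonds(system)
    system.special_constraints = detect_special_constraints(system)
    system.validate()
    return system


def _parse_conect(path: Path, serial_map: dict[int, int]) -> list[tuple[int, int]]:
    bonds = set()
    for line in path.read_text().splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = line[6:].split()
        if len(fields) < 2:
            continue
        try:
            serials = [int(f) for f in fields]
        except ValueError:
            continue
        a = serial_map.get(serials[0])
        if a is None:
            continue
        for s in serials[1:]:
            b = serial_map.get(s)
            if b is not None and a != b:
                bonds.add((min(a, b), max(a, b)))
    return sorted(bonds)


def _infer_bonds(system: MolecularSystem) -> list[tuple[int, int]]:
    bonds: set[tuple[int, int]] = set()
    n = system.n_atoms
    coords = system.coords
    radii = np.array([_COVALENT_RADII.get(e, 0.77) for e in system.elements])
    # distance-based within + between consecutive residues
    cut = radii[:, None] + radii[None, :] + 0.45
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.where((d < cut) & (d > 0.1))
    for a, b in zip(ii, jj):
        if a < b:
            ra, rb = system.residue_index[a], system.residue_index[b]
            if abs(int(ra) - int(rb)) <= 1:
                bonds.add((int(a), int(b)))
    # Cα-trace chains: one atom per residue, bond consecutive residues
    per_res = [len(system.residue_atoms(r)) for r in range(system.n_residues)]
    if all(c == 1 for c in per_res) and not bonds:
        for r in range(system.n_residues - 1):
            r1, r2 = system.residues[r], system.residues[r + 1]
            if r1.chain == r2.chain:
                a = int(system.residue_atoms(r)[0])
                b = int(system.residue_atoms(r + 1)[0])
                bonds.add((a, b))
    return sorted(bonds)


def detect_special_constraints(system: MolecularSystem,
                               ss_cut: float = 2.5,
                               metal_cut: float = 2.8) -> list[tuple[str, int, int]]:
    """Distance-detected disulfide (S–S < ``ss_cut`` Å) and metal–N/O
    (< ``metal_cut`` Å) constraint pairs."""
    out: list[tuple[str, int, int]] = []
    sulfurs = [i for i in range(system.n_atoms)
               if system.elements[i] == "S" and
               system.residues[system.residue_index[i]].name == "CYS"]
    for a_i, a in enumerate(sulfurs):
        for b in sulfurs[a_i + 1:]:
            if np.linalg.norm(system.coords[a] - system.coords[b]) < ss_cut:
                out.append(("disulfide", a, b))
    metals = [i for i in range(system.n_atoms) if system.elements[i] in _METAL_ELEMENTS]
    ligands = [i for i in range(system.n_atoms) if system.elements[i] in ("N", "O")]
    for m in metals:
        for l in ligands:
            if np.linalg.norm(system.coords[m] - system.coords[l]) < metal_cut:
                out.append(("metal", m, l))
    return out


def write_pdb(system: MolecularSystem, path, *, write_conect: bool = True) -> None:
    """Write a MolecularSystem as a PDB file (ATOM/TER/CONECT records)."""
    lines = []
    serial = 0
    last_chain = None
    atom_serials = np.zeros(system.n_atoms, dtype=int)
    for i in range(system.n_atoms):
        res = system.residues[system.residue_index[i]]
        if last_chain is not None and res.chain != last_chain:
            lines.append("TER")
        last_chain = res.chain
        serial += 1
        atom_serials[i] = serial
        name = system.atom_names[i]
        pname = f" {name:<3s}" if len(name) < 4 else name
        x, y, z = system.coords[i]
        el = system.elements[i]
        q = int(system.formal_charges[i])
        qs = "" if q == 0 else (f"{abs(q)}{'+' if q > 0 else '-'}")
        resname = _PDB_RESNAME_ALIASES.get(res.name, res.name[:3])
        lines.append(
            f"ATOM  {serial:5d} {pname:<4s}{resname:>4s} {res.chain:1s}"
            f"{res.seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {el:>2s}{qs:<2s}"
        )
    lines.append("TER")
    if write_conect:
        neigh: dict[int, list[int]] = {}
        for a, b in system.bonds:
            neigh.setdefault(a, []).append(b)
            neigh.setdefault(b, []).append(a)
        for a in sorted(neigh):
            ns = sorted(neigh[a])
            for k in range(0, len(ns), 4):
                chunk = "".join(f"{atom_serials[b]:5d}" for b in ns[k:k + 4])
                lines.append(f"CONECT{atom_serials[a]:5d}{chunk}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# point substitution
# ---------------------------------------------------------------------------

def build_sidechain(template: ResidueTemplate,
                    backbone: dict[str, np.ndarray],
                    chi: Sequence[float] | None = None) -> dict[str, np.ndarray]:
    """Place template side-chain atoms from internal coordinates given the
    backbone anchor positions (N, CA, C at minimum).

    ``chi`` supplies the χ torsions in degrees; defaults to the first
    staggered value (+60°) for every χ.
    """
    if chi is None:
        chi = [60.0] * template.n_chi
    if len(chi) != template.n_chi:
        raise ValueError(f"expected {template.n_chi} chi angles, got {len(chi)}")
    placed: dict[str, np.ndarray] = dict(backbone)
    for (atom, r1, r2, r3, bond, angle, tors) in template.internal:
        if atom in placed:
            continue
        if isinstance(tors, str):
            k = int(tors.removeprefix("chi"))
            tval = float(chi[k - 1])
        else:
            tval = float(tors)
        try:
            c, b, a = placed[r1], placed[r2], placed[r3]
        except KeyError as exc:
            raise ValueError(f"template {template.name}: reference atom "
                             f"{exc.args[0]} not yet placed for {atom}") from exc
        placed[atom] = place_atom(a, b, c, bond, angle, tval)
    return placed


def substitute_residue(system: MolecularSystem, chain: str, seq: int,
                       template: ResidueTemplate,
                       chi: Sequence[float] | None = None) -> MolecularSystem:
    """Replace the side chain of residue (chain, seq) with ``template``.

    Backbone atoms (N, CA, C, O) keep their names and coordinates; all other
    atoms of the residue are removed and the template side chain is rebuilt
    from internal coordinates, χ angles at their first staggered value unless
    given.  Peptide-bond constraints to sequence neighbours in the same chain
    are regenerated as special constraints.  Only the addressed residue
    changes; residue count, chain count and every other atom are untouched.
    """
    ridx = system.find_residue(chain, seq)
    site_atoms = system.residue_atoms(ridx)
    backbone: dict[str, np.ndarray] = {}
    for i in site_atoms:
        if system.atom_names[i] in BACKBONE_ATOMS:
            backbone[system.atom_names[i]] = system.coords[i].copy()
    for req in ("N", "CA", "C", "O"):
        if req not in backbone:
            raise IncompleteBackboneError(
                f"residue {chain}:{seq} lacks backbone atom {req}")

    placed = build_sidechain(template, backbone, chi)
    keep_mask = np.ones(system.n_atoms, dtype=bool)
    for i in site_atoms:
        if system.atom_names[i] not in BACKBONE_ATOMS:
            keep_mask[i] = False

    tpl_names = [a[0] for a in template.atoms]
    tpl_info = {a[0]: a for a in template.atoms}
    # new atom layout: everything before the site, site backbone in template
    # order, then template side-chain atoms, then everything after
    new_names: list[str] = []
    new_elements: list[str] = []
    new_charges: list[int] = []
    new_coords: list[np.ndarray] = []
    new_resindex: list[int] = []
    old_to_new: dict[int, int] = {}

    def _emit(name, element, charge, xyz, ridx_):
        new_names.append(name)
        new_elements.append(element)
        new_charges.append(charge)
        new_coords.append(np.asarray(xyz, dtype=float))
        new_resindex.append(ridx_)
        return len(new_names) - 1

    site_set = set(int(i) for i in site_atoms)
    site_backbone_idx = {system.atom_names[i]: int(i) for i in site_atoms
                         if system.atom_names[i] in BACKBONE_ATOMS}
    emitted_site = False
    for i in range(system.n_atoms):
        if int(system.residue_index[i]) == ridx:
            if not emitted_site:
                emitted_site = True
                for name in tpl_names:
                    _, element, charge = tpl_info[name]
                    if name in BACKBONE_ATOMS:
                        j = _emit(name, system.elements[site_backbone_idx[name]],
                                  charge, backbone[name], ridx)
                        old_to_new[site_backbone_idx[name]] = j
                    else:
                        _emit(name, element, charge, placed[name], ridx)
            continue
        j = _emit(system.atom_names[i], system.elements[i],
                  int(system.formal_charges[i]), system.coords[i],
                  int(system.residue_index[i]))
        old_to_new[i] = j

    name_to_new = {}
    for j, (nm, ri) in enumerate(zip(new_names, new_resindex)):
        if ri == ridx:
            name_to_new[nm] = j

    new_bonds: set[tuple[int, int]] = set()
    for a, b in system.bonds:
        if (a in site_set and a not in old_to_new) or \
           (b in site_set and b not in old_to_new):
            continue  # bond touched a removed side-chain atom
        na, nb = old_to_new[a], old_to_new[b]
        new_bonds.add((min(na, nb), max(na, nb)))
    for a_name, b_name in template.bonds:
        if a_name in name_to_new and b_name in name_to_new:
            na, nb = name_to_new[a_name], name_to_new[b_name]
            if na != nb:
                new_bonds.add((min(na, nb), max(na, nb)))

    new_special: list[tuple[str, int, int]] = []
    for kind, a, b in system.special_constraints:
        if a in old_to_new and b in old_to_new:
            new_special.append((kind, old_to_new[a], old_to_new[b]))

    new_residues = [replace(r) for r in system.residues]
    new_residues[ridx] = Residue(template.name, chain, seq)

    result = MolecularSystem(
        atom_names=new_names,
        elements=new_elements,
        formal_charges=np.array(new_charges, dtype=int),
        masses=np.array([ELEMENT_MASSES.get(e, ELEMENT_MASSES["X"])
                         for e in new_elements]),
        coords=np.vstack(new_coords),
        residue_index=np.array(new_resindex, dtype=int),
        residues=new_residues,
        bonds=sorted(new_bonds),
        special_constraints=new_special,
    )

    # regenerated peptide links to sequence neighbours in the same chain
    for nb_seq, (c_name, n_name) in ((seq - 1, ("C", "N")), (seq + 1, ("N", "C"))):
        try:
            nb = result.find_residue(chain, nb_seq)
        except ResidueNotFoundError:
            continue
        this_atom = result.atom_index(ridx, "N" if nb_seq == seq - 1 else "C")
        nb_atom = result.atom_index(nb, "C" if nb_seq == seq - 1 else "N")
        if this_atom is not None and nb_atom is not None:
            pair = ("peptide", min(this_atom, nb_atom), max(this_atom, nb_atom))
            if pair not in result.special_constraints:
                result.special_constraints.append(pair)
            bond = (min(this_atom, nb_atom), max(this_atom, nb_atom))
            if bond not in result.bonds:
                result.bonds.append(bond)
                result.bonds.sort()
    result.validate()
    return result
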