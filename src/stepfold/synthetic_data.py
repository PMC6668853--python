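"""Synthetic systems: every input the pipeline needs, generated in code.

Three families:

* an analytic two-level system with an exactly known partition function —
  the oracle for WHAM and specific-heat code;
* coarse-grained Gō-model peptides (one bead per residue, two fold
  templates) whose melting temperature is tunable through the native well
  depth ε — the desk-scale folding workhorse;
* "modified" variants of a Gō peptide with one bulkier, charge-carrying
  bead and weakened native wells — emulating the destabilization of a
  protein by misincorporation of a non-canonical residue (higher low-T
  potential energy, lower melting temperature, locally increased
  flexibility);

plus small all-atom peptide fixtures built from residue templates, used by
the repacking ΔΔG machinery.

All generators are deterministic under a fixed seed and can emit their
output as PDB-format fixtures so the file-based pipeline is exercisable
end-to-end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from . import model_io
from .forcefield import (GO_WELL_OUTER, InteractionTable, StepPotential,
                         build_go_model, native_contacts)
from .model_io import (ELEMENT_MASSES, MolecularSystem, Residue,
                       ResidueTemplate, build_sidechain, place_atom)

__all__ = [
    "TwoStateSystem",
    "GoPeptide",
    "make_two_state",
    "make_harmonic_pair",
    "make_go_peptide",
    "make_modified_variant",
    "build_peptide",
    "make_packed_core_fixture",
    "bulky_charged_template",
    "small_charged_template",
    "write_go_fixture",
]


# ---------------------------------------------------------------------------
# analytic two-level system
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateSystem:
    """Two energy levels with degeneracies; all thermodynamics closed-form.

    k_B = 1: Z(T) = g0 e^(-E0/T) + g1 e^(-E1/T).
    """

    E0: float
    E1: float
    g0: int
    g1: int

    def __post_init__(self):
        if self.g0 < 1 or self.g1 < 1:
            raise ValueError("degeneracies must be >= 1")
        if self.E1 <= self.E0:
            raise ValueError("E1 must exceed E0")

    def excited_probability(self, T: float) -> float:
        dE = self.E1 - self.E0
        w = self.g1 * math.exp(-dE / T)
        return w / (self.g0 + w)

    def partition_function(self, T: float) -> float:
        return (self.g0 * math.exp(-self.E0 / T)
                + self.g1 * math.exp(-self.E1 / T))

    def mean_energy(self, T: float) -> float:
        p1 = self.excited_probability(T)
        return self.E0 + p1 * (self.E1 - self.E0)

    def cv(self, T) -> np.ndarray | float:
        """Schottky specific heat, k_B units."""
        T = np.asarray(T, dtype=float)
        dE = self.E1 - self.E0
        w = self.g1 * np.exp(-dE / T)
        p1 = w / (self.g0 + w)
        out = dE * dE * p1 * (1.0 - p1) / (T * T)
        return float(out) if out.ndim == 0 else out

    def cv_peak(self, bracket=(1e-3, 50.0)) -> tuple[float, float]:
        """Temperature and height of the Schottky C_V maximum (numerical
        maximization of the closed form)."""
        dE = self.E1 - self.E0
        res = minimize_scalar(lambda T: -self.cv(T),
                              bounds=(bracket[0] * dE, bracket[1] * dE),
                              method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x), float(-res.fun)


def make_two_state(E0: float, E1: float, g0: int, g1: int):
    """Return ``(TwoStateSystem, sampler)`` where ``sampler(T, n, seed)``
    draws level energies i.i.d. from the exact Boltzmann distribution."""
    system = TwoStateSystem(E0=E0, E1=E1, g0=g0, g1=g1)

    def sampler(T: float, n: int, seed: int) -> np.ndarray:
        if T <= 0:
            raise ValueError("temperature must be positive")
        rng = np.random.default_rng(seed)
        p1 = system.excited_probability(T)
        excited = rng.random(n) < p1
        return np.where(excited, system.E1, system.E0).astype(float)

    return system, sampler


# ---------------------------------------------------------------------------
# Gō peptides
# ---------------------------------------------------------------------------

GO_BOND_LENGTH = 3.8       # Å, Cα virtual bond
GO_DEFAULT_EPS = 0.6       # kcal/mol native well depth (melts mid-ladder)
GO_DEFAULT_CUTOFF = 7.5    # Å native-contact cutoff
GO_DEFAULT_RADIUS = 2.0    # Å bead hard radius
GO_BEAD_MASS = ELEMENT_MASSES["C"]

FOLD_TEMPLATES = ("hairpin", "helix")


@dataclass
class GoPeptide:
    """One-bead-per-residue chain with an annotated native contact map."""

    positions: np.ndarray            # (n, 3) Å, native structure
    radii: np.ndarray                # per-bead hard radii, Å
    masses: np.ndarray               # amu
    contacts: list[tuple[int, int]]  # |i-j| >= 3 native pairs
    eps: float                       # kcal/mol well depth
    fold: str
    seed: int
    cutoff: float = GO_DEFAULT_CUTOFF
    modified_site: tuple[int, float, float] | None = None  # (index, Δr, Δε)

    @property
    def n_residues(self) -> int:
        return len(self.positions)

    def to_system(self) -> MolecularSystem:
        n = self.n_residues
        names = ["CA"] * n
        elements = ["C"] * n
        charges = np.zeros(n, dtype=int)
        residues = [Residue("ALA", "A", i + 1) for i in range(n)]
        if self.modified_site is not None:
            site = self.modified_site[0]
            residues[site] = Residue("MOD", "A", site + 1)
            charges[site] = 1
        sys_ = MolecularSystem(
            atom_names=names, elements=elements, formal_charges=charges,
            masses=self.masses.copy(), coords=self.positions.copy(),
            residue_index=np.arange(n), residues=residues,
            bonds=[(i, i + 1) for i in range(n - 1)])
        sys_.validate()
        return sys_

    def interaction_table(self) -> InteractionTable:
        table = build_go_model(self.to_system(), cutoff=self.cutoff,
                               eps=self.eps,
                               bead_radius=float(self.radii[0]))
        table.hard_radii = self.radii.copy()
        if self.modified_site is not None:
            site, d_radius, d_eps = self.modified_site
            table.hard_radii[site] += d_radius
            for (i, j), pot in list(table.pair_overrides.items()):
                if site in (i, j) and pot.energies:
                    hc = float(table.hard_radii[i] + table.hard_radii[j])
                    inner = max(pot.radii[0], hc)
                    outer = pot.radii[-1]
                    if inner >= outer:
                        inner = 0.95 * outer
                    depth = pot.energies[0] * (1.0 - d_eps)
                    table.pair_overrides[(i, j)] = StepPotential(
                        radii=(inner, outer), energies=(depth,))
        return table

    def contact_degree(self, site: int) -> int:
        return sum(1 for i, j in self.contacts if site in (i, j))


def _helix_coords(n: int) -> np.ndarray:
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    k = np.arange(n)
    return np.stack([radius * np.cos(twist * k),
                     radius * np.sin(twist * k),
                     rise * k], axis=1)


def _hairpin_coords(n: int) -> np.ndarray:
    half = n // 2
    spacing, sep, zig = 3.4, 4.8, 0.8
    coords = np.zeros((n, 3))
    for i in range(half):
        coords[i] = (spacing * i, 0.0, zig * (i % 2))
    for i in range(half, n):
        coords[i] = (spacing * (n - 1 - i), sep, zig * ((i + 1) % 2))
    return coords


def make_go_peptide(n_residues: int = 20, fold: str = "hairpin",
                    eps: float = GO_DEFAULT_EPS, seed: int = 0, *,
                    cutoff: float = GO_DEFAULT_CUTOFF,
                    bead_radius: float = GO_DEFAULT_RADIUS,
                    jitter: float = 0.05):
    """Build a foldable Gō peptide.

    Returns ``(GoPeptide, MolecularSystem, InteractionTable)``.  The native
    structure is a compact self-avoiding conformation from one of two fold
    templates ("hairpin", "helix"); a small seeded jitter breaks lattice
    degeneracies.  The approximate melting temperature grows with ``eps``.
    If a jitter draw creates an overlap the generator retries with an offset
    seed (logged as a warning).
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    if fold not in FOLD_TEMPLATES:
        raise ValueError(f"unknown fold template {fold!r}; "
                         f"choose from {FOLD_TEMPLATES}")
    base = _helix_coords(n_residues) if fold == "helix" \
        else _hairpin_coords(n_residues)
    hard = 2.0 * bead_radius
    for attempt in range(10):
        use_seed = seed + 1000 * attempt
        rng = np.random.default_rng(use_seed)
        coords = base + rng.normal(scale=jitter, size=base.shape)
        ok = True
        for i in range(n_residues):
            for j in range(i + 2, n_residues):
                if np.linalg.norm(coords[i] - coords[j]) <= hard + 0.05:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            if attempt > 0:
                warnings.warn(f"regenerated geometry with seed offset "
                              f"{1000 * attempt}", stacklevel=2)
            break
    else:
        raise RuntimeError("could not build an overlap-free geometry")

    contacts = []
    for i in range(n_residues):
        for j in range(i + 3, n_residues):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                contacts.append((i, j))
    peptide = GoPeptide(
        positions=coords, radii=np.full(n_residues, bead_radius),
        masses=np.full(n_residues, GO_BEAD_MASS), contacts=contacts,
        eps=eps, fold=fold, seed=seed, cutoff=cutoff)
    system = peptide.to_system()
    table = peptide.interaction_table()
    assert sorted(native_contacts(table)) == sorted(contacts)
    return peptide, system, table


def default_modified_site(peptide: GoPeptide) -> int:
    """Default substitution site: among beads with the maximum native-contact
    degree, the one nearest the quarter-chain position (a strand-core bead,
    away from the floppy termini and turn)."""
    degrees = [peptide.contact_degree(i) for i in range(peptide.n_residues)]
    dmax = max(degrees)
    anchor = peptide.n_residues // 4
    candidates = [i for i, d in enumerate(degrees) if d == dmax]
    return min(candidates, key=lambda i: (abs(i - anchor), i))


def make_modified_variant(peptide: GoPeptide, site: int,
                          delta_radius: float = 0.3,
                          delta_eps: float = 0.9) -> GoPeptide:
    """Destabilized variant: the site bead swells by ``delta_radius`` Å,
    carries a formal charge, and every native well involving the site is
    shallowed by the factor ``1 - delta_eps``.  Nothing else changes."""
    if not 0 <= site < peptide.n_residues:
        raise ValueError(f"site {site} outside the chain")
    if not 0.0 <= delta_eps < 1.0:
        raise ValueError("delta_eps must lie in [0, 1)")
    if delta_radius < 0:
        raise ValueError("delta_radius must be non-negative")
    return replace(peptide, modified_site=(site, delta_radius, delta_eps),
                   positions=peptide.positions.copy(),
                   radii=peptide.radii.copy(), masses=peptide.masses.copy(),
                   contacts=list(peptide.contacts))


def write_go_fixture(peptide: GoPeptide, directory) -> dict[str, Path]:
    """Emit the peptide as PDB + interaction-table text fixtures."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = "variant" if peptide.modified_site is not None else "wt"
    pdb_path = directory / f"go_{peptide.fold}_{tag}.pdb"
    table_path = directory / f"go_{peptide.fold}_{tag}_table.txt"
    model_io.write_pdb(peptide.to_system(), pdb_path)
    table_path.write_text(peptide.interaction_table().to_text())
    return {"pdb": pdb_path, "table": table_path}


def make_harmonic_pair(k: float = 5.0, r0: float = 3.8,
                       half_width: float = 0.8, n_steps: int = 8):
    """Two bonded beads in a discretized harmonic well — the fast-mixing
    toy for thermostat and replica-exchange stationarity checks.

    The pair potential is k (r - r0)^2 discretized into ``n_steps`` shells
    over [r0 - half_width, r0 + half_width] with infinite outer walls, so
    the potential energy takes a handful of discrete levels with exactly
    known Boltzmann weights.  Returns ``(MolecularSystem, InteractionTable)``.
    """
    edges = np.linspace(r0 - half_width, r0 + half_width, n_steps + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    pot = StepPotential(radii=tuple(edges),
                        energies=tuple(k * (mids - r0) ** 2), bounded=True)
    system = MolecularSystem(
        atom_names=["CA", "CA"], elements=["C", "C"],
        formal_charges=np.zeros(2, dtype=int),
        masses=np.full(2, ELEMENT_MASSES["C"]),
        coords=np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]),
        residue_index=np.arange(2),
        residues=[Residue("ALA", "A", 1), Residue("ALA", "A", 2)],
        bonds=[(0, 1)])
    table = InteractionTable(n_atoms=2, atom_types=["C", "C"],
                             pair_overrides={(0, 1): pot})
    return system, table


# ---------------------------------------------------------------------------
# all-atom peptide fixtures
# ---------------------------------------------------------------------------

_BB_GEOM = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "ang_N_CA_C": 111.0, "ang_CA_C_N": 116.6, "ang_C_N_CA": 121.7,
    "ang_CA_C_O": 120.5,
}


def build_peptide(template_names: list[str | ResidueTemplate],
                  phi: float = -120.0, psi: float = 130.0,
                  chain: str = "A") -> MolecularSystem:
    """Assemble a small all-atom peptide from residue templates with uniform
    backbone torsions (default extended-like φ/ψ) and side-chain χ at the
    first staggered value."""
    templates = [t if isinstance(t, ResidueTemplate) else
                 model_io.builtin_template(t) for t in template_names]
    g = _BB_GEOM
    names, elements, charges, coords, resindex = [], [], [], [], []
    residues = []
    bonds: list[tuple[int, int]] = []
    index_of: dict[tuple[int, str], int] = {}

    def emit(ridx, name, element, charge, xyz):
        idx = len(names)
        names.append(name)
        elements.append(element)
        charges.append(charge)
        coords.append(np.asarray(xyz, dtype=float))
        resindex.append(ridx)
        index_of[(ridx, name)] = idx
        return idx

    prev = None  # (N, CA, C) coordinates of previous residue
    for ridx, tpl in enumerate(templates):
        if prev is None:
            N = np.zeros(3)
            CA = np.array([g["N_CA"], 0.0, 0.0])
            th = math.radians(180.0 - g["ang_N_CA_C"])
            C = CA + g["CA_C"] * np.array([math.cos(th), math.sin(th), 0.0])
        else:
            pN, pCA, pC = prev
            N = place_atom(pN, pCA, pC, g["C_N"], g["ang_CA_C_N"], psi)
            CA = place_atom(pCA, pC, N, g["N_CA"], g["ang_C_N_CA"], 180.0)
            C = place_atom(pC, N, CA, g["CA_C"], g["ang_N_CA_C"], phi)
        O = place_atom(N, CA, C, g["C_O"], g["ang_CA_C_O"], psi + 180.0)
        backbone = {"N": N, "CA": CA, "C": C, "O": O}
        placed = build_sidechain(tpl, backbone)
        tpl_info = {a[0]: a for a in tpl.atoms}
        residues.append(Residue(tpl.name, chain, ridx + 1))
        for name in [a[0] for a in tpl.atoms]:
            _, element, charge = tpl_info[name]
            emit(ridx, name, element, charge, placed[name])
        for a, b in tpl.bonds:
            ia, ib = index_of[(ridx, a)], index_of[(ridx, b)]
            bonds.append((min(ia, ib), max(ia, ib)))
        if prev is not None:
            ia = index_of[(ridx - 1, "C")]
            ib = index_of[(ridx, "N")]
            bonds.append((min(ia, ib), max(ia, ib)))
        prev = (N, CA, C)

    system = MolecularSystem(
        atom_names=names, elements=elements,
        formal_charges=np.array(charges, dtype=int),
        masses=np.array([ELEMENT_MASSES.get(e, ELEMENT_MASSES["X"])
                         for e in elements]),
        coords=np.vstack(coords),
        residue_index=np.array(resindex, dtype=int),
        residues=residues, bonds=sorted(set(bonds)))
    system.validate()
    return system


def bulky_charged_template() -> ResidueTemplate:
    """Toy 'bulky + charged' target: a branched two-atom side-chain head
    carrying +1 — sterically demanding in a packed core."""
    text = """
name BLK
net_charge 1
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
CB C 0
NG N 1
CG C 0
[bonds]
N CA
CA C
C O
CA CB
CB NG
CB CG
[chi]
N CA CB NG
[internal]
CB CA N C  1.530 110.5 -122.6
NG CB CA N 1.490 109.5 chi1
CG CB CA NG 1.520 109.5 120.0
"""
    return model_io.load_template(text)


def small_charged_template() -> ResidueTemplate:
    """Toy 'conservative' target: a single charged side-chain atom in
    serine's footprint."""
    text = """
name SML
net_charge 1
[atoms]
N  N 0
CA C 0
C  C 0
O  O 0
CB N 1
[bonds]
N CA
CA C
C O
CA CB
[chi]
[internal]
CB CA N C 1.530 110.5 -122.6
"""
    return model_io.load_template(text)


def make_packed_core_fixture(blocked_rotamers=(60.0, 180.0),
                             standoff: float = 2.5) -> MolecularSystem:
    """GLY-SER-GLY peptide with fixed obstacle atoms crowding the serine
    side-chain pocket.

    One obstacle sits ``standoff`` Å beyond the serine Oγ position of each
    χ1 rotamer in ``blocked_rotamers`` (default +60° and 180°), leaving the
    -60° channel open.  A single-arm side chain escapes through the open
    channel, but a head branched at ~120° (two atoms on the Cβ) cannot
    orient both arms away from the obstacles — the geometry that makes a
    bulky substitution strongly destabilizing while a conservative one is
    nearly neutral.
    """
    system = build_peptide(["GLY", "SER", "GLY"])
    ridx = system.find_residue("A", 2)
    ser = model_io.builtin_template("SER")
    backbone = {nm: system.coords[system.atom_index(ridx, nm)]
                for nm in ("N", "CA", "C", "O")}
    cb = system.coords[system.atom_index(ridx, "CB")]

    names = list(system.atom_names)
    elements = list(system.elements)
    charges = list(system.formal_charges)
    coords = [c for c in system.coords]
    resindex = list(system.residue_index)
    residues = list(system.residues)
    obs_ridx = len(residues)
    residues.append(Residue("OBS", "B", 1))
    for k, chi1 in enumerate(blocked_rotamers):
        og = build_sidechain(ser, backbone, chi=[chi1])["OG"]
        direction = og - cb
        direction /= np.linalg.norm(direction)
        pos = og + standoff * direction
        names.append(f"X{k + 1}")
        elements.append("C")
        charges.append(0)
        coords.append(pos)
        resindex.append(obs_ridx)

    out = MolecularSystem(
        atom_names=names, elements=elements,
        formal_charges=np.array(charges, dtype=int),
        masses=np.array([ELEMENT_MASSES.get(e, ELEMENT_MASSES["X"])
                         for e in elements]),
        coords=np.vstack(coords),
        residue_index=np.array(resindex, dtype=int),
        residues=residues, bonds=list(system.bonds))
    out.validate()
    return out
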