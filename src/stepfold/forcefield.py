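"""Discretized step-function force field.

Everything the event-driven engine consumes is expressed as a
:class:`StepPotential`: a hard inner wall, a ladder of constant-energy
shells, and zero energy beyond the outermost radius.  Bonded terms (bond
lengths, 1-3 angle distances, 1-4 dihedral distances, disulfide/metal/
peptide links) are *bounded* wells — infinite walls on both sides.
Continuous potentials (Lennard-Jones, or an implicit-solvation profile
supplied as samples) are discretized into multi-step square wells.

A Gō model over a single-bead-per-residue chain serves as the desk-scale
folding surrogate: native contacts get a finite attractive well around
their native distance, everything else is hard-sphere repulsion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model_io import MolecularSystem

__all__ = [
    "StepPotential",
    "Constraint",
    "InteractionTable",
    "discretize_potential",
    "bonded_constraints",
    "build_go_model",
    "lennard_jones",
    "hard_sphere",
    "compute_energy",
]

#: van-der-Waals radii (Å) used for default hard cores
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "CU": 1.40, "ZN": 1.39, "FE": 1.40, "X": 1.70,
}

HARD_CORE_SCALE = 0.8  # default hard-core radius = 0.8 x sum of vdW radii

DEFAULT_BOND_TOL = 0.02
DEFAULT_ANGLE13_TOL = 0.05
DEFAULT_DIHEDRAL14_TOL = 0.10


@dataclass(frozen=True)
class StepPotential:
    """Piecewise-constant pair potential.

    ``radii`` are strictly increasing (Å).  ``energies[k]`` is the energy
    (kcal/mol) for ``radii[k] < r < radii[k+1]``; the region inside
    ``radii[0]`` is an infinite hard core, and the energy beyond
    ``radii[-1]`` is exactly 0 — unless ``bounded``, in which case the
    outermost radius is itself an infinite wall (a constraint well).
    """

    radii: tuple[float, ...]
    energies: tuple[float, ...] = ()
    bounded: bool = False

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or len(r) < 1:
            raise ValueError("need at least one radius")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if len(self.energies) != len(self.radii) - 1:
            raise ValueError("need exactly len(radii)-1 shell energies")
        if not all(math.isfinite(e) for e in self.energies):
            raise ValueError("shell energies must be finite")
        if self.bounded and len(self.radii) < 2:
            raise ValueError("bounded well needs inner and outer radius")

    def energy_at(self, r: float) -> float:
        if r < self.radii[0]:
            return math.inf
        if r >= self.radii[-1]:
            return math.inf if self.bounded else 0.0
        k = int(np.searchsorted(np.asarray(self.radii), r, side="right")) - 1
        return float(self.energies[k])

    @property
    def r_cut(self) -> float:
        return self.radii[-1]


def hard_sphere(radius: float) -> StepPotential:
    return StepPotential(radii=(float(radius),))


def square_well(r_inner: float, r_outer: float, depth: float,
                bounded: bool = False) -> StepPotential:
    return StepPotential(radii=(float(r_inner), float(r_outer)),
                         energies=(float(depth),), bounded=bounded)


@dataclass(frozen=True)
class Constraint:
    """Infinite square well [rmin, rmax] on one atom pair."""

    i: int
    j: int
    rmin: float
    rmax: float
    kind: str  # bond | angle13 | dihedral14 | disulfide | metal | peptide

    def as_potential(self) -> StepPotential:
        return StepPotential(radii=(self.rmin, self.rmax), energies=(0.0,),
                             bounded=True)


def lennard_jones(eps: float, sigma: float):
    """Continuous 12-6 Lennard-Jones, for discretization and tests."""
    def U(r):
        sr6 = (sigma / np.asarray(r, dtype=float)) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)
    return U


def discretize_potential(samples: Sequence[tuple[float, float]], n_steps: int,
                         r_cut: float, *, cap: float = 100.0) -> StepPotential:
    """Discretize a sampled continuous potential into ``n_steps`` equal-width
    shells between the hard core and ``r_cut``.

    The hard core sits at the first sampled radius where U drops to or below
    ``cap`` (default 100 kcal/mol); each shell's energy is the mean of the
    (linearly interpolated) continuous potential over the shell; the energy
    beyond ``r_cut`` is forced to 0.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rs = np.asarray([s[0] for s in samples], dtype=float)
    us = np.asarray([s[1] for s in samples], dtype=float)
    if len(rs) < 2:
        raise ValueError("need at least two samples")
    if np.any(np.diff(rs) <= 0):
        raise ValueError("samples must be sorted by increasing r")
    if r_cut > rs[-1] + 1e-12:
        raise ValueError("r_cut exceeds the sampled range")

    below = np.where(us <= cap)[0]
    if len(below) == 0:
        raise ValueError(f"potential never drops below the cap ({cap})")
    hard_core = float(rs[below[0]])
    if hard_core >= r_cut:
        raise ValueError("hard core at or beyond r_cut")

    edges = np.linspace(hard_core, r_cut, n_steps + 1)
    energies = []
    for k in range(n_steps):
        grid = np.linspace(edges[k], edges[k + 1], 64)
        energies.append(float(np.mean(np.interp(grid, rs, us))))
    return StepPotential(radii=tuple(edges), energies=tuple(energies))


# ---------------------------------------------------------------------------
# bonded constraints
# ---------------------------------------------------------------------------

def _bond_graph(n: int, bonds: Iterable[tuple[int, int]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def topology_pairs(n: int, bonds: Iterable[tuple[int, int]]):
    """Return (1-2, 1-3, 1-4) pair sets from a bond list."""
    adj = _bond_graph(n, bonds)
    p12 = {(min(a, b), max(a, b)) for a in range(n) for b in adj[a] if a < b}
    p13, p14 = set(), set()
    for a in range(n):
        for b in adj[a]:
            for c in adj[b]:
                if c != a:
                    key = (min(a, c), max(a, c))
                    if key not in p12:
                        p13.add(key)
                for d in adj[c]:
                    if d not in (a, b):
                        key = (min(a, d), max(a, d))
                        if key not in p12 and a != d:
                            p14.add(key)
    p13 -= p12
    p14 -= p12 | p13
    return p12, p13, p14


def bonded_constraints(system: MolecularSystem, tol: float = DEFAULT_BOND_TOL,
                       angle_tol: float = DEFAULT_ANGLE13_TOL,
                       dihedral_tol: float = DEFAULT_DIHEDRAL14_TOL,
                       include_dihedrals: bool = True) -> list[Constraint]:
    """Infinite square wells around the current 1-2, 1-3 and 1-4 distances,
    plus type-labelled wells for the system's special constraints
    (disulfide, metal, peptide)."""
    if not 0 < tol < 0.5:
        raise ValueError("tol must be in (0, 0.5)")
    if not system.bonds:
        raise ValueError("system has no bonds")
    p12, p13, p14 = topology_pairs(system.n_atoms, system.bonds)
    out: list[Constraint] = []

    def d(i, j):
        return float(np.linalg.norm(system.coords[i] - system.coords[j]))

    special_pairs = {(min(a, b), max(a, b)) for _, a, b in system.special_constraints}
    for i, j in sorted(p12):
        dist = d(i, j)
        out.append(Constraint(i, j, dist * (1 - tol), dist * (1 + tol), "bond"))
    for i, j in sorted(p13):
        if (i, j) in special_pairs:
            continue
        dist = d(i, j)
        out.append(Constraint(i, j, dist * (1 - angle_tol),
                              dist * (1 + angle_tol), "angle13"))
    if include_dihedrals:
        for i, j in sorted(p14):
            if (i, j) in special_pairs:
                continue
            dist = d(i, j)
            out.append(Constraint(i, j, dist * (1 - dihedral_tol),
                                  dist * (1 + dihedral_tol), "dihedral14"))
    for kind, a, b in system.special_constraints:
        i, j = min(a, b), max(a, b)
        if any(c.i == i and c.j == j for c in out):
            continue
        dist = d(i, j)
        out.append(Constraint(i, j, dist * (1 - tol), dist * (1 + tol), kind))
    return out


# ---------------------------------------------------------------------------
# interaction table
# ---------------------------------------------------------------------------

@dataclass
class InteractionTable:
    """Complete pairwise energy assignment for one system.

    ``constraints`` are bounded wells; ``pair_overrides`` map specific atom
    index pairs to step potentials (how Gō native contacts are stored);
    ``type_potentials`` map unordered atom-type pairs; any remaining
    non-excluded pair falls back to a hard sphere of radius
    ``HARD_CORE_SCALE x (vdW_i + vdW_j)`` (per-atom radii overridable via
    ``hard_radii``).
    """

    n_atoms: int
    atom_types: list[str]
    constraints: list[Constraint] = field(default_factory=list)
    pair_overrides: dict[tuple[int, int], StepPotential] = field(default_factory=dict)
    type_potentials: dict[tuple[str, str], StepPotential] = field(default_factory=dict)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    hard_radii: np.ndarray | None = None

    def __post_init__(self):
        cpairs = set()
        for c in self.constraints:
            if not c.rmin < c.rmax:
                raise ValueError(f"constraint {c.kind} ({c.i},{c.j}): min >= max")
            cpairs.add((min(c.i, c.j), max(c.i, c.j)))
        for p in self.pair_overrides:
            if p in cpairs:
                raise ValueError(f"pair {p} is both bonded constraint and nonbonded")

    def _default_radius(self, i: int, j: int) -> float:
        if self.hard_radii is not None:
            return float(self.hard_radii[i] + self.hard_radii[j])
        ri = VDW_RADII.get(self.atom_types[i], VDW_RADII["X"])
        rj = VDW_RADII.get(self.atom_types[j], VDW_RADII["X"])
        return HARD_CORE_SCALE * (ri + rj)

    def pair_potential(self, i: int, j: int) -> StepPotential | None:
        """The step potential governing pair (i, j); None if excluded or
        covered by a bonded constraint."""
        key = (min(i, j), max(i, j))
        if key in self.exclusions:
            return None
        for c in self.constraints:
            if (min(c.i, c.j), max(c.i, c.j)) == key:
                return None
        if key in self.pair_overrides:
            return self.pair_overrides[key]
        tkey = tuple(sorted((self.atom_types[i], self.atom_types[j])))
        if tkey in self.type_potentials:
            return self.type_potentials[tkey]
        return hard_sphere(self._default_radius(i, j))

    def compile(self) -> list[tuple[int, int, StepPotential]]:
        """All governing potentials, one entry per interacting pair
        (constraints included as bounded wells)."""
        cmap = {}
        for c in self.constraints:
            cmap[(min(c.i, c.j), max(c.i, c.j))] = c.as_potential()
        out = []
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                key = (i, j)
                if key in self.exclusions:
                    continue
                pot = cmap.get(key)
                if pot is None:
                    pot = self.pair_potential(i, j)
                if pot is not None:
                    out.append((i, j, pot))
        return out

    # -- plain-text serialization ------------------------------------------
    def to_text(self) -> str:
        lines = [f"natoms {self.n_atoms}",
                 "types " + " ".join(self.atom_types)]
        if self.hard_radii is not None:
            lines.append("hard_radii " + " ".join(f"{r:.6g}" for r in self.hard_radii))
        for c in self.constraints:
            lines.append(f"constraint {c.kind} {c.i} {c.j} {c.rmin:.6f} {c.rmax:.6f}")
        for (i, j), p in sorted(self.pair_overrides.items()):
            lines.append(
                f"pair {i} {j} {int(p.bounded)} "
                + " ".join(f"{r:.6f}" for r in p.radii) + " : "
                + " ".join(f"{e:.6f}" for e in p.energies))
        for (a, b), p in sorted(self.type_potentials.items()):
            lines.append(
                f"typepair {a} {b} {int(p.bounded)} "
                + " ".join(f"{r:.6f}" for r in p.radii) + " : "
                + " ".join(f"{e:.6f}" for e in p.energies))
        for i, j in sorted(self.exclusions):
            lines.append(f"exclude {i} {j}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "InteractionTable":
        n_atoms = 0
        atom_types: list[str] = []
        hard_radii = None
        constraints, overrides, typepots, excl = [], {}, {}, set()
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "natoms":
                n_atoms = int(parts[1])
            elif tag == "types":
                atom_types = parts[1:]
            elif tag == "hard_radii":
                hard_radii = np.array([float(x) for x in parts[1:]])
            elif tag == "constraint":
                constraints.append(Constraint(int(parts[2]), int(parts[3]),
                                              float(parts[4]), float(parts[5]),
                                              parts[1]))
            elif tag in ("pair", "typepair"):
                sep = parts.index(":")
                bounded = bool(int(parts[3]))
                radii = tuple(float(x) for x in parts[4:sep])
                energies = tuple(float(x) for x in parts[sep + 1:])
                pot = StepPotential(radii=radii, energies=energies, bounded=bounded)
                if tag == "pair":
                    overrides[(int(parts[1]), int(parts[2]))] = pot
                else:
                    typepots[(parts[1], parts[2])] = pot
            elif tag == "exclude":
                excl.add((int(parts[1]), int(parts[2])))
        return cls(n_atoms=n_atoms, atom_types=atom_types,
                   constraints=constraints, pair_overrides=overrides,
                   type_potentials=typepots, exclusions=excl,
                   hard_radii=hard_radii)


def compute_energy(coords: np.ndarray, table: InteractionTable) -> float:
    """Total step-potential energy of a configuration (inf on any hard-core
    or constraint violation)."""
    total = 0.0
    for i, j, pot in table.compile():
        r = float(np.linalg.norm(coords[i] - coords[j]))
        e = pot.energy_at(r)
        if math.isinf(e):
            return math.inf
        total += e
    return total


# ---------------------------------------------------------------------------
# Gō model
# ---------------------------------------------------------------------------

GO_WELL_INNER = 0.9   # inner wall of a native well, fraction of native distance
GO_WELL_OUTER = 1.1   # outer edge of a native well
GO_BEAD_RADIUS = 2.0  # Å, default bead hard radius (hard core = 4 Å per pair)
GO_ANGLE_TOL = 0.25   # 1-3 well tolerance when angle wells are requested


def build_go_model(system: MolecularSystem, cutoff: float = 7.5,
                   eps: float = 0.6, *, bead_radius: float = GO_BEAD_RADIUS,
                   bond_tol: float = DEFAULT_BOND_TOL,
                   include_angles: bool = False,
                   angle_tol: float = GO_ANGLE_TOL) -> InteractionTable:
    """Native-contact (Gō) interaction table for a one-bead-per-residue chain.

    Residue pairs with |i-j| >= 3 whose beads sit within ``cutoff`` Å in the
    reference structure receive a square well of depth ``-eps`` spanning
    [0.9, 1.1] x native distance; every other non-bonded pair is a pure hard
    sphere of radius ``2 x bead_radius``.  Chain connectivity enters as bond
    wells only by default — 1-3 (and especially 1-4) distance wells would
    drain the unfolded state's entropy and push the melting transition far
    above the working temperature window.
    """
    if cutoff <= 0 or eps <= 0:
        raise ValueError("cutoff and eps must be positive")
    n = system.n_atoms
    if system.n_residues < 4:
        raise ValueError("Gō model needs at least 4 residues")
    if n != system.n_residues:
        raise ValueError("expected a single-bead-per-residue chain "
                         "(reduce to the Cα trace first)")

    constraints = bonded_constraints(system, tol=bond_tol, angle_tol=angle_tol,
                                     include_dihedrals=False)
    if not include_angles:
        constraints = [c for c in constraints if c.kind != "angle13"]
    overrides: dict[tuple[int, int], StepPotential] = {}
    hc = 2.0 * bead_radius
    for i in range(n):
        for j in range(i + 3, n):
            d = float(np.linalg.norm(system.coords[i] - system.coords[j]))
            if d <= cutoff:
                inner = min(hc, GO_WELL_INNER * d)
                overrides[(i, j)] = square_well(inner, GO_WELL_OUTER * d, -eps)
    return InteractionTable(
        n_atoms=n,
        atom_types=[system.elements[i] for i in range(n)],
        constraints=constraints,
        pair_overrides=overrides,
        hard_radii=np.full(n, bead_radius),
    )


def native_contacts(table: InteractionTable) -> list[tuple[int, int]]:
    """Index pairs carrying an attractive native well."""
    return [p for p, pot in table.pair_overrides.items()
            if pot.energies and min(pot.energies) < 0]
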