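"""Event-driven discrete molecular dynamics over step potentials.

Between events every particle moves ballistically; an *event* is the instant
a pair reaches a discontinuity of its step potential (a hard wall or a shell
edge).  At an event the pair receives an impulse along the line of centers:
it crosses the step when the radial kinetic energy in the pair frame exceeds
the step height (total energy conserved exactly), and reflects elastically
otherwise.  An Andersen-style thermostat redraws one particle's velocity
from the Maxwell-Boltzmann distribution at Poisson-distributed times.

Reduced units throughout: length Å, energy kcal/mol, mass amu, k_B = 1
(temperature carries energy units).  One reduced time unit is
sqrt(amu Å² / (kcal/mol)) ≈ 48.9 fs.

The hot loop is compiled with numba over flat arrays; the module-level
helpers :func:`next_event_time` and :func:`resolve_step_crossing` are the
reference two-body computations the kernel applies pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .forcefield import InteractionTable
from .model_io import MolecularSystem

__all__ = [
    "SimState",
    "Trajectory",
    "InitializationError",
    "next_event_time",
    "resolve_step_crossing",
    "run_dmd",
    "maxwell_boltzmann_velocities",
    "write_energy_table",
    "write_trajectory_pdb",
]

_INF = 1.0e30
_EPS = 1.0e-12

#: reduced time unit in femtoseconds, sqrt(amu*Å^2/(kcal/mol))
TIME_UNIT_FS = 48.888


class InitializationError(RuntimeError):
    """Raised when the initial configuration violates a hard wall."""


@dataclass
class SimState:
    """Instantaneous state of one DMD simulation."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    clock: float
    potential_energy: float
    kinetic_energy: float
    seed: int

    @classmethod
    def make(cls, positions, velocities, masses, clock, potential_energy, seed):
        ke = 0.5 * float(np.sum(masses[:, None] * velocities ** 2))
        return cls(positions=positions, velocities=velocities, masses=masses,
                   clock=clock, potential_energy=potential_energy,
                   kinetic_energy=ke, seed=seed)


@dataclass
class Trajectory:
    """Time-stamped coordinate frames with per-frame energies."""

    times: np.ndarray                 # reduced time units, strictly increasing
    coords: np.ndarray                # (n_frames, n_atoms, 3) Å
    potential_energies: np.ndarray    # kcal/mol
    kinetic_energies: np.ndarray      # kcal/mol
    temperature: float                # reduced (kcal/mol per k_B)
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def __post_init__(self):
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")


# ---------------------------------------------------------------------------
# two-body reference computations
# ---------------------------------------------------------------------------

def next_event_time(rel_pos, rel_vel, wall_radius: float,
                    direction: str = "inward") -> float | None:
    """Earliest positive time at which |rel_pos + rel_vel t| = wall_radius.

    ``direction`` selects the crossing sense: "inward" (radius shrinking to
    the wall, i.e. the pair approaches an inner wall from outside) or
    "outward" (radius growing to the wall from inside).  Returns None when
    no such crossing happens.
    """
    if wall_radius <= 0:
        raise ValueError("wall_radius must be positive")
    dx = np.asarray(rel_pos, dtype=float)
    dv = np.asarray(rel_vel, dtype=float)
    a = float(dx @ dx) - wall_radius ** 2
    b = float(dv @ dv)
    c = float(dx @ dv)
    if b == 0.0:
        return None
    disc = c * c - b * a
    if direction == "inward":
        if c >= 0.0 or disc <= 0.0:
            return None
        t = (-c - math.sqrt(disc)) / b
    elif direction == "outward":
        if disc <= 0.0:
            return None
        t = (-c + math.sqrt(disc)) / b
    else:
        raise ValueError("direction must be 'inward' or 'outward'")
    return t if t > _EPS else None


def resolve_step_crossing(masses, rel_pos, velocities, dU: float,
                          tol: float = 1e-6):
    """Impulsive velocity update for a pair sitting exactly on a wall.

    Parameters
    ----------
    masses : (m_i, m_j) amu.
    rel_pos : x_i - x_j at the wall.
    velocities : (2, 3) array, rows v_i and v_j.
    dU : step height (kcal/mol) of the shell the pair is moving into.

    Returns ``(new_velocities, crossed)``.  Momentum is conserved exactly;
    when the radial kinetic energy in the pair frame exceeds ``dU`` the pair
    crosses (total energy conserved), otherwise it reflects elastically.
    """
    m_i, m_j = float(masses[0]), float(masses[1])
    dx = np.asarray(rel_pos, dtype=float)
    v = np.array(velocities, dtype=float)
    r = float(np.linalg.norm(dx))
    if r <= 0:
        raise RuntimeError("pair at zero separation")
    rhat = dx / r
    dv = v[0] - v[1]
    vr = float(dv @ rhat)
    mu = m_i * m_j / (m_i + m_j)
    if math.isinf(dU) or 0.5 * mu * vr * vr <= dU:
        impulse = -2.0 * mu * vr
        crossed = False
    else:
        vr_new = math.copysign(math.sqrt(vr * vr - 2.0 * dU / mu), vr)
        impulse = mu * (vr_new - vr)
        crossed = True
    v[0] += (impulse / m_i) * rhat
    v[1] -= (impulse / m_j) * rhat
    return v, crossed


# ---------------------------------------------------------------------------
# compiled event loop
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_index(i, j, n):  # i < j
    return i * n - (i * (i + 1)) // 2 + (j - i - 1)


@njit(cache=True, inline="always")
def _shell_energy(p, s, off, offe, energies, bounded):
    m = off[p + 1] - off[p]
    if s <= 0:
        return _INF
    if s <= m - 1:
        return energies[offe[p] + s - 1]
    if s == m and bounded[p] == 1:
        return _INF
    return 0.0


@njit(cache=True)
def _predict(p, i, j, pos, vel, off, radii2, bounded, shell):
    """Time to the next wall crossing for pair p; (-dt-or-INF, direction)."""
    m = off[p + 1] - off[p]
    if m == 0:
        return _INF, 0
    dxx = pos[i, 0] - pos[j, 0]
    dxy = pos[i, 1] - pos[j, 1]
    dxz = pos[i, 2] - pos[j, 2]
    dvx = vel[i, 0] - vel[j, 0]
    dvy = vel[i, 1] - vel[j, 1]
    dvz = vel[i, 2] - vel[j, 2]
    a = dxx * dxx + dxy * dxy + dxz * dxz
    b = dvx * dvx + dvy * dvy + dvz * dvz
    c = dxx * dvx + dxy * dvy + dxz * dvz
    if b <= 0.0:
        return _INF, 0
    s = shell[p]
    best_t = _INF
    best_dir = 0
    # inner wall (radius index s-1), approach requires c < 0
    if c < 0.0:
        r2 = radii2[off[p] + s - 1]
        disc = c * c - b * (a - r2)
        if disc > 0.0:
            t = (-c - math.sqrt(disc)) / b
            if t > _EPS:
                best_t = t
                best_dir = -1
    # outer wall (radius index s) exists while s <= m-1
    if s <= m - 1:
        r2 = radii2[off[p] + s]
        disc = c * c - b * (a - r2)
        if disc > 0.0:
            t = (-c + math.sqrt(disc)) / b
            if _EPS < t < best_t:
                best_t = t
                best_dir = 1
    return best_t, best_dir


@njit(cache=True)
def _update_pairs_of(k, n, pos, vel, off, radii2, bounded, shell,
                     next_dt, next_dir, t_now):
    for a in range(n):
        if a == k:
            continue
        i, j = (a, k) if a < k else (k, a)
        p = _pair_index(i, j, n)
        dt, d = _predict(p, i, j, pos, vel, off, radii2, bounded, shell)
        next_dt[p] = t_now + dt if dt < _INF else _INF
        next_dir[p] = d


@njit(cache=True)
def _run_core(pos, vel, mass, off, offe, radii2, energies, bounded, shell,
              pe_start, t_end, frame_interval, thermo_rate, temperature,
              seed, frames_t, frames_pos, frames_pe, frames_ke, max_events):
    np.random.seed(seed)
    n = pos.shape[0]
    npair = off.shape[0] - 1
    next_t = np.full(npair, _INF)
    next_dir = np.zeros(npair, dtype=np.int8)
    pi = np.empty(npair, dtype=np.int64)
    pj = np.empty(npair, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            p = _pair_index(i, j, n)
            pi[p] = i
            pj[p] = j
            dt, d = _predict(p, i, j, pos, vel, off, radii2, bounded, shell)
            next_t[p] = dt
            next_dir[p] = d

    t = 0.0
    pe = pe_start
    n_frames = 0
    # frame 0
    frames_t[0] = 0.0
    frames_pe[0] = pe
    ke = 0.0
    for i in range(n):
        ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    frames_ke[0] = ke
    for i in range(n):
        for d3 in range(3):
            frames_pos[0, i, d3] = pos[i, d3]
    n_frames = 1
    next_frame = frame_interval
    if thermo_rate > 0.0:
        next_thermo = np.random.exponential(1.0 / (thermo_rate * n))
    else:
        next_thermo = _INF
    events = 0

    while True:
        pmin = -1
        tmin = _INF
        for p in range(npair):
            if next_t[p] < tmin:
                tmin = next_t[p]
                pmin = p
        # earliest of: end, frame, thermostat, pair event
        if t_end <= tmin and t_end <= next_thermo and t_end <= next_frame:
            dt = t_end - t
            for i in range(n):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t = t_end
            break
        if next_frame <= tmin and next_frame <= next_thermo:
            dt = next_frame - t
            for i in range(n):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t = next_frame
            frames_t[n_frames] = t
            frames_pe[n_frames] = pe
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2
                                       + vel[i, 2] ** 2)
            frames_ke[n_frames] = ke
            for i in range(n):
                for d3 in range(3):
                    frames_pos[n_frames, i, d3] = pos[i, d3]
            n_frames += 1
            next_frame += frame_interval
            continue
        if next_thermo <= tmin:
            dt = next_thermo - t
            for i in range(n):
                pos[i, 0] += vel[i, 0] * dt
                pos[i, 1] += vel[i, 1] * dt
                pos[i, 2] += vel[i, 2] * dt
            t = next_thermo
            k = np.random.randint(0, n)
            sd = math.sqrt(temperature / mass[k])
            vel[k, 0] = sd * np.random.normal()
            vel[k, 1] = sd * np.random.normal()
            vel[k, 2] = sd * np.random.normal()
            _update_pairs_of(k, n, pos, vel, off, radii2, bounded, shell,
                             next_t, next_dir, t)
            next_thermo = t + np.random.exponential(1.0 / (thermo_rate * n))
            continue

        # pair event
        dt = tmin - t
        for i in range(n):
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
        t = tmin
        i = pi[pmin]
        j = pj[pmin]
        direction = next_dir[pmin]
        s = shell[pmin]
        dxx = pos[i, 0] - pos[j, 0]
        dxy = pos[i, 1] - pos[j, 1]
        dxz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dxx * dxx + dxy * dxy + dxz * dxz)
        rhx = dxx / r
        rhy = dxy / r
        rhz = dxz / r
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        vr = dvx * rhx + dvy * rhy + dvz * rhz
        mu = mass[i] * mass[j] / (mass[i] + mass[j])
        new_s = s + 1 if direction > 0 else s - 1
        e_old = _shell_energy(pmin, s, off, offe, energies, bounded)
        e_new = _shell_energy(pmin, new_s, off, offe, energies, bounded)
        dU = e_new - e_old
        if dU < _INF / 2 and (dU <= 0.0 or 0.5 * mu * vr * vr > dU):
            vr_new = math.sqrt(vr * vr - 2.0 * dU / mu)
            if vr < 0.0:
                vr_new = -vr_new
            impulse = mu * (vr_new - vr)
            shell[pmin] = new_s
            pe += dU
        else:
            impulse = -2.0 * mu * vr
        fx = impulse * rhx
        fy = impulse * rhy
        fz = impulse * rhz
        vel[i, 0] += fx / mass[i]
        vel[i, 1] += fy / mass[i]
        vel[i, 2] += fz / mass[i]
        vel[j, 0] -= fx / mass[j]
        vel[j, 1] -= fy / mass[j]
        vel[j, 2] -= fz / mass[j]
        events += 1
        _update_pairs_of(i, n, pos, vel, off, radii2, bounded, shell,
                         next_t, next_dir, t)
        _update_pairs_of(j, n, pos, vel, off, radii2, bounded, shell,
                         next_t, next_dir, t)
        if events >= max_events:
            return n_frames, events, pe, 1
    return n_frames, events, pe, 0


# ---------------------------------------------------------------------------
# table compilation and wrapper
# ---------------------------------------------------------------------------

class CompiledTable:
    """Flat-array view of an InteractionTable for the numba kernel."""

    def __init__(self, table: InteractionTable):
        n = table.n_atoms
        self.n_atoms = n
        npair = n * (n - 1) // 2
        pots: list = [None] * npair
        for i, j, pot in table.compile():
            p = i * n - (i * (i + 1)) // 2 + (j - i - 1)
            pots[p] = pot
        off = np.zeros(npair + 1, dtype=np.int64)
        offe = np.zeros(npair, dtype=np.int64)
        radii2: list[float] = []
        energies: list[float] = []
        bounded = np.zeros(npair, dtype=np.int8)
        for p in range(npair):
            offe[p] = len(energies)
            pot = pots[p]
            if pot is not None:
                radii2.extend(r * r for r in pot.radii)
                energies.extend(pot.energies)
                bounded[p] = 1 if pot.bounded else 0
            off[p + 1] = len(radii2)
        self.off = off
        self.offe = offe
        self.radii2 = np.array(radii2, dtype=float)
        self.energies = np.array(energies, dtype=float)
        self.bounded = bounded
        self.pots = pots

    def pair_ij(self, p: int) -> tuple[int, int]:
        n = self.n_atoms
        for i in range(n):
            base = i * n - (i * (i + 1)) // 2
            if base <= p < base + (n - i - 1):
                return i, p - base + i + 1
        raise IndexError(p)

    def initial_shells(self, coords: np.ndarray) -> tuple[np.ndarray, float]:
        """Shell assignment + total PE for a configuration; raises
        InitializationError on any hard-wall violation."""
        n = self.n_atoms
        npair = len(self.offe)
        shell = np.zeros(npair, dtype=np.int64)
        pe = 0.0
        p = 0
        for i in range(n):
            for j in range(i + 1, n):
                m = self.off[p + 1] - self.off[p]
                if m > 0:
                    r2 = float(np.sum((coords[i] - coords[j]) ** 2))
                    seg = self.radii2[self.off[p]:self.off[p + 1]]
                    s = int(np.searchsorted(seg, r2, side="right"))
                    if s == 0:
                        raise InitializationError(
                            f"atoms {i} and {j} overlap their hard core "
                            f"(r={math.sqrt(r2):.3f} Å < {math.sqrt(seg[0]):.3f} Å)")
                    if self.bounded[p] and s >= m:
                        raise InitializationError(
                            f"atoms {i} and {j} violate a bounded constraint "
                            f"(r={math.sqrt(r2):.3f} Å > {math.sqrt(seg[-1]):.3f} Å)")
                    shell[p] = s
                    if 1 <= s <= m - 1:
                        pe += self.energies[self.offe[p] + s - 1]
                p += 1
        return shell, pe

    def energy(self, coords: np.ndarray) -> float:
        _, pe = self.initial_shells(coords)
        return pe


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann draw at reduced temperature T with the total
    momentum removed."""
    n = len(masses)
    v = rng.normal(size=(n, 3)) * np.sqrt(temperature / masses)[:, None]
    v -= np.sum(masses[:, None] * v, axis=0) / np.sum(masses)
    return v


def run_dmd(system: MolecularSystem, table: InteractionTable,
            temperature: float, length: float, seed: int, *,
            thermostat: bool = True, frame_interval: float = 1.0,
            thermostat_rate: float = 0.1,
            state: SimState | None = None,
            max_events: int = 200_000_000) -> tuple[Trajectory, SimState]:
    """Run one event-driven DMD segment and return (trajectory, final state).

    With ``thermostat`` off the total energy is conserved to floating-point
    accuracy; with it on, Andersen velocity redraws at rate
    ``thermostat_rate`` per particle per reduced time unit drive the system
    to the canonical ensemble at ``temperature``.  Frames (coordinates, PE,
    KE) are recorded every ``frame_interval`` time units, frame 0 included.
    Fixed seeds give bitwise-identical trajectories.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    compiled = table if isinstance(table, CompiledTable) else CompiledTable(table)
    if state is not None:
        pos = state.positions.copy()
        vel = state.velocities.copy()
    else:
        pos = system.coords.astype(float).copy()
        rng = np.random.default_rng(seed)
        vel = maxwell_boltzmann_velocities(system.masses.astype(float),
                                           max(temperature, 1e-8), rng)
    mass = system.masses.astype(float)
    shell, pe0 = compiled.initial_shells(pos)

    n_frames_max = int(length / frame_interval) + 3
    frames_t = np.zeros(n_frames_max)
    frames_pos = np.zeros((n_frames_max, len(mass), 3))
    frames_pe = np.zeros(n_frames_max)
    frames_ke = np.zeros(n_frames_max)

    kernel_seed = int(seed) % (2 ** 31 - 1)
    nf, events, pe_end, status = _run_core(
        pos, vel, mass, compiled.off, compiled.offe, compiled.radii2,
        compiled.energies, compiled.bounded, shell, pe0, float(length),
        float(frame_interval),
        float(thermostat_rate) if thermostat else 0.0,
        float(temperature), kernel_seed,
        frames_t, frames_pos, frames_pe, frames_ke, max_events)
    if status != 0:
        raise RuntimeError(f"event budget exhausted after {events} events")

    traj = Trajectory(
        times=frames_t[:nf].copy(),
        coords=frames_pos[:nf].copy(),
        potential_energies=frames_pe[:nf].copy(),
        kinetic_energies=frames_ke[:nf].copy(),
        temperature=temperature,
        metadata={"seed": int(seed), "events": int(events),
                  "thermostat": bool(thermostat), "length": float(length)},
    )
    final = SimState.make(pos, vel, mass, float(length), float(pe_end), int(seed))
    return traj, final


DEFAULT_EQUILIBRATION_STAGES = ((0.5, 200.0), (0.4, 200.0), (0.3, 400.0))


def staged_equilibration(system: MolecularSystem, table: InteractionTable,
                         seed: int,
                         stages=DEFAULT_EQUILIBRATION_STAGES,
                         thermostat_rate: float = 0.2) -> SimState:
    """Iterative relaxation: successive thermostatted DMD segments at a
    descending temperature ladder, each continuing from the previous state.

    The standard post-substitution protocol: after grafting a new residue
    the local geometry is strained, and a few short annealing stages settle
    the structure before production runs.  Returns the final state (the
    relaxed coordinates are ``state.positions``).
    """
    state: SimState | None = None
    compiled = CompiledTable(table) if not isinstance(table, CompiledTable) else table
    for k, (temperature, length) in enumerate(stages):
        _, state = run_dmd(system, compiled, temperature, length,
                           seed + k, thermostat=True,
                           frame_interval=max(length / 4.0, 1.0),
                           thermostat_rate=thermostat_rate, state=state)
    return state


# ---------------------------------------------------------------------------
# trajectory output
# ---------------------------------------------------------------------------

def write_energy_table(traj: Trajectory, path) -> None:
    """Per-frame energies as a plain-text table: time, PE, KE, T."""
    with open(path, "w") as fh:
        fh.write("# time\tPE\tKE\tT\n")
        for t, pe, ke in zip(traj.times, traj.potential_energies,
                             traj.kinetic_energies):
            fh.write(f"{t:.6f}\t{pe:.8f}\t{ke:.8f}\t{traj.temperature:.6f}\n")


def write_trajectory_pdb(traj: Trajectory, system: MolecularSystem, path) -> None:
    """Multi-model PDB of the trajectory frames."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 0
        for i in range(system.n_atoms):
            res = system.residues[system.residue_index[i]]
            serial += 1
            name = system.atom_names[i]
            pname = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = traj.coords[f, i]
            lines.append(
                f"ATOM  {serial:5d} {pname:<4s}{res.name:>4s} {res.chain:1s}"
                f"{res.seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {system.elements[i]:>2s}")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
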