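"""Replica-exchange controller over the DMD engine.

Replicas run in parallel (serially interleaved here) at a ladder of reduced
temperatures; at a fixed interval, neighbouring rungs attempt to exchange
temperatures under the Metropolis criterion

    p_accept = min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)]),   T_i < T_j.

The default ladder is the 16-rung set 0.48 ... 0.71 kcal/(mol k_B) used for
SOD1-scale melting profiles; reduced temperatures convert to Kelvin through
k_B = 0.0019872 kcal/(mol K) (the conversion is indicative only — simulation
temperatures do not directly equate to physical ones).  On an accepted swap
velocities are rescaled by sqrt(T_new/T_old).  One RNG stream per replica
plus a dedicated swap stream, all derived from the master seed, make runs
reproducible without coupling the replicas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dmd_engine import SimState, TIME_UNIT_FS, Trajectory, run_dmd
from .forcefield import InteractionTable
from .model_io import MolecularSystem

__all__ = [
    "KB_KCAL_PER_MOL_K",
    "PAPER_LADDER",
    "ReplicaLadder",
    "ExchangeLog",
    "reduced_to_kelvin",
    "metropolis_swap",
    "run_remd",
]

#: Boltzmann constant, kcal/(mol K)
KB_KCAL_PER_MOL_K = 0.0019872

#: 16-rung reduced-temperature ladder (kcal/(mol k_B)) for melting profiles
PAPER_LADDER = (0.48, 0.495, 0.51, 0.525, 0.54, 0.555, 0.57, 0.585,
                0.60, 0.615, 0.63, 0.645, 0.65, 0.67, 0.69, 0.71)

#: default exchange interval: 50 ps expressed in reduced time units
DEFAULT_EXCHANGE_INTERVAL = 50_000.0 / TIME_UNIT_FS


def reduced_to_kelvin(t_red: float) -> float:
    """Convert a reduced temperature (kcal/(mol k_B)) to Kelvin."""
    if t_red <= 0:
        raise ValueError("reduced temperature must be positive")
    return t_red / KB_KCAL_PER_MOL_K


@dataclass(frozen=True)
class ReplicaLadder:
    """Ascending temperature ladder with an exchange interval (reduced time
    units).  Swaps alternate between even and odd neighbour pairs."""

    temperatures: tuple[float, ...] = PAPER_LADDER
    exchange_interval: float = DEFAULT_EXCHANGE_INTERVAL

    def __post_init__(self):
        t = self.temperatures
        if len(t) < 2:
            raise ValueError("ladder needs at least 2 temperatures")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("temperatures must be strictly ascending")
        if self.exchange_interval <= 0:
            raise ValueError("exchange interval must be positive")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    def in_kelvin(self) -> tuple[float, ...]:
        return tuple(reduced_to_kelvin(t) for t in self.temperatures)


@dataclass
class SwapAttempt:
    time: float
    rung_pair: tuple[int, int]         # temperature rung indices (k, k+1)
    replicas: tuple[int, int]          # replica ids occupying those rungs
    energies: tuple[float, float]
    delta: float
    accepted: bool


@dataclass
class ExchangeLog:
    """Record of every swap attempt plus the rung -> replica occupancy after
    each exchange round (always a bijection)."""

    attempts: list[SwapAttempt] = field(default_factory=list)
    occupancy: list[tuple[float, tuple[int, ...]]] = field(default_factory=list)

    def acceptance_rate(self) -> float:
        if not self.attempts:
            return float("nan")
        return sum(a.accepted for a in self.attempts) / len(self.attempts)

    def check_bijection(self) -> bool:
        n = max((max(occ) for _, occ in self.occupancy), default=-1) + 1
        return all(sorted(occ) == list(range(n)) for _, occ in self.occupancy)

    def to_text(self) -> str:
        lines = ["# time\trung_i\trung_j\trep_i\trep_j\tE_i\tE_j\tdelta\taccepted"]
        for a in self.attempts:
            lines.append(f"{a.time:.4f}\t{a.rung_pair[0]}\t{a.rung_pair[1]}\t"
                         f"{a.replicas[0]}\t{a.replicas[1]}\t"
                         f"{a.energies[0]:.6f}\t{a.energies[1]:.6f}\t"
                         f"{a.delta:.6f}\t{int(a.accepted)}")
        return "\n".join(lines) + "\n"


def metropolis_swap(E_i: float, E_j: float, T_i: float, T_j: float,
                    u: float) -> bool:
    """Metropolis acceptance for exchanging temperatures T_i < T_j between
    configurations with energies E_i (cold) and E_j (hot)."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    if T_i == T_j:
        raise ValueError("degenerate pair: equal temperatures")
    if T_i > T_j:
        E_i, E_j = E_j, E_i
        T_i, T_j = T_j, T_i
    delta = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    if delta >= 0:
        return True
    return u < math.exp(delta)


def run_remd(system: MolecularSystem, table: InteractionTable,
             ladder: ReplicaLadder, length: float, seed: int, *,
             frame_interval: float = 1.0, thermostat_rate: float = 0.1,
             ) -> tuple[dict[float, Trajectory], ExchangeLog]:
    """Replica-exchange DMD.

    Returns trajectories keyed by *temperature* (frames contributed by
    whichever replica occupied that rung) and the exchange log.  Exchange
    attempts occur every ``ladder.exchange_interval`` time units on
    alternating even/odd neighbour pairs.  Deterministic for a fixed seed.
    """
    from .dmd_engine import CompiledTable, maxwell_boltzmann_velocities

    temps = ladder.temperatures
    n_rep = ladder.n_replicas
    compiled = CompiledTable(table)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_rep + 1)
    swap_rng = np.random.default_rng(children[-1])
    replica_rngs = [np.random.default_rng(children[r]) for r in range(n_rep)]

    # rung k currently held by replica rung_to_rep[k]
    rung_to_rep = list(range(n_rep))
    masses = system.masses.astype(float)
    states: list[SimState] = []
    for r in range(n_rep):
        vel = maxwell_boltzmann_velocities(masses, temps[r], replica_rngs[r])
        states.append(SimState.make(system.coords.astype(float).copy(), vel,
                                    masses, 0.0, 0.0, seed))

    n_segments = max(1, int(round(length / ladder.exchange_interval)))
    seg_len = ladder.exchange_interval

    per_temp_frames: dict[int, list] = {k: [] for k in range(n_rep)}
    log = ExchangeLog()
    log.occupancy.append((0.0, tuple(rung_to_rep)))
    t_offset = 0.0

    for seg in range(n_segments):
        for k in range(n_rep):
            r = rung_to_rep[k]
            seg_seed = int(replica_rngs[r].integers(0, 2 ** 31 - 1))
            try:
                traj, states[r] = run_dmd(
                    system, compiled, temps[k], seg_len, seg_seed,
                    thermostat=True, frame_interval=frame_interval,
                    thermostat_rate=thermostat_rate, state=states[r])
            except Exception as exc:
                raise RuntimeError(f"replica {r} (rung {k}, T={temps[k]:.4g}) "
                                   f"failed in segment {seg}: {exc}") from exc
            skip = 1 if seg > 0 else 0  # frame 0 duplicates the previous end
            per_temp_frames[k].append((t_offset, traj, skip))
        t_offset += seg_len

        parity = seg % 2
        for k in range(parity, n_rep - 1, 2):
            ri, rj = rung_to_rep[k], rung_to_rep[k + 1]
            E_i = states[ri].potential_energy
            E_j = states[rj].potential_energy
            u = float(swap_rng.random())
            delta = (1.0 / temps[k] - 1.0 / temps[k + 1]) * (E_i - E_j)
            accepted = metropolis_swap(E_i, E_j, temps[k], temps[k + 1], u)
            log.attempts.append(SwapAttempt(
                time=t_offset, rung_pair=(k, k + 1), replicas=(ri, rj),
                energies=(E_i, E_j), delta=delta, accepted=accepted))
            if accepted:
                rung_to_rep[k], rung_to_rep[k + 1] = rj, ri
                # replica ri moves up in temperature, rj moves down
                scale_up = math.sqrt(temps[k + 1] / temps[k])
                states[ri].velocities *= scale_up
                states[rj].velocities /= scale_up
        log.occupancy.append((t_offset, tuple(rung_to_rep)))

    trajectories: dict[float, Trajectory] = {}
    for k in range(n_rep):
        times, coords, pes, kes = [], [], [], []
        for off, traj, skip in per_temp_frames[k]:
            times.append(traj.times[skip:] + off)
            coords.append(traj.coords[skip:])
            pes.append(traj.potential_energies[skip:])
            kes.append(traj.kinetic_energies[skip:])
        trajectories[temps[k]] = Trajectory(
            times=np.concatenate(times),
            coords=np.concatenate(coords),
            potential_energies=np.concatenate(pes),
            kinetic_energies=np.concatenate(kes),
            temperature=temps[k],
            metadata={"seed": int(seed), "ladder": tuple(temps),
                      "exchange_interval": ladder.exchange_interval},
        )
    return trajectories, log
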