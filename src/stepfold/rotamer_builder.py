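"""Backbone-dependent rotamer-library construction for non-canonical
residues.

The protocol mirrors the MakeRotLib recipe: a regular φ/ψ grid (10°
increments giving 36 x 36 = 1296 bins by default), within each bin a scan of
every χ torsion at 30° increments, assignment of each χ grid point to the
nearest of the three staggered seeds (+60°, 180°, -60° per χ), and
Boltzmann-weighted circular means, circular standard deviations and
probabilities per seed.  The quantum-chemical torsional surface is replaced
by a pluggable ``energy_fn(phi, psi, *chis) -> kcal/mol``; a
molecular-mechanics-style toy surface for the BMAA side chain ships as the
default.

A post-processing mode overwrites χ standard deviations and attaches a
reference energy from a packaged lysine table (both BMAA and lysine being
unbranched, positively charged side chains); the shipped table is a
synthetic stand-in, see its file docstring.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "RotamerRecord",
    "STAGGERED_CHI",
    "DEFAULT_KT",
    "phi_psi_grid",
    "chi_seed_conformations",
    "fit_bin_rotamers",
    "build_library",
    "write_rotlib",
    "read_rotlib",
    "apply_lysine_reference",
    "default_bmaa_energy",
]

#: the three staggered χ seed values, degrees
STAGGERED_CHI = (60.0, 180.0, -60.0)

#: Boltzmann temperature for rotamer probabilities: k_B T at 298 K, kcal/mol
DEFAULT_KT = 0.5917

DEFAULT_PHI_INCREMENT = 10.0
DEFAULT_CHI_INCREMENT = 30.0


@dataclass
class RotamerRecord:
    """One rotamer in one backbone bin."""

    phi: float                   # bin center, deg
    psi: float                   # bin center, deg
    seed: tuple[float, ...]      # staggered seed per χ
    chi_means: tuple[float, ...]  # deg, in (-180, 180]
    chi_sds: tuple[float, ...]   # deg, > 0
    probability: float

    @property
    def n_chi(self) -> int:
        return len(self.seed)


def _wrap(angle):
    """Map to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def phi_psi_grid(increment: float):
    """Bin centers of the regular (φ, ψ) grid over (-180, 180]².

    ``increment`` must divide 360; 10° gives 36 x 36 = 1296 bins.
    """
    if increment <= 0 or abs(360.0 / increment - round(360.0 / increment)) > 1e-9:
        raise ValueError("increment must be a positive divisor of 360")
    n = int(round(360.0 / increment))
    centers = [_wrap(-180.0 + increment * (k + 1)) for k in range(n)]
    return [(p, q) for p in centers for q in centers]


def chi_seed_conformations(n_chi: int):
    """Cartesian product of the three staggered conformations per χ:
    3^n_chi seed tuples."""
    if n_chi < 0:
        raise ValueError("n_chi must be non-negative")
    return [tuple(c) for c in itertools.product(STAGGERED_CHI, repeat=n_chi)]


def _circular_distance(a, b):
    d = np.abs(_wrap(np.asarray(a) - np.asarray(b)))
    return d


def _weighted_circular_mean_sd(angles_deg, weights):
    """Weighted circular mean (deg, in (-180, 180]) and circular standard
    deviation sqrt(-2 ln R̄) converted to degrees."""
    th = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.asarray(weights, dtype=float)
    W = w.sum()
    if W <= 0:
        return 0.0, 0.0
    C = float(np.sum(w * np.cos(th))) / W
    S = float(np.sum(w * np.sin(th))) / W
    mean = math.degrees(math.atan2(S, C))
    if mean <= -180.0:
        mean += 360.0
    R = min(1.0, math.hypot(C, S))
    sd = math.degrees(math.sqrt(max(-2.0 * math.log(max(R, 1e-300)), 0.0)))
    return mean, sd


def fit_bin_rotamers(energy_fn, bin_center: tuple[float, float],
                     chi_increment: float = DEFAULT_CHI_INCREMENT,
                     temperature: float = DEFAULT_KT,
                     n_chi: int | None = None) -> list[RotamerRecord]:
    """Scan χ space on a grid within one (φ, ψ) bin and condense it into
    staggered-seed rotamers.

    Every χ grid point goes to the seed nearest per-χ (circular distance);
    each seed's probability is its share of the total Boltzmann mass at
    ``temperature`` (kcal/mol), and its χ means/SDs are Boltzmann-weighted
    circular statistics.  Probabilities within the bin sum to 1.
    """
    if chi_increment <= 0 or abs(360.0 / chi_increment
                                 - round(360.0 / chi_increment)) > 1e-9:
        raise ValueError("chi_increment must divide 360")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    phi, psi = bin_center
    if n_chi is None:
        # probe the energy function's arity
        import inspect
        n_chi = max(0, len(inspect.signature(energy_fn).parameters) - 2)
    seeds = chi_seed_conformations(n_chi)
    if n_chi == 0:
        return [RotamerRecord(phi=phi, psi=psi, seed=(), chi_means=(),
                              chi_sds=(), probability=1.0)]

    n_pts = int(round(360.0 / chi_increment))
    axis = _wrap(np.array([-180.0 + chi_increment * (k + 1)
                           for k in range(n_pts)]))
    grids = np.meshgrid(*([axis] * n_chi), indexing="ij")
    chis = np.stack([g.ravel() for g in grids], axis=1)   # (M, n_chi)
    E = np.asarray(energy_fn(phi, psi, *chis.T), dtype=float)
    if not np.any(np.isfinite(E)):
        raise ValueError("energy function is non-finite on the whole χ grid")
    E = np.where(np.isfinite(E), E, np.inf)
    w = np.exp(-(E - np.min(E)) / temperature)
    total = w.sum()

    # nearest staggered seed, independently per χ; grid points equidistant
    # from two seeds (e.g. χ = 0° between +60 and -60) share their weight
    seed_axis = np.array(STAGGERED_CHI)
    membership = np.zeros((len(chis), n_chi, 3))
    for c in range(n_chi):
        d = _circular_distance(chis[:, [c]], seed_axis[None, :])
        tied = np.abs(d - d.min(axis=1, keepdims=True)) < 1e-9
        membership[:, c, :] = tied / tied.sum(axis=1, keepdims=True)

    records = []
    for seed_idx in itertools.product(range(3), repeat=n_chi):
        frac = np.ones(len(chis))
        for c in range(n_chi):
            frac = frac * membership[:, c, seed_idx[c]]
        seed = tuple(STAGGERED_CHI[k] for k in seed_idx)
        wf = w * frac
        mass = float(wf.sum())
        prob = mass / total
        means, sds = [], []
        for c in range(n_chi):
            if mass > 0:
                m, s = _weighted_circular_mean_sd(chis[:, c], wf)
            else:
                m, s = seed[c], chi_increment / 2.0
            means.append(m)
            sds.append(max(s, 1e-6))
        records.append(RotamerRecord(phi=phi, psi=psi, seed=seed,
                                     chi_means=tuple(means),
                                     chi_sds=tuple(sds), probability=prob))
    # normalize away any floating-point slack
    total_p = sum(r.probability for r in records)
    for r in records:
        r.probability /= total_p
    records.sort(key=lambda r: -r.probability)
    return records


def build_library(energy_fn, n_chi: int,
                  phi_increment: float = DEFAULT_PHI_INCREMENT,
                  chi_increment: float = DEFAULT_CHI_INCREMENT,
                  temperature: float = DEFAULT_KT) -> list[RotamerRecord]:
    """Fit rotamers in every (φ, ψ) bin of the grid."""
    records: list[RotamerRecord] = []
    for bin_center in phi_psi_grid(phi_increment):
        records.extend(fit_bin_rotamers(energy_fn, bin_center, chi_increment,
                                        temperature, n_chi=n_chi))
    return records


# ---------------------------------------------------------------------------
# library file format
# ---------------------------------------------------------------------------

def write_rotlib(records: list[RotamerRecord], path,
                 phi_increment: float | None = None) -> None:
    """Write a library: one line per (φ bin, ψ bin, rotamer) —
    φ, ψ, probability, χ means, χ SDs — rotamers sorted by descending
    probability within each bin.  Raises a coverage error listing missing
    bins if the records do not span the full φ/ψ grid."""
    if not records:
        raise ValueError("no records")
    present = {(r.phi, r.psi) for r in records}
    if phi_increment is None:
        phis = sorted({r.phi for r in records})
        phi_increment = min(np.diff(phis)) if len(phis) > 1 else 360.0
    expected = set(phi_psi_grid(phi_increment))
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"incomplete φ/ψ grid: {len(missing)} missing bins, "
                         f"first few {missing[:5]}")
    by_bin: dict[tuple[float, float], list[RotamerRecord]] = {}
    for r in records:
        by_bin.setdefault((r.phi, r.psi), []).append(r)
    lines = ["# phi psi probability chi_means... chi_sds... (seed...)"]
    for key in sorted(by_bin):
        for r in sorted(by_bin[key], key=lambda x: -x.probability):
            fields = [f"{r.phi:.1f}", f"{r.psi:.1f}", f"{r.probability:.8f}"]
            fields += [f"{m:.4f}" for m in r.chi_means]
            fields += [f"{s:.4f}" for s in r.chi_sds]
            fields += [f"{s:.1f}" for s in r.seed]
            lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rotlib(path) -> list[RotamerRecord]:
    records = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        vals = [float(x) for x in line.split()]
        n_chi = (len(vals) - 3) // 3
        phi, psi, prob = vals[0], vals[1], vals[2]
        means = tuple(vals[3:3 + n_chi])
        sds = tuple(vals[3 + n_chi:3 + 2 * n_chi])
        seed = tuple(vals[3 + 2 * n_chi:3 + 3 * n_chi])
        records.append(RotamerRecord(phi=phi, psi=psi, seed=seed,
                                     chi_means=means, chi_sds=sds,
                                     probability=prob))
    return records


def apply_lysine_reference(records: list[RotamerRecord]):
    """Overwrite every record's χ standard deviations with the packaged
    lysine per-χ values and return ``(new_records, reference_energy)``.

    The packaged table is a synthetic stand-in for the lysine library
    parameters (see data/lysine_reference_synthetic.txt).
    """
    text = resources.files("stepfold.data").joinpath(
        "lysine_reference_synthetic.txt").read_text()
    sds: dict[int, float] = {}
    ref_energy = 0.0
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, val = line.split()
        if key == "reference_energy":
            ref_energy = float(val)
        elif key.startswith("chi"):
            sds[int(key.removeprefix("chi"))] = float(val)
    out = []
    for r in records:
        new_sds = tuple(sds.get(c + 1, s) for c, s in enumerate(r.chi_sds))
        out.append(RotamerRecord(phi=r.phi, psi=r.psi, seed=r.seed,
                                 chi_means=r.chi_means, chi_sds=new_sds,
                                 probability=r.probability))
    return out, ref_energy


# ---------------------------------------------------------------------------
# default torsional surface for the BMAA side chain
# ---------------------------------------------------------------------------

def default_bmaa_energy(phi, psi, chi1, chi2):
    """Toy molecular-mechanics torsional surface for the BMAA side chain
    (kcal/mol): threefold barriers on both χ torsions, a mild χ1/χ2
    coupling, and a weak backbone dependence.  Vectorized over χ."""
    p = math.radians(float(np.asarray(phi).ravel()[0])) \
        if np.ndim(phi) == 0 else np.radians(phi)
    q = math.radians(float(np.asarray(psi).ravel()[0])) \
        if np.ndim(psi) == 0 else np.radians(psi)
    c1 = np.radians(np.asarray(chi1, dtype=float))
    c2 = np.radians(np.asarray(chi2, dtype=float))
    e = (1.4 * (1.0 + np.cos(3.0 * c1))
         + 1.0 * (1.0 + np.cos(3.0 * c2))
         + 0.35 * np.cos(c1 - c2)
         + 0.25 * np.cos(c1 + p) + 0.15 * np.cos(c2 - q))
    return e
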