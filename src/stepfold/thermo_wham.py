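"""Weighted histogram analysis: density of states, specific heat, melting
peaks, and single-temperature potential-energy histograms.

Multi-temperature energy histograms with overlapping support are combined
into one density of states g(E) by iterating the WHAM self-consistency
equations in log space:

    ln g_m = ln(Σ_k n_km) - logsumexp_k[ ln N_k + f_k - E_m / T_k ]
    f_k    = -logsumexp_m[ ln g_m - E_m / T_k ]

(k_B = 1; temperatures carry energy units).  The specific heat then follows
from canonical energy fluctuations, C_V(T) = (⟨E²⟩ - ⟨E⟩²) / T², and peaks
of C_V(T) mark melting events; the global maximum is the major melting
transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from scipy.special import logsumexp

from .dmd_engine import Trajectory

__all__ = [
    "EnergyHistogramSet",
    "ThermoProfile",
    "DisconnectedSupportError",
    "wham",
    "specific_heat",
    "find_melting_events",
    "pe_histogram",
    "melting_profile",
]

DEFAULT_WHAM_TOL = 1e-7
DEFAULT_WHAM_MAX_ITER = 100_000
DEFAULT_PEAK_PROMINENCE = 0.10
DEFAULT_EQUILIBRATION_FRACTION = 0.20


class DisconnectedSupportError(ValueError):
    """Raised when the temperature histograms do not share energy support."""


@dataclass
class EnergyHistogramSet:
    """Per-temperature energy histograms on shared bin edges."""

    bin_edges: np.ndarray          # shared, kcal/mol, length n_bins+1
    counts: np.ndarray             # (n_temperatures, n_bins)
    temperatures: np.ndarray       # reduced, ascending

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.counts.shape != (len(self.temperatures), len(self.bin_edges) - 1):
            raise ValueError("counts shape mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        order = np.argsort(self.temperatures)
        self.temperatures = self.temperatures[order]
        self.counts = self.counts[order]
        occ = self.counts > 0
        for k in range(len(self.temperatures) - 1):
            if not np.any(occ[k] & occ[k + 1]):
                warnings.warn(
                    f"histograms at T={self.temperatures[k]:.4g} and "
                    f"T={self.temperatures[k + 1]:.4g} do not overlap",
                    stacklevel=2)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def sample_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_samples(cls, samples_by_temperature, temperatures,
                     bin_width: float | None = None,
                     n_bins: int | None = None,
                     bin_edges=None) -> "EnergyHistogramSet":
        """Build shared-bin histograms from raw per-temperature energy
        samples.  Default bin width: Freedman-Diaconis on the pooled
        sample; pass explicit ``bin_edges`` (e.g. centred on the levels of a
        discrete system) to control the energy grid exactly."""
        samples = [np.asarray(s, dtype=float) for s in samples_by_temperature]
        if bin_edges is not None:
            edges = np.asarray(bin_edges, dtype=float)
            counts = np.vstack([np.histogram(s, bins=edges)[0] for s in samples])
            return cls(bin_edges=edges, counts=counts,
                       temperatures=np.asarray(temperatures, dtype=float))
        pooled = np.concatenate(samples)
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        if n_bins is None:
            if bin_width is None:
                q75, q25 = np.percentile(pooled, [75, 25])
                iqr = q75 - q25
                bin_width = (2 * iqr / len(pooled) ** (1 / 3)) if iqr > 0 else \
                    (hi - lo) / 50
            n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = np.linspace(lo, hi + 1e-9 * max(1.0, abs(hi)), n_bins + 1)
        counts = np.vstack([np.histogram(s, bins=edges)[0] for s in samples])
        return cls(bin_edges=edges, counts=counts,
                   temperatures=np.asarray(temperatures, dtype=float))


@dataclass
class ThermoProfile:
    """Density of states and derived thermodynamics."""

    energies: np.ndarray           # occupied-bin centers grid
    ln_g: np.ndarray               # ln density of states, max normalized to 0
    temperatures: np.ndarray       # histogram temperatures
    free_energies: np.ndarray      # per-temperature f_k
    converged: bool = True
    residual: float = 0.0
    temperature_grid: np.ndarray | None = None
    cv: np.ndarray | None = None
    peak_temperatures: np.ndarray = field(default_factory=lambda: np.array([]))
    major_peak: float | None = None


def _check_connected(occ: np.ndarray) -> None:
    """Temperatures form one component under shared-occupied-bin edges."""
    K = occ.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        k = frontier.pop()
        for l in range(K):
            if l not in seen and np.any(occ[k] & occ[l]):
                seen.add(l)
                frontier.append(l)
    if len(seen) != K:
        raise DisconnectedSupportError(
            "energy histograms split into disconnected support groups; "
            "cannot combine by WHAM")


def wham(histset: EnergyHistogramSet, tol: float = DEFAULT_WHAM_TOL,
         max_iter: int = DEFAULT_WHAM_MAX_ITER) -> ThermoProfile:
    """Iterate the WHAM equations to self-consistency.

    Returns a profile over the *occupied* energy bins with ln g normalized
    to max 0.  Deterministic; emits a convergence warning (and sets
    ``converged=False``) if ``max_iter`` is reached with free-energy
    residual above ``tol``.
    """
    counts = histset.counts
    occupied = counts.sum(axis=0) > 0
    if not np.any(occupied):
        raise ValueError("no occupied energy bins")
    _check_connected(counts > 0)

    E = histset.bin_centers[occupied]
    n_km = counts[:, occupied]
    T = histset.temperatures
    N_k = histset.sample_sizes
    beta = 1.0 / T

    ln_sum_counts = np.log(n_km.sum(axis=0))
    ln_N = np.log(N_k)
    f = np.zeros(len(T))
    residual = np.inf
    converged = False
    for _ in range(max_iter):
        # ln g_m
        denom = logsumexp(ln_N[:, None] + f[:, None]
                          - beta[:, None] * E[None, :], axis=0)
        ln_g = ln_sum_counts - denom
        f_new = -logsumexp(ln_g[None, :] - beta[:, None] * E[None, :], axis=1)
        f_new = f_new - f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"WHAM did not converge: residual {residual:.3g} after "
                      f"{max_iter} iterations", stacklevel=2)
    denom = logsumexp(ln_N[:, None] + f[:, None]
                      - beta[:, None] * E[None, :], axis=0)
    ln_g = ln_sum_counts - denom
    ln_g = ln_g - ln_g.max()
    return ThermoProfile(energies=E, ln_g=ln_g, temperatures=T,
                         free_energies=f, converged=converged,
                         residual=residual)


def specific_heat(profile: ThermoProfile, T_grid) -> np.ndarray:
    """C_V(T) = (⟨E²⟩-⟨E⟩²)/T² from the recovered density of states,
    computed with log-sum-exp stabilization.  Also stores the grid and curve
    on the profile."""
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    if np.any(T_grid <= 0):
        raise ValueError("temperatures must be positive")
    E = profile.energies
    ln_g = profile.ln_g
    cv = np.empty(len(T_grid))
    for idx, T in enumerate(T_grid):
        w = ln_g - E / T
        lz = logsumexp(w)
        pw = np.exp(w - lz)
        e_mean = float(pw @ E)
        e2_mean = float(pw @ (E * E))
        var = max(e2_mean - e_mean * e_mean, 0.0)
        cv[idx] = var / (T * T)
    profile.temperature_grid = T_grid
    profile.cv = cv
    return cv


def find_melting_events(T_grid, cv, min_prominence: float = DEFAULT_PEAK_PROMINENCE):
    """Local C_V maxima with prominence >= ``min_prominence`` x global max.

    Returns ``(peak_temperatures ascending, major_peak_temperature)``; the
    major peak is the global maximum among detected peaks (None if the curve
    is flat/featureless).
    """
    T_grid = np.asarray(T_grid, dtype=float)
    cv = np.asarray(cv, dtype=float)
    if len(T_grid) < 3:
        raise ValueError("need at least 3 grid points")
    cmax = cv.max()
    if cmax <= 0 or np.allclose(cv, cv[0]):
        return np.array([]), None
    idx, _ = find_peaks(cv)
    if len(idx) == 0:
        return np.array([]), None
    prom = peak_prominences(cv, idx)[0]
    keep = idx[prom >= min_prominence * cmax]
    if len(keep) == 0:
        return np.array([]), None
    peaks = T_grid[keep]
    major = float(T_grid[keep[np.argmax(cv[keep])]])
    order = np.argsort(peaks)
    return peaks[order], major


def melting_profile(histset: EnergyHistogramSet, T_grid,
                    tol: float = DEFAULT_WHAM_TOL,
                    max_iter: int = DEFAULT_WHAM_MAX_ITER,
                    min_prominence: float = DEFAULT_PEAK_PROMINENCE) -> ThermoProfile:
    """wham + specific_heat + peak detection in one call."""
    profile = wham(histset, tol=tol, max_iter=max_iter)
    cv = specific_heat(profile, T_grid)
    peaks, major = find_melting_events(profile.temperature_grid, cv,
                                       min_prominence)
    profile.peak_temperatures = peaks
    profile.major_peak = major
    return profile


def pe_histogram(traj: Trajectory, bins=None,
                 equilibration: float = DEFAULT_EQUILIBRATION_FRACTION):
    """Normalized potential-energy histogram of a trajectory with the
    leading ``equilibration`` fraction of frames discarded.

    Returns ``(bin_centers, density, modal_energy)``; the density integrates
    to 1 over the bins.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    start = int(np.floor(traj.n_frames * equilibration))
    pe = traj.potential_energies[start:]
    if len(pe) == 0:
        pe = traj.potential_energies[-1:]
    if bins is None:
        lo, hi = float(pe.min()), float(pe.max())
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        q75, q25 = np.percentile(pe, [75, 25])
        iqr = q75 - q25
        width = (2 * iqr / len(pe) ** (1 / 3)) if iqr > 0 else (hi - lo) / 20
        bins = np.linspace(lo, hi + 1e-9 * max(1.0, abs(hi)),
                           max(2, int(np.ceil((hi - lo) / width))) + 1)
    counts, edges = np.histogram(pe, bins=bins)
    widths = np.diff(edges)
    total = counts.sum()
    density = counts / (total * widths) if total > 0 else counts.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = float(centers[np.argmax(counts)])
    return centers, density, mode
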