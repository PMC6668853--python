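"""Structural and dynamic trajectory analytics: optimal rigid superposition
(Kabsch), per-residue RMSF, residue-pair correlated-motion maps, and
wild-type-vs-variant difference maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dmd_engine import Trajectory

__all__ = [
    "CorrelationMap",
    "superpose",
    "fit_frames",
    "rmsf",
    "correlation_map",
    "difference_map",
]


@dataclass
class CorrelationMap:
    """Normalized residue-displacement covariance matrix, values in [-1, 1],
    unit diagonal.  ``labels`` identify residues as "<chain><number>"."""

    labels: list[str]
    matrix: np.ndarray
    flagged: list[int] | None = None  # zero-variance rows forced to 0

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix/label size mismatch")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(m) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_text(self) -> str:
        header = "\t".join([""] + self.labels)
        rows = [header]
        for lab, row in zip(self.labels, self.matrix):
            rows.append("\t".join([lab] + [f"{v:.6f}" for v in row]))
        return "\n".join(rows) + "\n"


def superpose(X: np.ndarray, Y: np.ndarray, weights=None):
    """Least-squares rigid superposition of X onto Y (Kabsch, proper
    rotation).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` the fitted coordinates and
    ``rmsd`` the weighted root-mean-square deviation after the fit.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("coordinate sets differ in shape")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 atoms for a rigid superposition")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    xc = (w[:, None] * X).sum(axis=0)
    yc = (w[:, None] * Y).sum(axis=0)
    Xc = X - xc
    Yc = Y - yc
    H = (w[:, None] * Xc).T @ Yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    fitted = Xc @ R.T + yc
    rmsd = float(np.sqrt((w * np.sum((fitted - Y) ** 2, axis=1)).sum()))
    return R, t, rmsd


def fit_frames(coords: np.ndarray, n_rounds: int = 2) -> np.ndarray:
    """Superpose every frame onto the iteratively refined mean structure.

    ``coords`` has shape (n_frames, n_atoms, 3); returns the fitted copy.
    """
    frames = np.array(coords, dtype=float)
    reference = frames[0]
    for _ in range(n_rounds):
        for f in range(len(frames)):
            R, t, _ = superpose(frames[f], reference)
            frames[f] = frames[f] @ R.T + t
        reference = frames.mean(axis=0)
    return frames


def _select(traj: Trajectory, selection):
    coords = traj.coords
    if selection is not None:
        coords = coords[:, np.asarray(selection, dtype=int), :]
    return coords


def rmsf(traj: Trajectory, selection=None, fit: bool = True) -> np.ndarray:
    """Root-mean-square fluctuation of each selected atom about its mean
    position, Å.  With ``fit`` the frames are first superposed onto the
    iterated mean structure so rigid-body motion does not count as
    fluctuation.  A single-frame trajectory yields all zeros (with a
    warning)."""
    coords = _select(traj, selection)
    if coords.shape[0] < 2:
        warnings.warn("single-frame trajectory: RMSF is identically zero",
                      stacklevel=2)
        return np.zeros(coords.shape[1])
    if fit:
        coords = fit_frames(coords)
    mean = coords.mean(axis=0)
    dev2 = np.sum((coords - mean) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def correlation_map(traj: Trajectory, selection=None, fit: bool = True,
                    labels: list[str] | None = None) -> CorrelationMap:
    """Dynamic cross-correlation map C_ij = ⟨Δr_i·Δr_j⟩ /
    √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over the (fitted) trajectory.

    Residues with zero variance get their row/column set to 0 (diagonal 1)
    and are listed in ``flagged``.
    """
    coords = _select(traj, selection)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if fit:
        coords = fit_frames(coords)
    dev = coords - coords.mean(axis=0)             # (F, N, 3)
    cov = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    flagged = [int(i) for i in np.where(var <= 1e-15)[0]]
    denom = np.sqrt(np.outer(np.where(var > 1e-15, var, 1.0),
                             np.where(var > 1e-15, var, 1.0)))
    C = cov / denom
    for i in flagged:
        C[i, :] = 0.0
        C[:, i] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    if labels is None:
        labels = [str(i) for i in range(C.shape[0])]
    return CorrelationMap(labels=list(labels), matrix=C,
                          flagged=flagged or None)


def difference_map(A: CorrelationMap, B: CorrelationMap) -> np.ndarray:
    """Element-wise A - B (positive = correlation increased in A).  The
    diagonal is exactly 0; raises on residue-label mismatch."""
    if A.labels != B.labels:
        unmatched = sorted(set(A.labels) ^ set(B.labels))
        raise ValueError(f"residue labels differ between maps: {unmatched}")
    D = A.matrix - B.matrix
    np.fill_diagonal(D, 0.0)
    return D
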