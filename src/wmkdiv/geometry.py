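"""Rigid-body superposition and scalar geometric descriptors.

Superposition is the weighted Kabsch algorithm on Cα coordinates, with the
reflection branch corrected so the returned rotation is always proper
(det = +1). Degenerate point sets (fewer than 3 atoms, or collinear clouds,
where the optimal rotation is not unique) raise instead of returning an
arbitrary member of the solution set.

Distances are in Å except the radius of gyration, reported in nm to match
the conventional axis units of ensemble-compactness plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform ``x -> rotation @ x + translation`` fitting mobile onto target."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å
    rmsd: float  # Å, weighted RMSD after fitting
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Parameters
    ----------
    mobile, target : (N, 3) arrays, N >= 3
    weights : optional nonnegative (N,) array, not all zero

    Returns the proper rotation and translation minimizing the weighted RMSD,
    along with that RMSD.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atoms, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative with a positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(0) / wsum
    ct = (w[:, None] * target).sum(0) / wsum
    P = mobile - cm
    Q = target - ct
    H = (w[:, None] * P).T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate clouds: optimal rotation not unique
    if S[1] <= 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear or coincident) point cloud")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    fitted = P @ R.T + ct
    rmsd_val = float(np.sqrt(((fitted - target) ** 2).sum(1) @ w / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd_val, n_atoms=n)


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation in Å; no superposition is performed."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=-1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal rigid fit (convenience composition)."""
    return kabsch_superpose(mobile, target).rmsd


def radius_of_gyration(A: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Radius of gyration in nm (input Å): sqrt(Σ w_i |r_i − r̄|² / Σ w_i).

    Unweighted by default; Cα-only, so absolute values are a proxy for the
    all-atom quantity and only relative comparisons should be interpreted.
    """
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 1:
        raise ValueError(f"expected (N, 3) with N >= 1, got {A.shape}")
    n = A.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative with a positive sum")
    centroid = (w[:, None] * A).sum(0) / w.sum()
    rg_angstrom = np.sqrt(((A - centroid) ** 2).sum(1) @ w / w.sum())
    return float(rg_angstrom / 10.0)  # Å -> nm
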