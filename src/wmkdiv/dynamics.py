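"""Within-ensemble motion analysis: DCCM and Cartesian trajectory PCA.

The dynamic cross-correlation matrix (DCCM) uses the isotropic
scalar-product estimator

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),   Δr_i = r_i − <r_i>,

computed over superposed frames, so C_ij ∈ [−1, 1] with unit diagonal.
Anti-correlated blocks (C < 0 between two domains) are the signature of
hinge-like inter-domain motion.

Trajectory PCA eigendecomposes the 3N×3N covariance of superposed frame
coordinates (1/(F−1) normalization). Principal-motion interpolation writes
structures mean + t·σ_k·PC_k for t in [−3σ, +3σ], the usual way the motion
captured by one component is visualized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structio import Ensemble, Structure


@dataclass(frozen=True)
class DCCM:
    matrix: np.ndarray  # (N, N), symmetric, unit diagonal
    residue_numbers: tuple
    zero_fluctuation: tuple = ()  # residue numbers with no positional variance

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class PCAResult:
    mean_coords: np.ndarray  # (N, 3)
    eigenvalues: np.ndarray  # (k,), nonincreasing, >= 0
    eigenvectors: np.ndarray  # (3N, k), orthonormal columns
    variance_fractions: np.ndarray  # (k,), sums to 1
    projections: np.ndarray  # (frames, k), column means 0
    residue_numbers: tuple
    core_positions: tuple | None = None
    labels: tuple | None = None  # per-frame homolog labels (joint PCA)


def superpose_ensemble(
    ensemble: Ensemble,
    reference: Structure | str = "mean",
    positions=None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> Ensemble:
    """Rigidly fit every frame onto a reference using the stated positions.

    ``reference`` is a Structure (e.g. the representative conformation) or
    the string ``"mean"``, which iterates fit-to-mean until the mean shifts
    by less than ``tol`` Å.
    """
    numbers = ensemble.residue_numbers
    if positions is None:
        idx = np.arange(len(numbers))
    else:
        pos = set(positions)
        idx = np.array([i for i, n in enumerate(numbers) if n in pos])
        if len(idx) < 3:
            raise ValueError("need at least 3 superposition positions")
    coords = ensemble.coords_array()

    def fit_all(target_sub):
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            sup = kabsch_superpose(coords[f, idx], target_sub)
            out[f] = sup.apply(coords[f])
        return out

    if isinstance(reference, Structure):
        if reference.residue_numbers != numbers:
            raise ValueError("reference residue set differs from ensemble")
        coords = fit_all(reference.coords[idx])
    else:
        if reference != "mean":
            raise ValueError(f"unknown reference {reference!r}")
        target = coords[0, idx]
        for _ in range(max_iter):
            coords = fit_all(target)
            new_target = coords[:, idx].mean(0)
            shift = float(np.sqrt(np.mean(np.sum((new_target - target) ** 2, axis=1))))
            target = new_target
            if shift < tol:
                break
    frames = [fr.with_coords(coords[f]) for f, fr in enumerate(ensemble.frames)]
    return ensemble.with_frames(frames, ensemble.times_ns)


def dccm(superposed: Ensemble) -> DCCM:
    """Residue-residue cross-correlation over an already superposed ensemble."""
    if len(superposed) < 2:
        raise ValueError("need at least 2 frames")
    X = superposed.coords_array()  # (F, N, 3)
    dX = X - X.mean(0)
    cov = np.einsum("fid,fjd->ij", dX, dX) / X.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    denom = np.sqrt(np.where(zero, 1.0, var))
    C = cov / denom[:, None] / denom[None, :]
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, np.where(zero, 0.0, 1.0))
    C = np.clip(C, -1.0, 1.0)
    numbers = superposed.residue_numbers
    flagged = tuple(n for n, z in zip(numbers, zero) if z)
    return DCCM(C, numbers, flagged)


def inter_set_correlation(d: DCCM, set_a, set_b) -> float:
    """Mean C_ij over i in A, j in B (disjoint residue-number sets)."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("sets must be non-empty")
    if set_a & set_b:
        raise ValueError(f"sets overlap: {sorted(set_a & set_b)}")
    index = {n: i for i, n in enumerate(d.residue_numbers)}
    ia = [index[n] for n in sorted(set_a)]
    ib = [index[n] for n in sorted(set_b)]
    return float(d.matrix[np.ix_(ia, ib)].mean())


def _pca_from_coords(coords: np.ndarray, residue_numbers, labels=None, core_positions=None) -> PCAResult:
    """PCA of (F, N, 3) coordinates via SVD of the centered frame matrix."""
    F, N, _ = coords.shape
    flat = coords.reshape(F, 3 * N)
    mean = flat.mean(0)
    Xc = flat - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (F - 1)
    k = min(F - 1, 3 * N)
    eigvals = eigvals[:k]
    vecs = Vt[:k].T  # (3N, k)
    # sign convention: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    proj = Xc @ vecs
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(
        mean_coords=mean.reshape(N, 3),
        eigenvalues=eigvals,
        eigenvectors=vecs,
        variance_fractions=fractions,
        projections=proj,
        residue_numbers=tuple(residue_numbers),
        core_positions=tuple(core_positions) if core_positions is not None else None,
        labels=tuple(labels) if labels is not None else None,
    )


def trajectory_pca(superposed: Ensemble) -> PCAResult:
    """Cartesian PCA of a superposed single-homolog ensemble."""
    if len(superposed) < 3:
        raise ValueError("need at least 3 frames")
    return _pca_from_coords(superposed.coords_array(), superposed.residue_numbers)


def pc_interpolate(pca: PCAResult, pc_index: int = 1, n_steps: int = 11, t_range: float = 3.0) -> list:
    """Structures mean + t·σ·PC for t evenly spaced in [−t_range, +t_range].

    ``pc_index`` is 1-based. Returns a list of Structures (generic residue
    codes are not tracked here; callers writing PDB should attach codes).
    """
    j = pc_index - 1
    if j < 0 or j >= len(pca.eigenvalues):
        raise ValueError(f"pc_index {pc_index} out of range")
    lam = pca.eigenvalues[j]
    if lam <= 1e-12:
        raise ValueError(f"component {pc_index} has (near-)zero eigenvalue")
    sigma = np.sqrt(lam)
    vec = pca.eigenvectors[:, j]
    n = len(pca.residue_numbers)
    out = []
    for step, t in enumerate(np.linspace(-t_range, t_range, n_steps)):
        coords = pca.mean_coords.reshape(-1) + t * sigma * vec
        out.append(
            Structure(
                f"pc{pc_index}_step{step}",
                pca.residue_numbers,
                "A" * n,
                coords.reshape(n, 3),
            )
        )
    return out
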