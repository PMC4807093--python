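"""Essential dynamics: Cartesian PCA of Ca coordinates, RMSIP and projections.

The covariance analysed is the population (1/F) covariance of the 3N fitted
Ca coordinates.  Eigenpairs are obtained from the SVD of the centred
coordinate matrix, which is numerically equivalent to diagonalising the
3N x 3N covariance but stable for F << 3N.  Eigenvector signs follow a fixed
convention (largest-magnitude component positive) so results are reproducible
across eigensolvers and BLAS builds.

Before calling :func:`compute_pca` the ensemble should be superposed;
:func:`align_to_mean` implements the standard essential-dynamics choice of
fitting to the ensemble mean structure (one fit -> mean iteration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import CoordinateEnsemble, ResidueSelection
from .geometry import superpose_ensemble

__all__ = [
    "PcaResult",
    "Projection",
    "align_to_mean",
    "compute_pca",
    "rmsip",
    "project",
    "mode_vectors",
    "export_mode_pdb",
]


@dataclass(frozen=True)
class PcaResult:
    """Eigendecomposition of the fitted-coordinate covariance.

    ``eigenvalues`` are in A^2, sorted non-increasing; ``eigenvectors`` is
    (n_modes, 3N) row-orthonormal; variance fractions are percentages summing
    to 100 over all non-zero modes.
    """

    mean_coords: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # (n_modes,)
    eigenvectors: np.ndarray  # (n_modes, 3N)
    variance_fraction: np.ndarray  # (n_modes,), percent
    cumulative_fraction: np.ndarray  # (n_modes,), percent
    labels: tuple  # per-residue labels of the analysed selection

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.size // 3


@dataclass(frozen=True)
class Projection:
    """Per-frame scores (A) on PCs 1..k."""

    scores: np.ndarray  # (F, k)


def align_to_mean(ensemble: CoordinateEnsemble, selection: ResidueSelection,
                  n_iterations: int = 1) -> CoordinateEnsemble:
    """Superpose all frames to the ensemble mean structure.

    Frames are first fitted to the first frame (to remove the bulk rigid
    drift), the mean is formed, and each subsequent iteration refits to the
    current mean.  One iteration is the conventional essential-dynamics
    alignment.
    """
    aligned = superpose_ensemble(ensemble, ensemble.frame(0), selection)
    for _ in range(n_iterations):
        mean = aligned.coords.mean(axis=0)
        aligned = superpose_ensemble(aligned, mean, selection)
    return aligned


def compute_pca(ensemble: CoordinateEnsemble, selection: ResidueSelection) -> PcaResult:
    """PCA of the selected atoms' coordinates (assumed already superposed)."""
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(selection) == 0:
        raise ValueError("empty selection")
    x = ensemble.coords[:, selection.atom_indices, :].reshape(ensemble.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD route: eigenvalues of the 1/F covariance are s^2 / F.
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigvals = s**2 / ensemble.n_frames
    n_keep = min(x.shape[1], ensemble.n_frames - 1)
    eigvals = eigvals[:n_keep]
    vecs = vt[:n_keep]
    # Fixed sign convention: largest-|component| entry is positive.
    for row in vecs:
        k = np.argmax(np.abs(row))
        if row[k] < 0:
            row *= -1.0
    total = eigvals.sum()
    if total <= 0:
        raise ValueError("ensemble has zero coordinate variance")
    frac = 100.0 * eigvals / total
    return PcaResult(mean, eigvals, vecs, frac, np.cumsum(frac), selection.labels)


def rmsip(set_a: np.ndarray, set_b: np.ndarray, d: int = 10) -> float:
    """Root mean-square inner product between the first ``d`` modes of each set.

    RMSIP = sqrt( (1/d) sum_i sum_j (a_i . b_j)^2 ), 1 for identical
    subspaces, 0 for orthogonal ones; invariant to orthonormal re-mixing
    within each subspace.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("mode sets must be 2-D with a common coordinate dimension")
    if a.shape[0] < d or b.shape[0] < d:
        raise ValueError(f"need at least {d} modes in each set")
    a = a[:d]
    b = b[:d]
    for name, m in (("A", a), ("B", b)):
        gram = m @ m.T
        if not np.allclose(gram, np.eye(d), atol=1e-6):
            raise ValueError(f"mode set {name} is not orthonormal")
    inner = a @ b.T
    return float(np.sqrt(np.sum(inner**2) / d))


def project(ensemble: CoordinateEnsemble, pca: PcaResult, k: int,
            selection: ResidueSelection | None = None) -> Projection:
    """Scores of each frame on PCs 1..k (centred coordinates . eigenvectors)."""
    if k > pca.n_modes:
        raise ValueError(f"k={k} exceeds available modes ({pca.n_modes})")
    if selection is not None:
        x = ensemble.coords[:, selection.atom_indices, :].reshape(ensemble.n_frames, -1)
    else:
        x = ensemble.coords.reshape(ensemble.n_frames, -1)
    if x.shape[1] != pca.mean_coords.size:
        raise ValueError("ensemble selection does not match PCA dimension")
    return Projection((x - pca.mean_coords) @ pca.eigenvectors[:k].T)


def mode_vectors(pca: PcaResult, mode: int, scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement arrows for one PC (1-based mode number).

    Arrows are the eigenvector components reshaped to (N, 3) and scaled so
    the longest arrow has length ``scale`` (A).
    """
    if not 1 <= mode <= pca.n_modes:
        raise ValueError(f"mode {mode} not in 1..{pca.n_modes}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    arrows = pca.eigenvectors[mode - 1].reshape(-1, 3).copy()
    longest = np.linalg.norm(arrows, axis=1).max()
    if longest > 0:
        arrows *= scale / longest
    return arrows


def export_mode_pdb(pca: PcaResult, mode: int, atom_table, path,
                    scale: float = 5.0) -> None:
    """Write one PC as a two-model PDB: mean structure, then mean + arrows.

    Standard viewers can draw the displacement vectors between the two
    models (the usual way PC directions are rendered on a structure).
    """
    from .ensemble_io import AtomModel, CoordinateEnsemble, write_ensemble

    mean = pca.mean_coords.reshape(-1, 3)
    displaced = mean + mode_vectors(pca, mode, scale)
    table = atom_table.reset_index(drop=True)
    stack = CoordinateEnsemble(np.stack([mean, displaced]), table)
    write_ensemble(stack, path, format="multimodel-pdb")
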