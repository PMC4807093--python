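"""Dynamic cross-correlation matrices and the contact/magnitude filters.

The DCCM element for residues i, j is

    C_ij = <dr_i . dr_j> / ( <|dr_i|^2> <|dr_j|^2> )^(1/2)

where dr is the Ca displacement from its ensemble mean and <.> averages over
frames.  The ensemble-averaged denominator is what makes C_ij a correlation
coefficient bounded in [-1, 1].  The conventional preprocessing step is to
superpose all frames on the first frame (:func:`align_to_first_frame`) so
rigid-body motion does not masquerade as correlation; this intentionally
differs from the mean-structure alignment used for PCA.

Network construction keeps an entry only if |C_ij| clears a magnitude cutoff
(default 0.5) *and* the residue pair is in spatial contact (Ca-Ca distance
within 10 A) for a minimum fraction of frames (default 75%): persistent
correlation between residues that are never near each other is not treated
as a physical interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ensemble_io import CoordinateEnsemble, ResidueSelection
from .geometry import superpose_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "ContactOccupancy",
    "FilteredCorrelation",
    "align_to_first_frame",
    "compute_dccm",
    "contact_occupancy",
    "filter_correlations",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """N x N symmetric matrix of displacement correlations in [-1, 1]."""

    values: np.ndarray
    residue_labels: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.residue_labels)
        if v.shape != (n, n):
            raise ValueError("matrix/labels shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-10):
            raise ValueError("correlation diagonal must be 1")
        if v.max() > 1 + 1e-10 or v.min() < -1 - 1e-10:
            raise ValueError("correlations outside [-1, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ContactOccupancy:
    """Fraction of frames each residue pair spends within ``cutoff`` A."""

    values: np.ndarray
    residue_labels: tuple
    cutoff: float


@dataclass(frozen=True)
class FilteredCorrelation:
    """DCCM with entries failing the magnitude or contact filter masked out."""

    values: np.ndarray  # filtered entries hold the correlation, others nan
    keep: np.ndarray  # boolean mask, False on the diagonal
    residue_labels: tuple
    magnitude_cutoff: float
    occupancy_threshold: float


def align_to_first_frame(ensemble: CoordinateEnsemble,
                         selection: ResidueSelection) -> CoordinateEnsemble:
    """Superpose every frame onto the first frame using ``selection``."""
    return superpose_ensemble(ensemble, ensemble.frame(0), selection)


def compute_dccm(ensemble: CoordinateEnsemble,
                 selection: ResidueSelection) -> CorrelationMatrix:
    """DCCM over the selected atoms of an already-superposed ensemble."""
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    x = ensemble.coords[:, selection.atom_indices, :]  # (F, N, 3)
    d = x - x.mean(axis=0)
    cross = np.einsum("fia,fja->ij", d, d) / ensemble.n_frames
    var = np.diag(cross).copy()
    zero = var <= 0.0
    if zero.any():
        bad = selection.labels[int(np.flatnonzero(zero)[0])]
        raise ValueError(
            f"residue {bad} has zero displacement variance; correlation undefined"
        )
    denom = np.sqrt(np.outer(var, var))
    values = cross / denom
    # Guard against roundoff just past the bounds, then symmetrise exactly.
    values = np.clip(values, -1.0, 1.0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    frac_extreme = np.mean(np.abs(values) > 0.99)
    if frac_extreme > 0.9:
        logger.warning(
            "DCCM is near-degenerate: %.0f%% of |C| > 0.99 "
            "(rigid-body-dominated ensemble?)", 100 * frac_extreme,
        )
    return CorrelationMatrix(values, selection.labels)


def contact_occupancy(ensemble: CoordinateEnsemble, selection: ResidueSelection,
                      cutoff: float = 10.0) -> ContactOccupancy:
    """Per-pair fraction of frames with Ca-Ca distance <= ``cutoff`` (A)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    x = ensemble.coords[:, selection.atom_indices, :]
    n = x.shape[1]
    counts = np.zeros(n * (n - 1) // 2)
    for frame in x:
        counts += pdist(frame) <= cutoff
    occ = squareform(counts / ensemble.n_frames)
    np.fill_diagonal(occ, 1.0)
    return ContactOccupancy(occ, selection.labels, float(cutoff))


def filter_correlations(c: CorrelationMatrix, occ: ContactOccupancy,
                        magnitude_cutoff: float = 0.5,
                        occupancy_threshold: float = 0.75) -> FilteredCorrelation:
    """Keep off-diagonal entries with |C| >= cutoff and occupancy >= threshold.

    Masked entries are represented as absent (nan), never as zero, so that
    downstream network construction cannot mistake them for true zero
    correlation.  The diagonal is always excluded.
    """
    if c.residue_labels != occ.residue_labels:
        raise ValueError("correlation and occupancy labels differ")
    if not 0 <= magnitude_cutoff <= 1:
        raise ValueError("magnitude cutoff must be in [0, 1]")
    if not 0 <= occupancy_threshold <= 1:
        raise ValueError("occupancy threshold must be in [0, 1]")
    keep = (np.abs(c.values) >= magnitude_cutoff) & (occ.values >= occupancy_threshold)
    np.fill_diagonal(keep, False)
    values = np.where(keep, c.values, np.nan)
    return FilteredCorrelation(values, keep, c.residue_labels,
                               float(magnitude_cutoff), float(occupancy_threshold))
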