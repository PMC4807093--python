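"""Rigid-body superposition, RMSD time series and distance monitors.

Superposition uses the Kabsch SVD procedure with reflection correction — the
standard least-squares fit of one point set onto another.  RMSD series follow
the usual trajectory-analysis protocol: each frame is first fitted on a *fit*
selection (e.g. the kinase C-lobe), then the RMSD is measured over a possibly
different *measure* selection (e.g. the aC-helix), so that local motions are
read relative to a rigid core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import CoordinateEnsemble, ResidueSelection

__all__ = [
    "SuperpositionResult",
    "kabsch_superpose",
    "superpose_ensemble",
    "rmsd",
    "rmsd_series",
    "DistanceSeries",
    "distance_series",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid transform ``x -> x @ rotation.T + translation`` (A)."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)
    rmsd_after_fit: float  # over the fit atoms, A

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _as_indices(fit) -> np.ndarray:
    if isinstance(fit, ResidueSelection):
        return fit.atom_indices
    return np.asarray(fit, dtype=int)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, fit) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    ``fit`` selects the atoms that define the transform (>= 3, non-collinear).
    The returned transform minimises the RMSD of the fit atoms and can be
    applied to the full mobile frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _as_indices(fit)
    if len(idx) < 3:
        raise ValueError(f"need >= 3 fit atoms, got {len(idx)}")
    mob = mobile[idx]
    ref = reference[idx]
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    p = mob - mob_c
    q = ref - ref_c
    # Collinear points leave the rotation about their axis undetermined.
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear or degenerate")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mob_c
    fitted = p @ rot.T + ref_c
    value = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rot, trans, value)


def superpose_ensemble(ensemble: CoordinateEnsemble, reference: np.ndarray,
                       fit) -> CoordinateEnsemble:
    """Fit every frame onto ``reference`` using the fit selection."""
    out = np.empty_like(ensemble.coords)
    for i, frame in enumerate(ensemble.coords):
        sup = kabsch_superpose(frame, reference, fit)
        out[i] = sup.apply(frame)
    return CoordinateEnsemble(out, ensemble.atom_table, ensemble.frame_times)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(ensemble: CoordinateEnsemble, reference: np.ndarray | None,
                fit, measure) -> np.ndarray:
    """Per-frame RMSD (A) over ``measure`` after fitting each frame on ``fit``.

    ``reference`` defaults to the first ensemble frame (use a minimised
    structure's coordinates to reproduce a reference-based series).
    """
    midx = _as_indices(measure)
    if len(midx) == 0:
        raise ValueError("empty measure selection")
    ref = ensemble.frame(0) if reference is None else np.asarray(reference, dtype=float)
    out = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.coords):
        sup = kabsch_superpose(frame, ref, fit)
        fitted = sup.apply(frame)
        out[i] = rmsd(fitted[midx], ref[midx])
    return out


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame scalar distance (A) between two atom sets."""

    values: np.ndarray  # (F,)
    set_a: tuple
    set_b: tuple
    rule: str  # "pair" or "min"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("distances must be positive and finite")
        object.__setattr__(self, "values", v)


def distance_series(ensemble: CoordinateEnsemble, set_a, set_b,
                    rule: str = "min") -> DistanceSeries:
    """Distance monitor between two disjoint atom sets.

    ``rule="pair"`` requires singleton sets; ``rule="min"`` takes the minimum
    over all cross-set atom pairs in each frame (the usual side-chain
    contact-distance convention).
    """
    ia = np.asarray(set_a, dtype=int)
    ib = np.asarray(set_b, dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("atom sets must be non-empty")
    if set(ia.tolist()) & set(ib.tolist()):
        raise ValueError("atom sets overlap")
    if rule == "pair":
        if len(ia) != 1 or len(ib) != 1:
            raise ValueError('rule "pair" requires singleton sets')
        diff = ensemble.coords[:, ia[0], :] - ensemble.coords[:, ib[0], :]
        values = np.sqrt(np.sum(diff**2, axis=1))
    elif rule == "min":
        values = np.array(
            [cdist(frame[ia], frame[ib]).min() for frame in ensemble.coords]
        )
    else:
        raise ValueError(f"unknown distance rule {rule!r}")
    return DistanceSeries(values, tuple(ia.tolist()), tuple(ib.tolist()), rule)
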