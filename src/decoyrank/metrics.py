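"""Structural distance measures: superposed RMSD and TM-score.

RMSD is the root-mean-square CA deviation after an optimal rigid-body
(Kabsch) superposition; reflections are excluded.  TM-score is the
length-normalised similarity

    TM = max over superpositions of (1/L_n) Σ_i 1 / (1 + (d_i / d0)²),

maximised with the classic fragment-seeded heuristic: superpositions are
seeded from contiguous fragments, then iteratively refitted on the residues
closer than a shrinking distance cutoff until the included set is stable, and
the best full-length score over all seeds and cutoffs is kept.  Decoys of one
protein share the native's length and residue order, so the alignment is
positional and the aligned length always equals the native length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DimensionMismatchError
from .structure_io import StructureModel

__all__ = [
    "Superposition",
    "TMScoreParams",
    "d0_from_length",
    "superpose",
    "rmsd",
    "tm_score",
]


@dataclass
class Superposition:
    """An optimal rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float  # Å at the optimum

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class TMScoreParams:
    """TM-score normalisation parameters.

    ``L_n`` is the native sequence length, ``L_a`` the aligned length
    (positional correspondence forces ``L_a == L_n`` here) and ``d0`` the
    length-dependent distance scale in Å.
    """

    L_n: int
    L_a: int
    d0: float

    def __post_init__(self) -> None:
        if self.L_a > self.L_n:
            raise DimensionMismatchError("L_a cannot exceed L_n")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


def d0_from_length(L_n: int) -> float:
    """Standard TM-score distance scale: 1.24·(L_n − 15)^⅓ − 1.8, floored at 0.5 Å."""
    if L_n > 15:
        d0 = 1.24 * (L_n - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _as_coords(s) -> np.ndarray:
    if isinstance(s, StructureModel):
        return s.coords
    return np.asarray(s, dtype=float)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimising ‖(P@Rᵀ+t) − Q‖.

    P is the mobile point set, Q the reference; both (N, 3).
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(mobile, reference) -> Superposition:
    """Least-squares rigid-body fit of *mobile* onto *reference* (Kabsch/SVD)."""
    P, Q = _as_coords(mobile), _as_coords(reference)
    if P.shape != Q.shape:
        raise DimensionMismatchError(
            f"cannot superpose {P.shape[0]} onto {Q.shape[0]} residues"
        )
    if P.shape[0] < 3:
        raise DimensionMismatchError("superposition needs at least 3 points")
    R, t = _kabsch(P, Q)
    diff = P @ R.T + t - Q
    value = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return Superposition(rotation=R, translation=t, rmsd=value)


def rmsd(a, b, superpose_first: bool = True) -> float:
    """Root-mean-square CA deviation between two equal-length structures.

    With ``superpose_first`` (the default) the minimised value over rigid
    motions is returned; otherwise coordinates are compared as given.
    """
    P, Q = _as_coords(a), _as_coords(b)
    if P.shape != Q.shape:
        raise DimensionMismatchError(
            f"rmsd requires equal residue counts, got {P.shape[0]} and {Q.shape[0]}"
        )
    if superpose_first:
        return superpose(P, Q).rmsd
    diff = P - Q
    return float(np.sqrt((diff * diff).sum() / P.shape[0]))


def _tm_sum(model: np.ndarray, native: np.ndarray, R: np.ndarray,
            t: np.ndarray, d0: float) -> float:
    d2 = ((model @ R.T + t - native) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / (d0 * d0))).sum())


def _weighted_kabsch(P: np.ndarray, Q: np.ndarray, w: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    wsum = w.sum()
    pc = (w[:, None] * P).sum(axis=0) / wsum
    qc = (w[:, None] * Q).sum(axis=0) / wsum
    H = (w[:, None] * (P - pc)).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return R, t


def _polish_tm(P: np.ndarray, Q: np.ndarray, R: np.ndarray, t: np.ndarray,
               d0: float, max_iter: int = 60, tol: float = 1e-10) -> float:
    """Monotone ascent on the TM objective by reweighted superposition.

    Each per-residue term 1/(1 + d²/d0²) is convex and decreasing in d², so
    its tangent at the current distances is a global lower bound; maximising
    the tangent sum is a weighted least-squares superposition with weights
    1/(1 + d²/d0²)².  Iterating is a majorise-minimise scheme whose fixed
    points are stationary points of the TM objective.
    """
    d0sq = d0 * d0
    score = _tm_sum(P, Q, R, t, d0)
    for _ in range(max_iter):
        d2 = ((P @ R.T + t - Q) ** 2).sum(axis=1)
        w = 1.0 / (1.0 + d2 / d0sq) ** 2
        R, t = _weighted_kabsch(P, Q, w)
        new_score = _tm_sum(P, Q, R, t, d0)
        if new_score - score <= tol:
            score = max(score, new_score)
            break
        score = new_score
    return score


def tm_score(model, native, params: Optional[TMScoreParams] = None,
             max_iter: int = 20) -> float:
    """TM-score of *model* against *native* (positional correspondence).

    Superpositions are seeded from non-overlapping contiguous fragments of
    lengths L, L/2 and L/4 (minimum 4 residues).  Each seed is refined by
    repeatedly superposing on the residues within a distance cutoff, for a
    cutoff schedule starting at d0 and decreasing in 0.5 Å steps to 1.0 Å,
    until the included-residue set is stable.  The best seed superpositions
    are then polished by directly maximising the TM objective over the six
    rigid-motion parameters (the optimum is generally not the least-squares
    fit of any residue subset).  Deterministic.
    """
    P, Q = _as_coords(model), _as_coords(native)
    if P.shape != Q.shape:
        raise DimensionMismatchError(
            f"tm_score requires equal residue counts, got {P.shape[0]} and {Q.shape[0]}"
        )
    L = Q.shape[0]
    if params is None:
        params = TMScoreParams(L_n=L, L_a=L, d0=d0_from_length(L))
    d0 = params.d0

    cutoffs = [max(c, 1.0) for c in np.arange(d0, 0.99, -0.5)]
    if not cutoffs:
        cutoffs = [1.0]

    frag_lengths = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    seed_bests: list[tuple[float, np.ndarray, np.ndarray]] = []
    for flen in frag_lengths:
        for start in range(0, L - flen + 1, flen):
            seed = np.arange(start, start + flen)
            seed_best = (-1.0, None, None)
            for cutoff in cutoffs:
                sel = seed
                for _ in range(max_iter):
                    R, t = _kabsch(P[sel], Q[sel])
                    s = _tm_sum(P, Q, R, t, d0)
                    if s > seed_best[0]:
                        seed_best = (s, R, t)
                    d2 = ((P @ R.T + t - Q) ** 2).sum(axis=1)
                    new_sel = np.flatnonzero(d2 < cutoff * cutoff)
                    if len(new_sel) < 4:
                        new_sel = np.argsort(d2)[:4]
                        new_sel.sort()
                    if np.array_equal(new_sel, sel):
                        break
                    sel = new_sel
            seed_bests.append(seed_best)

    best = max(s for s, _, _ in seed_bests)
    # The optimal superposition is generally not the least-squares fit of any
    # residue subset, so polish every seed's best superposition by a direct
    # monotone ascent on the TM objective (cheap closed-form steps).
    for s, R, t in seed_bests:
        if R is None:
            continue
        best = max(best, _polish_tm(P, Q, R, t, d0))
    return min(best / L, 1.0)
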