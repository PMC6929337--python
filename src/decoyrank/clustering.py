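"""SPICKER-style shrinking-scale clustering of a decoy set.

The clustering distance is superposed CA RMSD.  Clusters are extracted
iteratively: at each round a distance cutoff d_c is chosen from a shrinking
set of scales so that the densest neighbourhood covers a target fraction of
the decoys still unassigned; the decoy with the most neighbours within d_c
becomes the next cluster centroid, its neighbourhood becomes the cluster, and
the members are removed (hard clustering).  The top-K clusters ranked by size
are the candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, InsufficientClustersError
from .metrics import rmsd
from .structure_io import DecoySet, StructureModel

__all__ = [
    "ClusterConfig",
    "Cluster",
    "CandidateSet",
    "pairwise_rmsd_matrix",
    "spicker_cluster",
    "select_candidates",
    "read_candidate_table",
]


@dataclass
class ClusterConfig:
    """Shrinking-scale search parameters.

    d_c is scanned over ``n_scales`` evenly spaced values in
    ``[d_min, d_max]`` (Å); the smallest scale whose densest neighbourhood
    covers at least ``target_fraction`` of the remaining decoys is used, else
    ``d_max``.
    """

    d_min: float = 1.0
    d_max: float = 8.0
    n_scales: int = 40
    target_fraction: float = 0.15

    def scales(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_scales)


@dataclass
class Cluster:
    """One decoy cluster: a centroid and its members (centroid included)."""

    centroid_id: str
    member_ids: list[str]
    #: mean superposed RMSD between the centroid and the other members (Å)
    centroid_mean_rmsd: float = 0.0
    #: the d_c at which the cluster was formed (Å); informational
    cutoff: float = float("nan")

    def __post_init__(self) -> None:
        if self.centroid_id not in self.member_ids:
            raise ValueError("centroid must be one of its cluster's members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class CandidateSet:
    """Top-K clusters of one protein, ordered by decreasing size."""

    protein_id: str
    clusters: list[Cluster]
    K: int = field(default=0)

    def __post_init__(self) -> None:
        if self.K == 0:
            self.K = len(self.clusters)
        if len(self.clusters) != self.K:
            raise ValueError(
                f"{self.protein_id}: {len(self.clusters)} clusters for K={self.K}"
            )
        sizes = [c.size for c in self.clusters]
        if sizes != sorted(sizes, reverse=True):
            raise ValueError(f"{self.protein_id}: clusters not sorted by size")
        seen: set[str] = set()
        for c in self.clusters:
            overlap = seen.intersection(c.member_ids)
            if overlap:
                raise ValueError(
                    f"{self.protein_id}: decoys in two clusters: {sorted(overlap)}"
                )
            seen.update(c.member_ids)

    def centroid_ids(self) -> list[str]:
        return [c.centroid_id for c in self.clusters]


def pairwise_rmsd_matrix(decoys: DecoySet) -> np.ndarray:
    """Symmetric matrix of superposed CA RMSDs between all decoy pairs.

    Uses a batched Kabsch solution: for centred coordinate sets P, Q with
    cross-covariance H = PᵀQ and singular values σ (sign-corrected for proper
    rotations), min Σ‖RP − Q‖² = ‖P‖² + ‖Q‖² − 2Σσ.
    """
    n = len(decoys.decoys)
    if n < 2:
        raise DegenerateInputError("pairwise RMSD needs at least 2 decoys")
    coords = np.stack([d.coords for d in decoys.decoys])  # (n, L, 3)
    L = coords.shape[1]
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq_norm = (centred ** 2).sum(axis=(1, 2))  # (n,)

    ii, jj = np.triu_indices(n, k=1)
    H = np.einsum("pki,pkj->pij", centred[ii], centred[jj])  # (m, 3, 3)
    sigma = np.linalg.svd(H, compute_uv=False)  # descending
    det = np.linalg.det(H)
    # proper-rotation correction: flip the smallest singular value when det<0
    trace = sigma.sum(axis=1) - 2.0 * sigma[:, 2] * (det < 0)
    msd = np.maximum(sq_norm[ii] + sq_norm[jj] - 2.0 * trace, 0.0) / L
    mat = np.zeros((n, n))
    mat[ii, jj] = mat[jj, ii] = np.sqrt(msd)
    return mat


def spicker_cluster(
    decoys: DecoySet,
    K: int = 5,
    config: Optional[ClusterConfig] = None,
    rmsd_matrix: Optional[np.ndarray] = None,
) -> CandidateSet:
    """Cluster a decoy set and return the top-K size-ranked clusters.

    Raises :class:`InsufficientClustersError` when fewer than K clusters can
    be formed (decoys exhausted first).
    """
    if K < 1:
        raise DegenerateInputError("K must be >= 1")
    config = config or ClusterConfig()
    ids = decoys.decoy_ids()
    n = len(ids)
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(decoys)
    scales = config.scales()

    remaining = list(range(n))
    clusters: list[Cluster] = []
    while len(clusters) < K and remaining:
        sub = rmsd_matrix[np.ix_(remaining, remaining)]
        m = len(remaining)
        target = config.target_fraction * m
        d_c = scales[-1]
        for scale in scales:
            counts = (sub <= scale).sum(axis=1)  # includes self
            if counts.max() >= target:
                d_c = scale
                break
        counts = (sub <= d_c).sum(axis=1)
        # max-neighbour decoy wins; ties resolved by lexicographic decoy id
        best_count = counts.max()
        tied = [k for k in range(m) if counts[k] == best_count]
        centre_local = min(tied, key=lambda k: ids[remaining[k]])
        member_local = np.flatnonzero(sub[centre_local] <= d_c)
        member_global = [remaining[k] for k in member_local]
        centroid_global = remaining[centre_local]
        others = [g for g in member_global if g != centroid_global]
        mean_r = float(np.mean(rmsd_matrix[centroid_global, others])) if others else 0.0
        clusters.append(
            Cluster(
                centroid_id=ids[centroid_global],
                member_ids=[ids[g] for g in member_global],
                centroid_mean_rmsd=mean_r,
                cutoff=float(d_c),
            )
        )
        remaining = [g for g in remaining if g not in set(member_global)]

    if len(clusters) < K:
        raise InsufficientClustersError(formed=len(clusters), requested=K)

    clusters.sort(key=lambda c: (-c.size, c.centroid_mean_rmsd, c.centroid_id))
    return CandidateSet(protein_id=decoys.protein_id, clusters=clusters, K=K)


def select_candidates(
    candidate_set: CandidateSet, decoys: DecoySet
) -> list[tuple[StructureModel, Cluster]]:
    """Resolve the ordered (centroid structure, cluster) pairs of a candidate set.

    Clusters are in size order; equal sizes are broken by lower centroid mean
    intra-cluster RMSD, then lexicographic centroid id (the order already
    enforced by :class:`CandidateSet` construction).
    """
    ordered = sorted(
        candidate_set.clusters,
        key=lambda c: (-c.size, c.centroid_mean_rmsd, c.centroid_id),
    )
    return [(decoys.decoy_by_id(c.centroid_id), c) for c in ordered]


def read_candidate_table(path, decoys: DecoySet, K: Optional[int] = None
                         ) -> CandidateSet:
    """Ingest an external clustering result as a candidate set.

    The table is a headerless whitespace/tab-separated text file with one row
    per candidate: ``rank  decoy_filename  cluster_size``, as produced by
    external clustering tools.  Cluster membership is not part of such tables,
    so every decoy is assigned to its nearest declared centroid by superposed
    RMSD (documented approximation).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'rank file size' columns")
        rows.append((int(tokens[0]), Path(tokens[1]).stem, int(tokens[2])))
    rows.sort()
    if K is not None:
        rows = rows[:K]
    centroid_ids = [r[1] for r in rows]
    for cid in centroid_ids:  # fail fast on unknown decoys
        decoys.decoy_by_id(cid)

    assignment: dict[str, list[str]] = {cid: [] for cid in centroid_ids}
    for d in decoys.decoys:
        nearest = min(centroid_ids,
                      key=lambda cid: (rmsd(d, decoys.decoy_by_id(cid)), cid))
        assignment[nearest].append(d.id)
    clusters = []
    for cid in centroid_ids:
        members = assignment[cid]
        if cid not in members:
            members.append(cid)
        others = [m for m in members if m != cid]
        mean_r = (
            float(np.mean([rmsd(decoys.decoy_by_id(cid), decoys.decoy_by_id(m))
                           for m in others]))
            if others else 0.0
        )
        clusters.append(Cluster(centroid_id=cid, member_ids=members,
                                centroid_mean_rmsd=mean_r))
    clusters.sort(key=lambda c: (-c.size, c.centroid_mean_rmsd, c.centroid_id))
    return CandidateSet(protein_id=decoys.protein_id, clusters=clusters,
                        K=len(clusters))
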