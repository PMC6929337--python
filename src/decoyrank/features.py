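"""Candidate feature vectors: protein, intra-cluster and inter-cluster blocks.

Each of the K candidate models gets a vector of length ``6 + MAXN × M``:

1. protein sequence length,
2. the PSSM flattened row-major to ``MAXN × M`` values (zero-padded beyond
   the protein length, truncated to the first MAXN rows for longer chains),
3. cluster size,
4. mean RMSD between the cluster centroid and the remaining cluster members,
5. mean TM-score between the centroid and the remaining members,
6. mean RMSD between this centroid and the other K−1 centroids,
7. mean TM-score between this centroid and the other K−1 centroids.

When the native structure is known, the candidate with the minimum
RMSD-to-native among the current candidates is labelled 1, all others 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import CandidateSet, Cluster, select_candidates
from .errors import ConfigurationError, DegenerateInputError
from .metrics import rmsd, tm_score
from .structure_io import DecoySet, PSSMProfile, StructureModel

__all__ = [
    "FeatureSpec",
    "FeatureVector",
    "encode_pssm",
    "intra_cluster_stats",
    "inter_cluster_stats",
    "build_feature_vector",
    "build_feature_matrix",
    "assign_labels",
    "feature_names",
    "matrix_to_tsv",
]


@dataclass(frozen=True)
class FeatureSpec:
    """Shape of the feature encoding: MAXN residue rows × M profile columns."""

    maxn: int = 200
    m: int = 20

    @property
    def vector_length(self) -> int:
        return 6 + self.maxn * self.m


@dataclass
class FeatureVector:
    """One candidate's features, serialisable to a flat numeric vector."""

    protein_id: str
    candidate_id: str
    protein_length: int
    pssm_flat: np.ndarray
    cluster_size: int
    intra_avg_rmsd: float
    intra_avg_tm: float
    inter_avg_rmsd: float
    inter_avg_tm: float
    label: Optional[int] = None
    rmsd_to_native: Optional[float] = None

    def values(self, spec: FeatureSpec) -> np.ndarray:
        if self.pssm_flat.shape[0] != spec.maxn * spec.m:
            raise ConfigurationError(
                f"PSSM block has {self.pssm_flat.shape[0]} values, spec wants "
                f"{spec.maxn * spec.m}"
            )
        scalars_tail = [
            self.cluster_size,
            self.intra_avg_rmsd,
            self.intra_avg_tm,
            self.inter_avg_rmsd,
            self.inter_avg_tm,
        ]
        return np.concatenate(
            [[float(self.protein_length)], self.pssm_flat.astype(float), scalars_tail]
        )


def feature_names(spec: FeatureSpec) -> list[str]:
    """Column names for a serialised feature matrix (length ``6 + MAXN×M``)."""
    names = ["protein_length"]
    names += [f"pssm_{i}_{j}" for i in range(spec.maxn) for j in range(spec.m)]
    names += ["cluster_size", "intra_avg_rmsd", "intra_avg_tm",
              "inter_avg_rmsd", "inter_avg_tm"]
    return names


def encode_pssm(pssm: PSSMProfile, spec: FeatureSpec) -> np.ndarray:
    """Row-major flattening of the profile to exactly MAXN×M values.

    Rows beyond the protein length are zero; proteins longer than MAXN keep
    only their first MAXN rows.
    """
    scores = pssm.scores[:, : spec.m]
    out = np.zeros((spec.maxn, spec.m))
    n = min(pssm.length, spec.maxn)
    out[:n] = scores[:n]
    return out.ravel()


def intra_cluster_stats(
    centroid: StructureModel, members: Sequence[StructureModel]
) -> tuple[float, float]:
    """Mean centroid-vs-member RMSD and TM-score.

    *members* excludes the centroid itself.  A singleton cluster returns
    (0, 1) by convention: the centroid is its own perfect neighbour.
    """
    if not members:
        return 0.0, 1.0
    rmsds = [rmsd(m, centroid) for m in members]
    tms = [tm_score(m, centroid) for m in members]
    return float(np.mean(rmsds)), float(np.mean(tms))


def inter_cluster_stats(
    centroid: StructureModel, other_centroids: Sequence[StructureModel]
) -> tuple[float, float]:
    """Mean RMSD and TM-score between a centroid and the other K−1 centroids."""
    if not other_centroids:
        raise DegenerateInputError(
            "inter-cluster statistics need at least one other centroid (K >= 2)"
        )
    rmsds = [rmsd(centroid, o) for o in other_centroids]
    tms = [tm_score(centroid, o) for o in other_centroids]
    return float(np.mean(rmsds)), float(np.mean(tms))


def build_feature_vector(
    candidate: tuple[StructureModel, Cluster],
    decoy_set: DecoySet,
    candidate_set: CandidateSet,
    spec: FeatureSpec,
    require_pssm: bool = True,
) -> FeatureVector:
    """Assemble the feature vector for one candidate of a candidate set.

    The label is not set here; labels depend on which candidates are still in
    play at a cascade stage (see :func:`build_feature_matrix`).
    """
    centroid, cluster = candidate
    if cluster.centroid_id not in candidate_set.centroid_ids():
        raise ConfigurationError(
            f"candidate {cluster.centroid_id} does not belong to the candidate set"
        )
    if decoy_set.pssm is None:
        if require_pssm:
            raise ConfigurationError(
                f"{decoy_set.protein_id}: no PSSM available; pass "
                "require_pssm=False to encode a zero profile block"
            )
        pssm_flat = np.zeros(spec.maxn * spec.m)
    else:
        pssm_flat = encode_pssm(decoy_set.pssm, spec)

    members = [
        decoy_set.decoy_by_id(mid)
        for mid in cluster.member_ids
        if mid != cluster.centroid_id
    ]
    intra_rmsd, intra_tm = intra_cluster_stats(centroid, members)
    others = [
        decoy_set.decoy_by_id(cid)
        for cid in candidate_set.centroid_ids()
        if cid != cluster.centroid_id
    ]
    inter_rmsd, inter_tm = inter_cluster_stats(centroid, others)

    rmsd_native = (
        rmsd(centroid, decoy_set.native) if decoy_set.native is not None else None
    )
    return FeatureVector(
        protein_id=decoy_set.protein_id,
        candidate_id=cluster.centroid_id,
        protein_length=decoy_set.length,
        pssm_flat=pssm_flat,
        cluster_size=cluster.size,
        intra_avg_rmsd=intra_rmsd,
        intra_avg_tm=intra_tm,
        inter_avg_rmsd=inter_rmsd,
        inter_avg_tm=inter_tm,
        rmsd_to_native=rmsd_native,
    )


def assign_labels(vectors: Sequence[FeatureVector]) -> None:
    """Set label 1 on the candidate with minimum RMSD-to-native, 0 elsewhere.

    Ties go to the earlier-ranked (larger-cluster) candidate, which is the
    earlier list position.
    """
    if any(v.rmsd_to_native is None for v in vectors):
        raise ConfigurationError("labels require RMSD-to-native for all candidates")
    best = min(range(len(vectors)), key=lambda i: (vectors[i].rmsd_to_native, i))
    for i, v in enumerate(vectors):
        v.label = 1 if i == best else 0


def build_feature_matrix(
    decoy_set: DecoySet,
    candidate_set: CandidateSet,
    spec: FeatureSpec,
    require_pssm: bool = True,
) -> list[FeatureVector]:
    """Feature vectors for all K candidates, in candidate (size-rank) order.

    When the native structure is present, labels are assigned among the full
    candidate set (exactly one label 1).
    """
    pairs = select_candidates(candidate_set, decoy_set)
    vectors = [
        build_feature_vector(pair, decoy_set, candidate_set, spec, require_pssm)
        for pair in pairs
    ]
    if decoy_set.native is not None:
        assign_labels(vectors)
    return vectors


def matrix_to_tsv(vectors: Sequence[FeatureVector], spec: FeatureSpec, path) -> None:
    """Write a feature matrix as TSV, one row per candidate, named columns."""
    import pandas as pd

    data = pd.DataFrame(
        [v.values(spec) for v in vectors], columns=feature_names(spec)
    )
    data.insert(0, "candidate_id", [v.candidate_id for v in vectors])
    data.insert(0, "protein_id", [v.protein_id for v in vectors])
    if all(v.label is not None for v in vectors):
        data["label"] = [v.label for v in vectors]
    data.to_csv(path, sep="\t", index=False)
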