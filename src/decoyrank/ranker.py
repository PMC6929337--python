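"""Sequential binary random-forest cascade for candidate re-ranking.

K candidate models per protein are ranked by K−1 binary forests applied in
order: stage 1 scores all K candidates and the highest class-1 probability
takes position 1; stage 2 scores the remaining K−1; the final leftover
candidate takes position K.  During training, stage s sees — per protein —
the candidates not yet consumed by earlier stages (the true minimum
RMSD-to-native candidate is removed at each stage) with labels recomputed
among the remainder, and the minority positive class is balanced by
oversampling.

Trees split continuous features by dichotomy thresholds chosen to maximise
the Shannon-entropy information gain; each forest bags 100 trees with √D
feature subsampling per split (scikit-learn ``RandomForestClassifier`` with
``criterion="entropy"``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .clustering import CandidateSet
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionMismatchError,
)
from .features import FeatureSpec, FeatureVector, build_feature_matrix
from .structure_io import DecoySet

__all__ = [
    "TrainingSample",
    "CascadeConfig",
    "CascadeModel",
    "entropy",
    "oversample",
    "train_stage",
    "train_cascade",
    "rerank",
    "save_model",
    "load_model",
]

_ARCHIVE_FORMAT = "decoyrank-cascade-v1"

logger = logging.getLogger(__name__)


def entropy(class_proportions: Sequence[float]) -> float:
    """Shannon entropy −Σ Pᵢ log₂ Pᵢ in bits, with 0·log 0 = 0.

    Proportions must be non-negative and sum to 1 (tolerance 1e-9).
    """
    p = np.asarray(class_proportions, dtype=float)
    if p.size == 0:
        raise DegenerateInputError("entropy of an empty distribution")
    if np.any(p < 0):
        raise ValueError("class proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


@dataclass
class TrainingSample:
    """One labelled candidate: feature values x, class y ∈ {0, 1}."""

    x: np.ndarray
    y: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.y}")
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class CascadeConfig:
    """Cascade hyper-parameters.

    ``n_trees`` is the forest size (100 by default), ``K`` the number of
    candidates per protein; the stopping controls are passed through to the
    underlying trees.
    """

    n_trees: int = 100
    K: int = 5
    oversample: bool = True
    seed: int = 0
    max_depth: Optional[int] = None
    min_samples_leaf: int = 1
    impurity_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.K < 2:
            raise ConfigurationError("K must be >= 2")

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        return int(
            np.random.SeedSequence([self.seed, stage]).generate_state(1)[0]
            % (2**31 - 1)
        )


@dataclass
class CascadeModel:
    """K−1 trained stage forests plus the feature specification behind them."""

    stages: list[RandomForestClassifier]
    spec: FeatureSpec
    config: CascadeConfig

    def __post_init__(self) -> None:
        if len(self.stages) != self.config.K - 1:
            raise ConfigurationError(
                f"{len(self.stages)} stages for K={self.config.K}; need K-1"
            )


def oversample(
    samples: Sequence[TrainingSample], seed: int
) -> list[TrainingSample]:
    """Balance classes by duplicating class-1 samples with replacement.

    The class-0 multiset is untouched; class-1 samples are drawn with
    replacement (deterministically for a given seed) until both classes have
    equal counts.  Already-balanced input is returned unchanged.
    """
    positives = [s for s in samples if s.y == 1]
    negatives = [s for s in samples if s.y == 0]
    if not positives or not negatives:
        raise DegenerateInputError(
            "oversampling needs both classes present "
            f"(got {len(positives)} positive, {len(negatives)} negative)"
        )
    deficit = len(negatives) - len(positives)
    if deficit <= 0:
        return list(samples)
    rng = np.random.default_rng(seed)
    extra_idx = rng.integers(0, len(positives), size=deficit)
    return list(samples) + [positives[i] for i in extra_idx]


def _make_forest(config: CascadeConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="entropy",
        max_features="sqrt",
        bootstrap=True,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        min_impurity_decrease=config.impurity_threshold,
        random_state=seed,
        n_jobs=1,
    )


def train_stage(
    samples: Sequence[TrainingSample],
    config: CascadeConfig,
    seed: Optional[int] = None,
) -> RandomForestClassifier:
    """Fit one binary stage forest on (optionally oversampled) samples."""
    if seed is None:
        seed = config.seed
    work = list(samples)
    if config.oversample:
        work = oversample(work, seed=seed)
    labels = {s.y for s in work}
    if labels != {0, 1}:
        raise DegenerateInputError(
            f"stage training needs both classes, got labels {sorted(labels)}"
        )
    X = np.stack([s.x for s in work])
    y = np.array([s.y for s in work])
    forest = _make_forest(config, seed)
    forest.fit(X, y)
    return forest


def positive_probability(
    forest: RandomForestClassifier, X: np.ndarray
) -> np.ndarray:
    """Class-1 probability (fraction of trees voting 1) for each row of X."""
    proba = forest.predict_proba(np.atleast_2d(X))
    idx = list(forest.classes_).index(1)
    return proba[:, idx]


def _stage_samples(
    per_protein: list[tuple[str, np.ndarray, np.ndarray]]
) -> tuple[list[TrainingSample], list[tuple[str, np.ndarray, np.ndarray]]]:
    """Build stage samples and the per-protein remainder for the next stage.

    ``per_protein`` holds (protein_id, X of remaining candidates, their
    RMSD-to-native).  Labels are recomputed among the remainder: argmin RMSD
    gets 1.  The true best candidate is then removed for the next stage.
    """
    samples = []
    remainder = []
    for pid, X, r in per_protein:
        best = int(np.argmin(r))
        for i in range(X.shape[0]):
            samples.append(TrainingSample(x=X[i], y=int(i == best), protein_id=pid))
        keep = [i for i in range(X.shape[0]) if i != best]
        remainder.append((pid, X[keep], r[keep]))
    return samples, remainder


def train_cascade(
    dataset: Sequence[tuple[DecoySet, CandidateSet]],
    config: CascadeConfig,
    spec: Optional[FeatureSpec] = None,
    require_pssm: bool = True,
    feature_cache: Optional[dict] = None,
) -> CascadeModel:
    """Train the K−1 stage forests on a list of (decoy set, candidate set).

    Every decoy set must carry a native structure — stage labels are derived
    from RMSD-to-native.  ``feature_cache`` may map protein_id to a
    precomputed list of :class:`FeatureVector` (as returned by
    :func:`decoyrank.features.build_feature_matrix`) to avoid recomputing
    structural features.
    """
    spec = spec or FeatureSpec()
    if len(dataset) < 2:
        warnings.warn(
            "training on fewer than 2 proteins; the cascade will almost "
            "certainly overfit", stacklevel=2,
        )
    per_protein = []
    for decoy_set, candidate_set in dataset:
        if decoy_set.native is None:
            raise ConfigurationError(
                f"{decoy_set.protein_id}: training requires a native structure"
            )
        if candidate_set.K != config.K:
            raise DimensionMismatchError(
                f"{decoy_set.protein_id}: candidate set has K={candidate_set.K}, "
                f"cascade expects K={config.K}"
            )
        if feature_cache is not None and decoy_set.protein_id in feature_cache:
            vectors: list[FeatureVector] = feature_cache[decoy_set.protein_id]
        else:
            vectors = build_feature_matrix(
                decoy_set, candidate_set, spec, require_pssm=require_pssm
            )
            if feature_cache is not None:
                feature_cache[decoy_set.protein_id] = vectors
        X = np.stack([v.values(spec) for v in vectors])
        r = np.array([v.rmsd_to_native for v in vectors])
        per_protein.append((decoy_set.protein_id, X, r))

    stages = []
    for stage in range(config.K - 1):
        samples, per_protein = _stage_samples(per_protein)
        n_pos = sum(s.y for s in samples)
        n_neg = len(samples) - n_pos
        logger.info(
            "stage %d: %d positive / %d negative before oversampling, "
            "%d / %d after",
            stage + 1, n_pos, n_neg,
            max(n_pos, n_neg) if config.oversample else n_pos,
            n_neg,
        )
        stages.append(train_stage(samples, config, seed=config.stage_seed(stage)))
    return CascadeModel(stages=stages, spec=spec, config=config)


def rerank(
    model: CascadeModel, candidates: Sequence[FeatureVector] | np.ndarray
) -> list[int]:
    """Order K candidates by the cascade; returns a permutation of 0..K−1.

    At each stage the remaining candidate with the highest class-1
    probability takes the next position; probability ties are broken by the
    original (cluster-size rank) order.  The last candidate left takes the
    final position.
    """
    if isinstance(candidates, np.ndarray):
        X = np.atleast_2d(candidates)
    else:
        X = np.stack([v.values(model.spec) for v in candidates])
    K = model.config.K
    if X.shape[0] != K:
        raise DimensionMismatchError(
            f"expected {K} candidates, got {X.shape[0]}"
        )
    if X.shape[1] != model.spec.vector_length:
        raise DimensionMismatchError(
            f"feature length {X.shape[1]} does not match spec "
            f"{model.spec.vector_length}"
        )
    remaining = list(range(K))
    order = []
    for forest in model.stages:
        p = positive_probability(forest, X[remaining])
        # argmax with ties to the earlier-ranked candidate
        pick = int(np.argmax(p))
        order.append(remaining.pop(pick))
    order.extend(remaining)
    return order


def rerank_probabilities(
    model: CascadeModel, candidates: Sequence[FeatureVector] | np.ndarray
) -> tuple[list[int], list[float]]:
    """Like :func:`rerank` but also returns the winning stage probability
    for each assigned position (1.0 for the leftover last position)."""
    if isinstance(candidates, np.ndarray):
        X = np.atleast_2d(candidates)
    else:
        X = np.stack([v.values(model.spec) for v in candidates])
    remaining = list(range(model.config.K))
    order, probs = [], []
    for forest in model.stages:
        p = positive_probability(forest, X[remaining])
        pick = int(np.argmax(p))
        probs.append(float(p[pick]))
        order.append(remaining.pop(pick))
    order.extend(remaining)
    probs.extend([1.0] * (len(order) - len(probs)))
    return order, probs


def save_model(model: CascadeModel, path) -> None:
    """Serialise a cascade (config, feature spec and forests) to one file."""
    payload = {
        "format": _ARCHIVE_FORMAT,
        "spec": {"maxn": model.spec.maxn, "m": model.spec.m},
        "config": model.config,
        "stages": model.stages,
    }
    joblib.dump(payload, path)


def load_model(path) -> CascadeModel:
    payload = joblib.load(path)
    if payload.get("format") != _ARCHIVE_FORMAT:
        raise ConfigurationError(
            f"{path}: not a decoyrank cascade archive "
            f"(format={payload.get('format')!r})"
        )
    spec = FeatureSpec(**payload["spec"])
    return CascadeModel(stages=payload["stages"], spec=spec,
                        config=payload["config"])
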