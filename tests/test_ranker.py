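"""Entropy, oversampling, stage forests and the re-ranking cascade."""

import numpy as np
import pytest

from decoyrank.errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionMismatchError,
)
from decoyrank.features import FeatureSpec
from decoyrank.ranker import (
    CascadeConfig,
    CascadeModel,
    TrainingSample,
    entropy,
    load_model,
    oversample,
    positive_probability,
    rerank,
    save_model,
    train_stage,
)

# ---------------------------------------------------------------------------
# entropy


@pytest.mark.parametrize(
    "proportions, expected",
    [
        ([0.5, 0.5], 1.0),
        ([1.0, 0.0], 0.0),
        ([0.25, 0.75], 0.8112781244591328),  # closed form -sum p log2 p
        ([0.25, 0.25, 0.25, 0.25], 2.0),
    ],
)
def test_entropy_values(proportions, expected):
    assert entropy(proportions) == pytest.approx(expected, abs=1e-9)


def test_entropy_bounds_and_domain():
    rng = np.random.default_rng(3)
    for c in (2, 3, 5):
        p = rng.dirichlet(np.ones(c))
        h = entropy(p)
        assert 0.0 <= h <= np.log2(c) + 1e-12
    assert entropy(np.ones(4) / 4) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        entropy([0.5, 0.6])
    with pytest.raises(ValueError):
        entropy([-0.1, 1.1])


# ---------------------------------------------------------------------------
# oversampling


def _samples(n_pos, n_neg, rng, dim=3):
    out = [TrainingSample(x=rng.normal(size=dim), y=1, protein_id=f"p{i}")
           for i in range(n_pos)]
    out += [TrainingSample(x=rng.normal(size=dim), y=0, protein_id=f"n{i}")
            for i in range(n_neg)]
    return out


def test_oversample_parity(rng):
    balanced = oversample(_samples(1, 4, rng), seed=0)
    ys = [s.y for s in balanced]
    assert ys.count(1) == ys.count(0) == 4


def test_oversample_parity_with_replacement(rng):
    out = oversample(_samples(2, 7, rng), seed=1)
    ys = [s.y for s in out]
    assert ys.count(1) == ys.count(0) == 7
    # duplicates drawn from the 2 originals only
    pos_ids = {s.protein_id for s in out if s.y == 1}
    assert pos_ids <= {"p0", "p1"}


def test_oversample_balanced_unchanged(rng):
    samples = _samples(3, 3, rng)
    assert oversample(samples, seed=0) == samples


def test_oversample_preserves_negative_multiset(rng):
    samples = _samples(2, 9, rng)
    out = oversample(samples, seed=5)
    neg_in = sorted(id(s) for s in samples if s.y == 0)
    neg_out = sorted(id(s) for s in out if s.y == 0)
    assert neg_in == neg_out


def test_oversample_deterministic(rng):
    samples = _samples(2, 9, rng)
    a = oversample(samples, seed=7)
    b = oversample(samples, seed=7)
    assert [s.protein_id for s in a] == [s.protein_id for s in b]


def test_oversample_single_class_error(rng):
    with pytest.raises(DegenerateInputError):
        oversample(_samples(0, 5, rng), seed=0)


# ---------------------------------------------------------------------------
# stage training


def _separable(n, rng, threshold=3.0, dim=6):
    samples = []
    for i in range(n):
        x = rng.uniform(0, 6, size=dim)
        samples.append(TrainingSample(x=x, y=int(x[3] < threshold), protein_id=str(i)))
    return samples


def test_train_stage_separable_accuracy(rng):
    samples = _separable(50, rng)
    config = CascadeConfig(K=5, seed=0)
    forest = train_stage(samples, config)
    X = np.stack([s.x for s in samples])
    y = np.array([s.y for s in samples])
    assert (forest.predict(X) == y).all()


def test_train_stage_null_features_near_chance():
    """Labels independent of features: cross-validated accuracy near 0.5."""
    from sklearn.model_selection import cross_val_score

    rng = np.random.default_rng(2718)
    X = rng.normal(size=(200, 6))
    y = rng.integers(0, 2, size=200)
    samples = [TrainingSample(x=xi, y=int(yi)) for xi, yi in zip(X, y)]
    config = CascadeConfig(K=5, seed=1, oversample=False)
    forest = train_stage(samples, config)
    scores = cross_val_score(forest, X, y, cv=5)
    assert 0.35 <= scores.mean() <= 0.65


def test_train_stage_deterministic(rng):
    samples = _separable(40, rng)
    config = CascadeConfig(K=5, seed=11)
    X = np.stack([s.x for s in samples])
    p1 = positive_probability(train_stage(samples, config), X)
    p2 = positive_probability(train_stage(samples, config), X)
    np.testing.assert_array_equal(p1, p2)


# ---------------------------------------------------------------------------
# rerank


def _toy_cascade(K, rng, spec=None):
    """A cascade whose stages perfectly key on feature 0 (lower = better)."""
    spec = spec or FeatureSpec(maxn=1, m=2)
    stages = []
    config = CascadeConfig(K=K, n_trees=25, seed=3)
    for stage in range(K - 1):
        samples = []
        for _ in range(60):
            vals = rng.uniform(0, 10, size=(K - stage, spec.vector_length))
            best = int(np.argmin(vals[:, 0]))
            for i, v in enumerate(vals):
                samples.append(TrainingSample(x=v, y=int(i == best)))
        stages.append(train_stage(samples, config, seed=stage))
    return CascadeModel(stages=stages, spec=spec, config=config)


def test_rerank_returns_permutation(rng):
    model = _toy_cascade(5, rng)
    for _ in range(5):
        X = rng.uniform(0, 10, size=(5, model.spec.vector_length))
        order = rerank(model, X)
        assert sorted(order) == [0, 1, 2, 3, 4]


def test_rerank_separable_puts_best_first(rng):
    model = _toy_cascade(2, rng)
    X = rng.uniform(0, 10, size=(2, model.spec.vector_length))
    X[0, 0], X[1, 0] = 9.0, 1.0
    assert rerank(model, X)[0] == 1


def test_rerank_deterministic(rng):
    model = _toy_cascade(5, rng)
    X = rng.uniform(0, 10, size=(5, model.spec.vector_length))
    assert rerank(model, X) == rerank(model, X)


def test_rerank_wrong_count_raises(rng):
    model = _toy_cascade(5, rng)
    with pytest.raises(DimensionMismatchError):
        rerank(model, rng.uniform(size=(4, model.spec.vector_length)))


def test_cascade_model_stage_count_invariant(rng):
    model = _toy_cascade(3, rng)
    with pytest.raises(ConfigurationError):
        CascadeModel(stages=model.stages[:1], spec=model.spec,
                     config=model.config)


def test_model_archive_roundtrip(tmp_path, rng):
    model = _toy_cascade(3, rng)
    path = tmp_path / "cascade.joblib"
    save_model(model, path)
    back = load_model(path)
    assert back.config.K == 3 and back.spec == model.spec
    X = rng.uniform(0, 10, size=(3, model.spec.vector_length))
    assert rerank(back, X) == rerank(model, X)


def test_load_model_rejects_foreign_archive(tmp_path):
    import joblib

    path = tmp_path / "foreign.joblib"
    joblib.dump({"format": "something-else"}, path)
    with pytest.raises(ConfigurationError):
        load_model(path)


# ---------------------------------------------------------------------------
# train_cascade on a small synthetic benchmark


def test_train_cascade_structure_and_warning():
    from decoyrank.ranker import train_cascade
    from decoyrank.synthetic import SyntheticConfig, generate_benchmark

    config = SyntheticConfig(n_proteins=3, n_decoys=24,
                             length_range=(20, 30), seed=9)
    bench = generate_benchmark(config, K=3)
    spec = FeatureSpec(maxn=32)
    model = train_cascade(bench, CascadeConfig(K=3, n_trees=20, seed=9),
                          spec=spec)
    assert len(model.stages) == 2  # K-1 forests; the last slot is leftover

    with pytest.warns(UserWarning, match="fewer than 2 proteins"):
        train_cascade(bench[:1], CascadeConfig(K=3, n_trees=10, seed=9),
                      spec=spec)


def test_train_cascade_requires_native():
    from decoyrank.ranker import train_cascade
    from decoyrank.structure_io import DecoySet
    from decoyrank.synthetic import SyntheticConfig, generate_benchmark

    config = SyntheticConfig(n_proteins=1, n_decoys=24,
                             length_range=(20, 30), seed=9)
    (ds, cs), = generate_benchmark(config, K=3)
    bare = DecoySet(protein_id=ds.protein_id, decoys=ds.decoys,
                    native=None, pssm=ds.pssm)
    with pytest.raises(ConfigurationError, match=ds.protein_id):
        train_cascade([(bare, cs)], CascadeConfig(K=3, n_trees=10, seed=9),
                      spec=FeatureSpec(maxn=32))
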