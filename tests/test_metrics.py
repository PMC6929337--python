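"""Superposed RMSD and TM-score, checked against brute-force search oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from conftest import make_model, random_rigid
from decoyrank.errors import DimensionMismatchError
from decoyrank.metrics import (
    TMScoreParams,
    d0_from_length,
    rmsd,
    superpose,
    tm_score,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (grid over SO(3) + local refinement)

_OCTAHEDRAL = Rotation.create_group("O")


def brute_force_rmsd(P, Q):
    """Minimise RMSD over rigid motions by multi-start 6-dof optimisation."""

    def objective(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        d = P @ R.T + x[3:] - Q
        return np.sqrt((d * d).sum() / len(P))

    best = np.inf
    for seed_rot in _OCTAHEDRAL:
        x0 = np.concatenate(
            [seed_rot.as_rotvec(),
             Q.mean(axis=0) - seed_rot.as_matrix() @ P.mean(axis=0)]
        )
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


def brute_force_tm(P, Q, d0):
    """Maximise the TM sum over rigid motions by multi-start optimisation."""

    def neg_tm(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        d2 = ((P @ R.T + x[3:] - Q) ** 2).sum(axis=1)
        return -(1.0 / (1.0 + d2 / d0**2)).sum() / len(Q)

    best = 0.0
    starts = list(_OCTAHEDRAL)
    # a denser rotation grid around the octahedral orientations
    rng = np.random.default_rng(123)
    starts += [Rotation.from_rotvec(rng.normal(0, 0.8, 3)) * g
               for g in _OCTAHEDRAL for _ in range(2)]
    for seed_rot in starts:
        x0 = np.concatenate(
            [seed_rot.as_rotvec(),
             Q.mean(axis=0) - seed_rot.as_matrix() @ P.mean(axis=0)]
        )
        res = minimize(neg_tm, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        best = max(best, -res.fun)
    return best


# ---------------------------------------------------------------------------
# superpose / rmsd

def test_superpose_identity(zigzag10):
    sup = superpose(zigzag10, zigzag10)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(sup.translation, 0.0, atol=1e-9)


def test_superpose_recovers_rigid_motion(zigzag10):
    R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = make_model(zigzag10.coords @ R.T + [1, 2, 3], "moved")
    sup = superpose(moved, zigzag10)
    assert sup.rmsd < 1e-9
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
    np.testing.assert_allclose(sup.rotation @ sup.rotation.T, np.eye(3),
                               atol=1e-8)


def test_superpose_rejects_reflection():
    rng = np.random.default_rng(5)
    P = rng.normal(size=(6, 3))
    mirrored = P * [1, 1, -1]
    sup = superpose(make_model(mirrored), make_model(P))
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
    assert sup.rmsd > 0.1  # a reflection would give 0


def test_superposed_rmsd_matches_brute_force_on_toys():
    # 4-point toy with one displaced point
    P = np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 0.0]])
    Q = P.copy()
    Q[2] += [1.1, -0.7, 0.9]
    ours = rmsd(make_model(P), make_model(Q))
    oracle = brute_force_rmsd(P, Q)
    assert ours == pytest.approx(oracle, abs=1e-5)


def test_superposed_rmsd_matches_brute_force_random(rng):
    for _ in range(3):
        P = rng.normal(0, 4, size=(7, 3))
        Q = random_rigid(P + rng.normal(0, 1, size=P.shape), rng)
        assert rmsd(make_model(P), make_model(Q)) == pytest.approx(
            brute_force_rmsd(P, Q), abs=1e-5
        )


def test_rmsd_raw_vs_superposed_translation(zigzag10):
    shifted = make_model(zigzag10.coords + [0, 0, 2], "shift")
    assert rmsd(zigzag10, shifted, superpose_first=False) == pytest.approx(2.0)
    assert rmsd(zigzag10, shifted) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_symmetry_and_nonnegativity(rng, zigzag10):
    other = make_model(
        random_rigid(zigzag10.coords + rng.normal(0, 1.5, (10, 3)), rng), "o"
    )
    ab = rmsd(zigzag10, other)
    ba = rmsd(other, zigzag10)
    assert ab >= 0
    assert ab == pytest.approx(ba, abs=1e-9)


def test_rmsd_length_mismatch():
    with pytest.raises(DimensionMismatchError):
        rmsd(make_model(np.zeros((4, 3)) + np.arange(4)[:, None]),
             make_model(np.zeros((5, 3)) + np.arange(5)[:, None]))


# ---------------------------------------------------------------------------
# tm_score

def test_tm_score_identical_up_to_rigid_motion(zigzag10, rng):
    moved = make_model(random_rigid(zigzag10.coords, rng), "mv")
    assert tm_score(moved, zigzag10) == pytest.approx(1.0, abs=1e-6)


def test_tm_score_rigid_motion_invariance(zigzag10, rng):
    noisy = make_model(zigzag10.coords + rng.normal(0, 1.0, (10, 3)), "n")
    base = tm_score(noisy, zigzag10)
    for _ in range(3):
        m2 = make_model(random_rigid(noisy.coords, rng), "m2")
        n2 = make_model(random_rigid(zigzag10.coords, rng), "n2")
        assert tm_score(m2, n2) == pytest.approx(base, abs=1e-6)


def test_tm_score_all_residues_at_d0_bound(zigzag10):
    # a superposition placing every residue exactly d0 away exists, so the
    # maximised score must be at least 0.5
    L = len(zigzag10)
    d0 = d0_from_length(L)
    shifted = make_model(zigzag10.coords + [0, 0, d0], "s")
    score = tm_score(shifted, zigzag10)
    assert score >= 0.5 - 1e-9


def test_tm_score_matches_dense_search_oracle(zigzag10, rng):
    d0 = d0_from_length(10)
    for sigma in (0.5, 1.5, 3.0):
        P = zigzag10.coords + rng.normal(0, sigma, (10, 3))
        P = random_rigid(P, rng)
        ours = tm_score(make_model(P), zigzag10)
        oracle = brute_force_tm(P, zigzag10.coords, d0)
        assert ours == pytest.approx(oracle, abs=1e-3)


def test_tm_score_params_and_errors(zigzag10):
    with pytest.raises(DimensionMismatchError):
        tm_score(zigzag10, make_model(np.zeros((5, 3)) + np.arange(5)[:, None]))
    with pytest.raises(DimensionMismatchError):
        TMScoreParams(L_n=5, L_a=6, d0=1.0)
    # explicit params are honoured
    loose = tm_score(zigzag10, zigzag10, params=TMScoreParams(10, 10, 5.0))
    assert loose == pytest.approx(1.0, abs=1e-9)


def test_d0_default_rule():
    assert d0_from_length(120) == pytest.approx(1.24 * 105 ** (1 / 3) - 1.8)
    assert d0_from_length(15) == 0.5  # floor
    assert d0_from_length(20) == pytest.approx(max(0.5, 1.24 * 5 ** (1 / 3) - 1.8))


# ---------------------------------------------------------------------------
# monotonicity under noise

def test_metrics_monotone_in_noise_level():
    """Mean RMSD grows and mean TM-score shrinks with the noise scale."""
    rng = np.random.default_rng(99)
    base = np.cumsum(rng.normal(0, 2.2, size=(30, 3)), axis=0)
    native = make_model(base, "nat")
    sigmas = [0.5, 1.0, 2.0, 4.0]
    mean_r, mean_t = [], []
    for sigma in sigmas:
        rs, ts = [], []
        for _ in range(20):
            decoy = make_model(
                random_rigid(base + rng.normal(0, sigma, base.shape), rng), "d"
            )
            rs.append(rmsd(decoy, native))
            ts.append(tm_score(decoy, native))
        mean_r.append(np.mean(rs))
        mean_t.append(np.mean(ts))
    assert spearmanr(sigmas, mean_r).statistic == pytest.approx(1.0)
    assert spearmanr(sigmas, mean_t).statistic == pytest.approx(-1.0)
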