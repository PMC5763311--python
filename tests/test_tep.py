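import math

import numpy as np
import pytest

from tepcausal import (
    EmbeddingConfig,
    TimeSeriesMatrix,
    causal_score,
    causality_matrix,
    delay_embed,
    loo_scores,
    pairwise_distances,
    simulate_logistic,
    tep_relative_errors,
    tep_score,
    unidirectional_logistic,
)
from tepcausal.exceptions import (
    CoincidentPointsError,
    DegenerateReferencePairError,
    InsufficientPointsError,
)

from conftest import make_series


# ---------------------------------------------------------------- oracles

def loop_relative_errors(d, D):
    """Scalar-by-scalar transcription of the relative-error definition."""
    n = d.shape[0]
    gamma = d[0, 1] / D[0, 1]
    out = {}
    for i in range(2, n):  # 1-based i = 3..n
        for j in range(i):
            out[(i, j)] = abs(d[i, j] - gamma * D[i, j]) / (gamma * D[i, j])
    return gamma, out


def loop_score(errors, n):
    """Literal double-loop transcription of the score aggregation."""
    outer = 0.0
    for i in range(2, n):
        inner = 0.0
        for j in range(i):
            inner += 1.0 / math.exp(errors[(i, j)])
        outer += inner / i
    return outer / (n - 1)


def loop_pair_score(x_values, y_values, dim=2, lag=1):
    d = pairwise_distances(delay_embed(make_series("x", x_values), EmbeddingConfig(dim, lag)))
    D = pairwise_distances(delay_embed(make_series("y", y_values), EmbeddingConfig(dim, lag)))
    gamma, errs = loop_relative_errors(d, D)
    return loop_score(errs, d.shape[0])


# ---------------------------------------------------- pairwise distances

def test_pairwise_distances_345_triangle():
    from tepcausal import EmbeddedAttractor

    att = EmbeddedAttractor("s", np.array([[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]]))
    d = pairwise_distances(att)
    assert d[0, 1] == 5.0
    assert d.shape == (3, 3)
    assert np.all(np.diag(d) == 0)


def test_pairwise_distances_identical_points_all_zero():
    from tepcausal import EmbeddedAttractor

    att = EmbeddedAttractor("s", np.ones((4, 2)))
    assert np.all(pairwise_distances(att) == 0)


def test_pairwise_distances_matches_double_loop(rng):
    from tepcausal import EmbeddedAttractor

    pts = rng.random((6, 3))
    d = pairwise_distances(EmbeddedAttractor("s", pts))
    for i in range(6):
        for j in range(6):
            assert d[i, j] == pytest.approx(np.linalg.norm(pts[i] - pts[j]), abs=1e-14)


# ------------------------------------------------------- relative errors

def test_identical_attractors_zero_errors(rng):
    from tepcausal import EmbeddedAttractor

    d = pairwise_distances(EmbeddedAttractor("s", rng.random((5, 2))))
    gamma, rel = tep_relative_errors(d, d)
    assert gamma == 1.0
    evaluated = rel[~np.isnan(rel)]
    assert np.all(evaluated == 0.0)


@pytest.mark.parametrize("c", [0.5, 3.0])
def test_similar_attractors_absorbed_by_gamma(rng, c):
    from tepcausal import EmbeddedAttractor

    D = pairwise_distances(EmbeddedAttractor("s", rng.random((6, 2))))
    gamma, rel = tep_relative_errors(c * D, D)
    assert gamma == pytest.approx(c, abs=1e-14)
    assert np.nanmax(rel) < 1e-12


def test_relative_errors_match_scalar_oracle(rng):
    from tepcausal import EmbeddedAttractor

    d = pairwise_distances(EmbeddedAttractor("a", rng.random((4, 2))))
    D = pairwise_distances(EmbeddedAttractor("b", rng.random((4, 2))))
    gamma, rel = tep_relative_errors(d, D)
    oracle_gamma, oracle = loop_relative_errors(d, D)
    assert gamma == oracle_gamma
    for (i, j), val in oracle.items():
        assert rel[i, j] == pytest.approx(val, abs=1e-14)
    # only rows i >= 3 (0-based 2) are evaluated
    assert np.isnan(rel[1, 0])


def test_degenerate_reference_pair_errors():
    d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0.0]])
    D = np.ones((3, 3)) - np.eye(3)
    with pytest.raises(DegenerateReferencePairError, match="predictor"):
        tep_relative_errors(d, D)
    with pytest.raises(DegenerateReferencePairError, match="predicted"):
        tep_relative_errors(D, d)


def test_coincident_target_points_error_and_skip():
    D = np.array(
        [[0, 1, 1, 1], [1, 0, 1, 0.0], [1, 1, 0, 1], [1, 0.0, 1, 0]]
    )  # points 2 and 4 coincide
    d = np.ones((4, 4)) - np.eye(4)
    with pytest.raises(CoincidentPointsError, match="4 and 2"):
        tep_relative_errors(d, D)
    gamma, rel = tep_relative_errors(d, D, skip_degenerate_pairs=True)
    assert np.isnan(rel[3, 1])
    assert np.isfinite(tep_score(rel, 4))


# ------------------------------------------------------------ pair score

def test_score_minimal_case_exact():
    rel = np.full((3, 3), np.nan)
    rel[2, 0] = rel[2, 1] = 0.0
    assert tep_score(rel, 3) == 0.5


def test_score_zero_error_n10_exact():
    rel = np.full((10, 10), np.nan)
    for i in range(2, 10):
        rel[i, :i] = 0.0
    assert tep_score(rel, 10) == pytest.approx(8 / 9, abs=1e-15)


def test_score_matches_loop_transcription(rng):
    n = 6
    rel = np.full((n, n), np.nan)
    errors = {}
    for i in range(2, n):
        for j in range(i):
            errors[(i, j)] = rel[i, j] = rng.random() * 2
    assert tep_score(rel, n) == pytest.approx(loop_score(errors, n), abs=1e-15)


def test_score_requires_three_points():
    with pytest.raises(InsufficientPointsError):
        tep_score(np.full((2, 2), np.nan), 2)


# ----------------------------------------------------------- causal_score

def test_affine_copy_attains_maximum(rng):
    x = make_series("x", rng.random(10))
    y = make_series("y", 3.0 * x.values - 7.0)
    res = causal_score(x, y)
    assert res.score == pytest.approx((res.n - 2) / (res.n - 1), abs=1e-12)
    assert np.nanmax(res.rel_errors) < 1e-12


def test_affine_invariance(rng):
    x = make_series("x", rng.random(10))
    y = make_series("y", rng.random(10))
    base = causal_score(x, y).score
    xt = make_series("x", -4.0 * x.values + 2.0)
    yt = make_series("y", 0.5 * y.values + 9.0)
    assert causal_score(xt, yt).score == pytest.approx(base, abs=1e-12)


def test_directionality_on_unidirectional_logistic():
    """With Y autonomous and driving X, the claim 'Y causes X' (scored
    from X's attractor) must beat the false claim 'X causes Y'."""
    data = unidirectional_logistic(n_steps=10)
    x = make_series("X", data.series("X"))
    y = make_series("Y", data.series("Y"))
    true_direction = causal_score(x, y).score  # "Y causes X"
    false_direction = causal_score(y, x).score  # "X causes Y"
    assert true_direction > false_direction


def test_white_noise_null_is_direction_symmetric():
    """Under independence, neither direction is favoured on average."""
    rng = np.random.default_rng(77)
    diffs = []
    for _ in range(20):
        x = make_series("x", rng.standard_normal(10))
        y = make_series("y", rng.standard_normal(10))
        diffs.append(causal_score(x, y).score - causal_score(y, x).score)
    assert abs(np.mean(diffs)) < 0.05


def test_score_bounds(random_series_pair):
    x, y = random_series_pair
    res = causal_score(x, y)
    assert 0 < res.score <= (res.n - 2) / (res.n - 1)


def test_causal_score_matches_loop_oracle(rng):
    for _ in range(10):
        xv, yv = rng.random(9), rng.random(9)
        vectorized = causal_score(make_series("x", xv), make_series("y", yv)).score
        assert vectorized == pytest.approx(loop_pair_score(xv, yv), abs=1e-12)


# ------------------------------------------------------ causality_matrix

def test_matrix_two_variables():
    data = simulate_logistic(n_steps=10)
    m = causality_matrix(data)
    off = ~np.eye(2, dtype=bool)
    assert np.isfinite(m.scores[off]).sum() == 2
    assert np.all(np.isnan(np.diag(m.scores)))


def test_matrix_orientation_matches_causal_score():
    """Entry (A, B) is the claim 'A causes B': predictor is B."""
    data = unidirectional_logistic(n_steps=10)
    m = causality_matrix(data)
    x = make_series("X", data.series("X"))
    y = make_series("Y", data.series("Y"))
    assert m.scores[m.names.index("Y"), m.names.index("X")] == causal_score(x, y).score
    assert m.scores[m.names.index("X"), m.names.index("Y")] == causal_score(y, x).score


def test_duplicated_variable_scores_maximum(rng):
    vals = rng.random(10)
    data = TimeSeriesMatrix(
        names=("a", "a_copy", "b"),
        times=tuple(range(10)),
        values=np.vstack([vals, vals, rng.random(10)]),
    )
    m = causality_matrix(data)
    n = 10 - 1  # embedded points at default dim=2, lag=1
    expected = (n - 2) / (n - 1)
    assert m.scores[0, 1] == pytest.approx(expected, abs=1e-12)
    assert m.scores[1, 0] == pytest.approx(expected, abs=1e-12)


def test_degenerate_pair_marked_missing_not_fatal(caplog):
    data = TimeSeriesMatrix(
        names=("const", "v"),
        times=tuple(range(8)),
        values=np.vstack([np.ones(8), np.arange(8.0)]),
    )
    import logging

    with caplog.at_level(logging.WARNING, logger="tepcausal.tep"):
        m = causality_matrix(data)
    assert np.isnan(m.scores[0, 1]) and np.isnan(m.scores[1, 0])
    assert any("left unscored" in rec.message for rec in caplog.records)


# ------------------------------------------------------------- leave-one-out

def test_loo_affine_copy(rng):
    x = make_series("x", rng.random(10))
    y = make_series("y", 2.0 * x.values + 1.0)
    scores, mean = loo_scores(x, y)
    n = 9  # embedded points; each loo run has m = n - 1
    m = n - 1
    np.testing.assert_allclose(scores, (m - 2) / (m - 1), atol=1e-12)
    assert mean == pytest.approx((m - 2) / (m - 1), abs=1e-12)


def test_loo_bounds(random_series_pair):
    x, y = random_series_pair
    scores, mean = loo_scores(x, y)
    assert len(scores) == 9
    assert np.all((scores > 0) & (scores < 1))
    assert 0 < mean < 1


def test_loo_matches_from_scratch_recomputation(rng):
    from scipy.spatial.distance import pdist, squareform

    from tepcausal.tep import _score_from_distances

    x = make_series("x", rng.random(8))
    y = make_series("y", rng.random(8))
    cfg = EmbeddingConfig()
    scores, _ = loo_scores(x, y, cfg)
    Px = delay_embed(x, cfg).points
    Py = delay_embed(y, cfg).points
    for k in range(len(scores)):
        d = squareform(pdist(np.delete(Px, k, axis=0)))
        D = squareform(pdist(np.delete(Py, k, axis=0)))
        assert scores[k] == _score_from_distances(d, D).score


def test_no_randomness_in_scoring(random_series_pair):
    x, y = random_series_pair
    assert causal_score(x, y).score == causal_score(x, y).score
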