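"""The topologically-equivalent-position (TEP) causality score.

Two attractors reconstructed from components of the same dynamical system
are topologically equivalent, and corresponding points sit at
*topologically equivalent positions*: their distances to all other points
agree up to one common scale

    d_ij = gamma * D_ij,      gamma = d_12 / D_12,

where ``d`` collects Euclidean distances on the predictor attractor M_X
and ``D`` those on the predicted attractor M_Y. How far an observed pair
deviates from this similarity is the relative error

    eps_ij = |d_ij - gamma * D_ij| / (gamma * D_ij),   i >= 3, j < i,

and the pair score aggregates the errors through a bounded exponential
transform,

    eps = 1/(n-1) * sum_{i=3..n} [ 1/(i-1) * sum_{j<i} exp(-eps_ij) ],

so that larger scores mean smaller errors. With all errors zero the score
attains its maximum (n-2)/(n-1). Direction convention: a high score for
the pair (predictor = X, predicted = Y) is read as evidence that
*Y causes X* - the effect's coordinates carry enough information to
predict the cause's positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embedding import EmbeddedAttractor, EmbeddingConfig, ScalarSeries, delay_embed
from .exceptions import (
    CoincidentPointsError,
    DegenerateReferencePairError,
    InsufficientPointsError,
)

__all__ = [
    "TepResult",
    "CausalityMatrix",
    "pairwise_distances",
    "tep_relative_errors",
    "tep_score",
    "causal_score",
    "causality_matrix",
    "loo_scores",
]

logger = logging.getLogger(__name__)

ReferencePair = Literal["first", "farthest"]


@dataclass(frozen=True)
class TepResult:
    """Outcome of scoring one directed claim.

    ``rel_errors`` is an n-by-n array holding eps_ij in its strict lower
    triangle for rows i >= 3 (0-based rows >= 2); all other entries are
    NaN, as are any (i, j) terms skipped due to coincident target points.
    ``n`` counts embedded points, not raw time points.
    """

    gamma: float
    rel_errors: np.ndarray
    score: float
    n: int


@dataclass(frozen=True)
class CausalityMatrix:
    """All-pairs directed scores, rows -> columns.

    ``scores[a, b]`` is the score for the claim "names[a] causes
    names[b]"; the diagonal is NaN (self-causation undefined), as is any
    pair whose scoring degenerated.
    """

    names: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        G = len(self.names)
        if self.scores.shape != (G, G):
            raise ValueError("scores shape must match number of names")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores, index=list(self.names), columns=list(self.names))


def pairwise_distances(attractor: EmbeddedAttractor) -> np.ndarray:
    """Full symmetric Euclidean distance matrix of an attractor's points."""
    if attractor.n_points < 3:
        raise InsufficientPointsError(
            f"attractor {attractor.source_name!r}: need at least 3 points, "
            f"got {attractor.n_points}"
        )
    return squareform(pdist(attractor.points))


def _reference_indices(D: np.ndarray, reference_pair: ReferencePair) -> tuple[int, int]:
    if reference_pair == "first":
        return 0, 1
    if reference_pair == "farthest":
        i, j = np.unravel_index(np.argmax(D), D.shape)
        return int(i), int(j)
    raise ValueError(f"unknown reference_pair {reference_pair!r}")


def tep_relative_errors(
    d: np.ndarray,
    D: np.ndarray,
    *,
    reference_pair: ReferencePair = "first",
    skip_degenerate_pairs: bool = False,
) -> tuple[float, np.ndarray]:
    """Scale ratio gamma and relative errors eps_ij of two distance matrices.

    ``d`` lives on the predictor attractor, ``D`` on the predicted one.
    Evaluated entries are i = 3..n, j = 1..i-1 (1-based); the returned
    n-by-n array holds eps_ij there and NaN elsewhere.

    Raises
    ------
    DegenerateReferencePairError
        If the reference distance vanishes on either attractor.
    CoincidentPointsError
        If some evaluated D_ij is zero and ``skip_degenerate_pairs`` is
        off; with the flag on, the offending term becomes NaN and the
        score later renormalizes over the remaining terms.
    """
    d = np.asarray(d, dtype=float)
    D = np.asarray(D, dtype=float)
    if d.shape != D.shape or d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("d and D must be square matrices of equal size")
    n = d.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"need at least 3 points, got {n}")

    i0, j0 = _reference_indices(D, reference_pair)
    if d[i0, j0] == 0.0:
        raise DegenerateReferencePairError("predictor", i0 + 1, j0 + 1)
    if D[i0, j0] == 0.0:
        raise DegenerateReferencePairError("predicted", i0 + 1, j0 + 1)
    gamma = d[i0, j0] / D[i0, j0]

    rel = np.full((n, n), np.nan)
    rows, cols = np.tril_indices(n, k=-1)
    keep = rows >= 2  # 1-based i >= 3
    rows, cols = rows[keep], cols[keep]
    denom = gamma * D[rows, cols]
    zero = denom == 0.0
    if np.any(zero):
        if not skip_degenerate_pairs:
            k = int(np.flatnonzero(zero)[0])
            raise CoincidentPointsError(int(rows[k]) + 1, int(cols[k]) + 1)
        valid = ~zero
        rel[rows[valid], cols[valid]] = (
            np.abs(d[rows[valid], cols[valid]] - denom[valid]) / denom[valid]
        )
    else:
        rel[rows, cols] = np.abs(d[rows, cols] - denom) / denom
    return float(gamma), rel


def tep_score(rel_errors: np.ndarray, n: int) -> float:
    """Aggregate relative errors into the bounded pair score.

    The outer factor is deliberately kept as 1/(n-1), exactly as the
    defining formula states, although the outer sum has n-2 terms, so the maximum score is
    (n-2)/(n-1), reached iff every eps_ij = 0. Rows with skipped
    (NaN) terms average over their remaining terms.
    """
    if n < 3:
        raise InsufficientPointsError(f"need at least 3 points, got {n}")
    rel = np.asarray(rel_errors, dtype=float)
    total = 0.0
    for i in range(2, n):  # 1-based i = 3..n
        row = rel[i, :i]
        valid = ~np.isnan(row)
        if not np.any(valid):
            raise CoincidentPointsError(i + 1, 1)
        total += float(np.exp(-row[valid]).mean())
    return total / (n - 1)


def _score_from_distances(
    d: np.ndarray,
    D: np.ndarray,
    *,
    reference_pair: ReferencePair = "first",
    skip_degenerate_pairs: bool = False,
) -> TepResult:
    gamma, rel = tep_relative_errors(
        d, D, reference_pair=reference_pair, skip_degenerate_pairs=skip_degenerate_pairs
    )
    n = d.shape[0]
    return TepResult(gamma=gamma, rel_errors=rel, score=tep_score(rel, n), n=n)


def causal_score(
    x: ScalarSeries,
    y: ScalarSeries,
    config: EmbeddingConfig | None = None,
    *,
    reference_pair: ReferencePair = "first",
    skip_degenerate_pairs: bool = False,
) -> TepResult:
    """Score the directed claim "y causes x".

    ``x`` is the predictor: its attractor M_X supplies the distances
    ``d``; ``y`` is the predicted variable supplying ``D``. The measure is
    asymmetric in general: ``causal_score(x, y)`` need not equal
    ``causal_score(y, x)``.
    """
    if len(x) != len(y):
        raise ValueError(
            f"series lengths differ: {x.name!r} has {len(x)}, {y.name!r} has {len(y)}"
        )
    cfg = config or EmbeddingConfig()
    d = pairwise_distances(delay_embed(x, cfg))
    D = pairwise_distances(delay_embed(y, cfg))
    return _score_from_distances(
        d, D, reference_pair=reference_pair, skip_degenerate_pairs=skip_degenerate_pairs
    )


def causality_matrix(
    data,
    config: EmbeddingConfig | None = None,
    *,
    reference_pair: ReferencePair = "first",
    skip_degenerate_pairs: bool = False,
) -> CausalityMatrix:
    """Score every ordered pair of variables in a time-series matrix.

    Entry (A, B) scores the claim "A causes B" (rows -> columns), i.e.
    B's attractor is the predictor and A's the predicted, giving
    G*(G-1) scores for G variables. A pair whose scoring degenerates is
    logged and left NaN rather than failing the whole matrix.
    """
    cfg = config or EmbeddingConfig()
    names = tuple(data.names)
    G = len(names)
    if G < 2:
        raise ValueError("need at least 2 variables")
    dists = [
        pairwise_distances(delay_embed(ScalarSeries(name, row), cfg))
        for name, row in zip(names, data.values)
    ]
    scores = np.full((G, G), np.nan)
    for a in range(G):
        for b in range(G):
            if a == b:
                continue
            try:
                # claim "A causes B": predictor is B (d), predicted is A (D)
                res = _score_from_distances(
                    dists[b],
                    dists[a],
                    reference_pair=reference_pair,
                    skip_degenerate_pairs=skip_degenerate_pairs,
                )
            except (DegenerateReferencePairError, CoincidentPointsError) as exc:
                logger.warning(
                    "pair (%s -> %s) left unscored: %s", names[a], names[b], exc
                )
                continue
            scores[a, b] = res.score
    return CausalityMatrix(names=names, scores=scores)


def loo_scores(
    x: ScalarSeries,
    y: ScalarSeries,
    config: EmbeddingConfig | None = None,
    *,
    reference_pair: ReferencePair = "first",
    skip_degenerate_pairs: bool = False,
) -> tuple[np.ndarray, float]:
    """Leave-one-out diagnostic for :func:`causal_score`.

    For each embedded point index k the score is recomputed with point k
    deleted from both attractors' point lists; returns the n scores and
    their mean. The full-data score remains the headline statistic; this
    is an opt-in stability check.
    """
    cfg = config or EmbeddingConfig()
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    Ax = delay_embed(x, cfg)
    Ay = delay_embed(y, cfg)
    n = Ax.n_points
    if n < 4:
        raise InsufficientPointsError(
            f"leave-one-out needs at least 4 embedded points, got {n}"
        )
    out = np.empty(n)
    for k in range(n):
        Px = np.delete(Ax.points, k, axis=0)
        Py = np.delete(Ay.points, k, axis=0)
        d = squareform(pdist(Px))
        D = squareform(pdist(Py))
        out[k] = _score_from_distances(
            d, D, reference_pair=reference_pair, skip_degenerate_pairs=skip_degenerate_pairs
        ).score
    return out, float(out.mean())
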