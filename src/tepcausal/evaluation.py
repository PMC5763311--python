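"""ROC/AUC evaluation of directed score matrices against known networks.

Every ordered pair of distinct variables is one ranking instance,
labelled positive iff the ground truth contains that directed edge.
AUC is the tie-aware Mann-Whitney U statistic (ties count half), which
matters here because short series readily produce tied scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import SingleClassTruthError
from .simulators import GroundTruthNetwork
from .tep import CausalityMatrix

__all__ = ["DetectionConfig", "RocResult", "roc", "detect", "benchmark"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """How scores become binary causal calls.

    Exactly one of ``score_threshold`` (call an edge when score >=
    threshold) or ``top_k`` (call the k best-scoring pairs) must be set.
    ``error_tolerance`` is the pointwise prediction-error tolerance the
    neighborhood criterion is stated with (an error below 1e-3 counts as
    an accurate prediction); it is carried in the config for reporting
    but the threshold-free ROC surface is the primary evaluation.
    """

    score_threshold: float | None = None
    top_k: int | None = None
    error_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        if (self.score_threshold is None) == (self.top_k is None):
            raise ValueError("set exactly one of score_threshold or top_k")
        if self.score_threshold is not None and not 0 <= self.score_threshold <= 1:
            raise ValueError("score_threshold must lie in [0, 1]")
        if self.top_k is not None and self.top_k < 0:
            raise ValueError("top_k must be >= 0")


@dataclass(frozen=True)
class RocResult:
    """A ROC curve with its area and class counts."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def _instances(scores: CausalityMatrix, truth: GroundTruthNetwork):
    unknown = sorted({v for e in truth.edges for v in e} - set(scores.names))
    if unknown:
        raise ValueError(f"truth references variables absent from scores: {unknown}")
    G = len(scores.names)
    y, s = [], []
    n_missing = 0
    for a in range(G):
        for b in range(G):
            if a == b:
                continue
            value = scores.scores[a, b]
            if not np.isfinite(value):
                n_missing += 1
                continue
            y.append(1 if truth.has_edge(scores.names[a], scores.names[b]) else 0)
            s.append(float(value))
    if n_missing:
        logger.warning("excluded %d unscored pairs from evaluation", n_missing)
    return np.asarray(y), np.asarray(s)


def roc(scores: CausalityMatrix, truth: GroundTruthNetwork) -> RocResult:
    """ROC curve and AUC of a score matrix against a directed network.

    Raises :class:`SingleClassTruthError` when the labelled pairs are all
    positive or all negative.
    """
    y, s = _instances(scores, truth)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassTruthError(
            f"single-class truth: {n_pos} positives, {n_neg} negatives"
        )
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, n_positive=n_pos, n_negative=n_neg)


def detect(scores: CausalityMatrix, cfg: DetectionConfig) -> np.ndarray:
    """Binary call matrix (rows -> columns); diagonal always False.

    Threshold mode calls score >= threshold; rank mode calls the top-k
    finite scores (ties broken by matrix order)."""
    G = len(scores.names)
    off = ~np.eye(G, dtype=bool)
    calls = np.zeros((G, G), dtype=bool)
    vals = scores.scores
    if cfg.score_threshold is not None:
        calls[off] = np.nan_to_num(vals[off], nan=-np.inf) >= cfg.score_threshold
        return calls
    flat = np.where(off, np.nan_to_num(vals, nan=-np.inf), -np.inf).ravel()
    k = min(cfg.top_k, int(np.isfinite(flat).sum()))
    if k > 0:
        order = np.argsort(-flat, kind="stable")[:k]
        calls.ravel()[order] = True
    return calls


def benchmark(
    detector_runs: list[tuple[str, CausalityMatrix]], truth: GroundTruthNetwork
) -> pd.DataFrame:
    """AUC table for several labelled score matrices vs one truth,
    sorted by AUC descending."""
    rows = []
    for label, matrix in detector_runs:
        result = roc(matrix, truth)
        rows.append(
            {
                "label": label,
                "auc": result.auc,
                "n_positive": result.n_positive,
                "n_negative": result.n_negative,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("auc", ascending=False, ignore_index=True)
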