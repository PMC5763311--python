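"""Delay (lagged-coordinate) embedding of scalar time series.

A scalar series ``x_1..x_T`` observed from a dynamical system is lifted to
a cloud of ``E``-dimensional delay vectors

    (x_k, x_{k+tau}, ..., x_{k+(E-1)tau}),   k = 1..T-(E-1)tau,

which, by Takens' theorem, reconstructs an attractor topologically
equivalent to the original system's. Downstream scoring only needs the
ordered point cloud, so that is all :class:`EmbeddedAttractor` stores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConstantSeriesError, InsufficientPointsError

__all__ = ["ScalarSeries", "EmbeddingConfig", "EmbeddedAttractor", "delay_embed"]


@dataclass(frozen=True)
class ScalarSeries:
    """A named scalar time series.

    Parameters
    ----------
    name
        Identifier of the observed variable (e.g. a gene name).
    values
        Ordered real observations, length T >= 3, all finite.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"series {self.name!r}: values must be 1-D")
        if vals.size < 3:
            raise InsufficientPointsError(
                f"series {self.name!r}: need at least 3 time points, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"series {self.name!r}: values must be finite")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters.

    ``dim`` is the embedding dimension E >= 1 and ``lag`` the delay tau >= 1
    in sample steps. With ``standardize`` the series is z-scored before
    embedding; recommended when comparing variables on different scales
    (cross-gene expression), off by default so that worked arithmetic on
    raw values is literal. Defaults E=2, tau=1 keep the embedded point
    count n = T - (E-1)tau as large as possible for ~10-sample series,
    which matters because the score needs n >= 3.
    """

    dim: int = 2
    lag: int = 1
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"embedding dimension must be >= 1, got {self.dim}")
        if self.lag < 1:
            raise ValueError(f"embedding lag must be >= 1, got {self.lag}")

    def min_length(self) -> int:
        """Shortest series length that yields the required >= 3 points."""
        return (self.dim - 1) * self.lag + 3


@dataclass(frozen=True)
class EmbeddedAttractor:
    """Ordered delay vectors reconstructed from one scalar series."""

    source_name: str
    points: np.ndarray  # shape (n, E), temporal order
    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def delay_embed(series: ScalarSeries, config: EmbeddingConfig | None = None) -> EmbeddedAttractor:
    """Embed a scalar series into delay coordinates.

    Returns ``n = T - (E-1)*tau`` points in temporal order, where point k is
    ``(x_k, x_{k+tau}, ..., x_{k+(E-1)tau})``.

    Raises
    ------
    InsufficientPointsError
        If ``T < (E-1)*tau + 3`` (fewer than three embedded points).
    ConstantSeriesError
        If ``config.standardize`` is set and the series has zero variance.
    """
    cfg = config or EmbeddingConfig()
    values = series.values
    T = values.size
    min_T = cfg.min_length()
    if T < min_T:
        raise InsufficientPointsError(
            f"series {series.name!r}: insufficient points for dim={cfg.dim}, "
            f"lag={cfg.lag}: need T >= {min_T}, got T = {T}"
        )
    if cfg.standardize:
        sd = values.std()
        if sd == 0.0:
            raise ConstantSeriesError(
                f"series {series.name!r}: constant series cannot be standardized"
            )
        values = (values - values.mean()) / sd

    n = T - (cfg.dim - 1) * cfg.lag
    cols = [values[k * cfg.lag : k * cfg.lag + n] for k in range(cfg.dim)]
    points = np.column_stack(cols)
    return EmbeddedAttractor(source_name=series.name, points=points, config=cfg)
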