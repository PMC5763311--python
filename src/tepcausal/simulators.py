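"""Benchmark dynamical systems and synthetic gene-expression data.

Three generators cover the validation ladder for short-series causality
detection:

* a pair of coupled logistic maps (chaotic, with tunable one- or
  two-way coupling),
* a 5-species coupled map whose wiring is known exactly (species 1-3
  mutually coupled and driving species 4 and 5, which feed back on
  nothing), and
* random gene regulatory networks with Michaelis-Menten/Hill node
  kinetics, integrated by fixed-step RK4 and subsampled to a handful of
  time points, optionally with additive measurement noise.

All randomness is seeded explicitly; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergentTrajectoryError
from .io import TimeSeriesMatrix

__all__ = [
    "LogisticParams",
    "FiveSpeciesParams",
    "GrnConfig",
    "GroundTruthNetwork",
    "simulate_logistic",
    "unidirectional_logistic",
    "simulate_five_species",
    "five_species_truth",
    "simulate_grn",
    "add_noise",
]


@dataclass(frozen=True)
class GroundTruthNetwork:
    """Directed ground-truth edges over named variables (no self-loops)."""

    names: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "edges", frozenset(self.edges))
        known = set(self.names)
        for src, tgt in self.edges:
            if src == tgt:
                raise ValueError(f"self-loop {src!r} -> {tgt!r} not allowed")
            if src not in known or tgt not in known:
                raise ValueError(f"edge ({src!r}, {tgt!r}) references unknown variable")

    def has_edge(self, src: str, tgt: str) -> bool:
        return (src, tgt) in self.edges


@dataclass(frozen=True)
class LogisticParams:
    """Coupled logistic map parameters (standard benchmark defaults).

    X(t+1) = X(t) [r_x - r_x X(t) - beta_xy Y(t)]
    Y(t+1) = Y(t) [r_y - r_y Y(t) - beta_yx X(t)]
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.02
    beta_yx: float = 0.1
    x0: float = 0.4
    y0: float = 0.2


def simulate_logistic(
    params: LogisticParams | None = None, n_steps: int = 10, burn_in: int = 0
) -> TimeSeriesMatrix:
    """Iterate the coupled logistic maps for ``n_steps`` points.

    No transient is discarded by default (the benchmark uses the raw
    trajectory from the given initial conditions); ``burn_in`` extra
    leading steps can be dropped for robustness studies.
    """
    p = params or LogisticParams()
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    total = n_steps + burn_in
    X = np.empty(total)
    Y = np.empty(total)
    X[0], Y[0] = p.x0, p.y0
    for t in range(total - 1):
        X[t + 1] = X[t] * (p.r_x - p.r_x * X[t] - p.beta_xy * Y[t])
        Y[t + 1] = Y[t] * (p.r_y - p.r_y * Y[t] - p.beta_yx * X[t])
        if not (np.isfinite(X[t + 1]) and np.isfinite(Y[t + 1])):
            raise DivergentTrajectoryError(t + 2)
    return TimeSeriesMatrix(
        names=("X", "Y"),
        times=tuple(range(1, n_steps + 1)),
        values=np.vstack([X[burn_in:], Y[burn_in:]]),
    )


def unidirectional_logistic(
    params: LogisticParams | None = None, n_steps: int = 10, burn_in: int = 0
) -> TimeSeriesMatrix:
    """The one-way variant: Y is autonomous (beta_yx forced to 0), X is
    driven by Y, so the only true influence is Y -> X."""
    p = params or LogisticParams()
    return simulate_logistic(
        LogisticParams(p.r_x, p.r_y, p.beta_xy, 0.0, p.x0, p.y0), n_steps, burn_in
    )


_FIVE_SPECIES_GROWTH = np.array([4.0, 3.1, 2.12, 3.8, 4.1])
_FIVE_SPECIES_COUPLING = np.array(
    [
        [-4.0, -2.0, -0.4, 0.0, 0.0],
        [-0.3, -3.1, -0.93, 0.0, 0.0],
        [0.636, 0.636, -2.12, 0.0, 0.0],
        [-0.111, -0.011, 0.131, -3.8, 0.0],
        [-0.082, -0.111, -0.125, 0.0, -4.1],
    ]
)
_FIVE_SPECIES_NAMES = ("Y1", "Y2", "Y3", "Y4", "Y5")


@dataclass(frozen=True)
class FiveSpeciesParams:
    """5-species coupled map: Y_i(t+1) = Y_i(t) [growth_i + sum_j coupling_ij Y_j(t)].

    The diagonal of ``coupling`` carries the self-limitation -growth_i.
    ``init`` may be None, in which case the simulator draws it uniformly
    from (0.2, 0.8) with its seed (the benchmark does not fix initial
    conditions).
    """

    growth: np.ndarray = field(default_factory=lambda: _FIVE_SPECIES_GROWTH.copy())
    coupling: np.ndarray = field(default_factory=lambda: _FIVE_SPECIES_COUPLING.copy())
    init: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "growth", np.asarray(self.growth, dtype=float))
        object.__setattr__(self, "coupling", np.asarray(self.coupling, dtype=float))
        if self.growth.shape != (5,) or self.coupling.shape != (5, 5):
            raise ValueError("growth must be length-5 and coupling 5x5")
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if init.shape != (5,):
                raise ValueError("init must be length-5")
            object.__setattr__(self, "init", init)


def simulate_five_species(
    params: FiveSpeciesParams | None = None,
    n_steps: int = 15,
    seed: int | None = None,
    burn_in: int = 0,
) -> TimeSeriesMatrix:
    """Iterate the 5-species map for ``n_steps`` points.

    Raises :class:`DivergentTrajectoryError` if the trajectory escapes to
    a non-finite value; random initial conditions do diverge for a
    sizeable fraction of draws, so callers sampling initial conditions
    should redraw on that error (see ``sample_bounded_five_species``).
    """
    p = params or FiveSpeciesParams()
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    if p.init is not None:
        init = p.init
    else:
        init = np.random.default_rng(seed).uniform(0.2, 0.8, 5)
    total = n_steps + burn_in
    Y = np.empty((5, total))
    Y[:, 0] = init
    for t in range(total - 1):
        Y[:, t + 1] = Y[:, t] * (p.growth + p.coupling @ Y[:, t])
        bad = ~np.isfinite(Y[:, t + 1])
        # overflow shows up as inf/nan only after a few more iterations;
        # treat any excursion far outside the unit box as escaped too
        bad |= np.abs(Y[:, t + 1]) > 1e6
        if np.any(bad):
            k = int(np.flatnonzero(bad)[0])
            raise DivergentTrajectoryError(t + 2, _FIVE_SPECIES_NAMES[k])
    return TimeSeriesMatrix(
        names=_FIVE_SPECIES_NAMES,
        times=tuple(range(1, n_steps + 1)),
        values=Y[:, burn_in:],
    )


def sample_bounded_five_species(
    n_steps: int = 15, seed: int | None = None, max_tries: int = 100
) -> TimeSeriesMatrix:
    """Draw random initial conditions until the trajectory stays bounded."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        init = rng.uniform(0.2, 0.8, 5)
        try:
            return simulate_five_species(FiveSpeciesParams(init=init), n_steps)
        except DivergentTrajectoryError:
            continue
    raise DivergentTrajectoryError(0)


def five_species_truth(params: FiveSpeciesParams | None = None) -> GroundTruthNetwork:
    """The directed edges implied by nonzero off-diagonal couplings.

    With the default coefficients this is exactly 12 edges: species 1-3
    influence each other and drive species 4 and 5, which influence
    nothing.
    """
    p = params or FiveSpeciesParams()
    edges = {
        (_FIVE_SPECIES_NAMES[j], _FIVE_SPECIES_NAMES[i])
        for i in range(5)
        for j in range(5)
        if i != j and p.coupling[i, j] != 0.0
    }
    return GroundTruthNetwork(names=_FIVE_SPECIES_NAMES, edges=frozenset(edges))


@dataclass(frozen=True)
class GrnConfig:
    """Configuration of the synthetic gene-network generator.

    A directed random topology (no self-loops, expected in-degree
    ``mean_in_degree``) is sampled with ``topology_seed``; each gene's
    expression follows

        dx_i/dt = m_i * prod_over_regulators(hill term) - degradation_rate * x_i

    where an activator r contributes x_r^h / (K^h + x_r^h) and a
    repressor K^h / (K^h + x_r^h), integrated by fixed-step RK4 from a
    random positive state (``dynamics_seed``), subsampled to
    ``n_timepoints`` equally spaced states over ``sampling_horizon``
    relaxation times (1/degradation_rate), then passed through
    :func:`add_noise` with ``noise_seed``.
    """

    n_genes: int = 20
    topology_seed: int = 0
    dynamics_seed: int = 1
    noise_seed: int = 2
    n_timepoints: int = 10
    noise_level: float = 0.0
    hill_coefficient: float = 2.0
    degradation_rate: float = 1.0
    mean_in_degree: float = 1.5
    activator_prob: float = 0.5
    sampling_horizon: float = 2.0
    rk4_steps: int = 400

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


def _gene_names(G: int) -> tuple[str, ...]:
    width = len(str(G))
    return tuple(f"g{i + 1:0{width}d}" for i in range(G))


def _sample_topology(cfg: GrnConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adjacency (adj[target, source]), signs and per-edge Hill constants."""
    rng = np.random.default_rng(cfg.topology_seed)
    G = cfg.n_genes
    p = min(1.0, cfg.mean_in_degree / (G - 1))
    adj = (rng.random((G, G)) < p) & ~np.eye(G, dtype=bool)
    sign = np.where(rng.random((G, G)) < cfg.activator_prob, 1, -1)
    K = rng.uniform(0.3, 1.0, (G, G))
    return adj, sign, K


def _integrate(
    adj: np.ndarray, sign: np.ndarray, K: np.ndarray, cfg: GrnConfig
) -> np.ndarray:
    """RK4-integrate the Hill-kinetics network; returns genes x timepoints."""
    rng = np.random.default_rng(cfg.dynamics_seed)
    G = cfg.n_genes
    m = rng.uniform(0.5, 1.5, G)
    x = rng.uniform(0.1, 1.0, G)
    h = cfg.hill_coefficient
    Kh = K**cfg.hill_coefficient

    def f(state: np.ndarray) -> np.ndarray:
        xp = np.clip(state, 0.0, None)
        act = xp[None, :] ** h / (Kh + xp[None, :] ** h)
        term = np.where(sign > 0, act, 1.0 - act)
        prod = np.where(adj, term, 1.0).prod(axis=1)
        return m * prod - cfg.degradation_rate * state

    t_end = cfg.sampling_horizon / cfg.degradation_rate
    steps = cfg.rk4_steps
    dt = t_end / steps
    traj = np.empty((steps + 1, G))
    traj[0] = x
    for s in range(steps):
        k1 = f(x)
        k2 = f(x + dt / 2 * k1)
        k3 = f(x + dt / 2 * k2)
        k4 = f(x + dt * k3)
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x)):
            g = int(np.flatnonzero(~np.isfinite(x))[0])
            raise DivergentTrajectoryError(s + 1, _gene_names(G)[g])
        traj[s + 1] = x
    idx = np.linspace(0, steps, cfg.n_timepoints).round().astype(int)
    return traj[idx].T


def simulate_grn(cfg: GrnConfig | None = None) -> tuple[TimeSeriesMatrix, GroundTruthNetwork]:
    """Generate one synthetic expression matrix and its true network."""
    cfg = cfg or GrnConfig()
    adj, sign, K = _sample_topology(cfg)
    data = _integrate(adj, sign, K, cfg)
    names = _gene_names(cfg.n_genes)
    times = tuple(range(1, cfg.n_timepoints + 1))
    matrix = TimeSeriesMatrix(names=names, times=times, values=data)
    if cfg.noise_level > 0:
        matrix = add_noise(matrix, cfg.noise_level, cfg.noise_seed)
    edges = frozenset(
        (names[j], names[i])
        for i in range(cfg.n_genes)
        for j in range(cfg.n_genes)
        if adj[i, j]
    )
    truth = GroundTruthNetwork(names=names, edges=edges)
    return matrix, truth


def add_noise(data: TimeSeriesMatrix, level: float, seed: int | None = None) -> TimeSeriesMatrix:
    """Add Gaussian measurement noise scaled per variable.

    Each entry receives independent N(0, (level * sd_g)^2) noise, where
    sd_g is the clean standard deviation of that variable's series; a
    unitless "noise level" of 0.1 thus perturbs every gene by 10% of its
    own dynamic spread. Level 0 returns the input unchanged.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return data
    rng = np.random.default_rng(seed)
    sd = data.values.std(axis=1, ddof=0)
    noisy = data.values + rng.standard_normal(data.values.shape) * (level * sd)[:, None]
    return TimeSeriesMatrix(names=data.names, times=data.times, values=noisy)
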