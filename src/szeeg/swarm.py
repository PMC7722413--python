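"""Population metaheuristics behind a single maximize-over-a-box interface.

Four algorithms are provided:

* **Artificial Flora** (``af_optimize``): plants spread Gaussian offspring
  whose spread evolves from the parent/grandparent propagation distances;
  offspring survive a fitness- and index-dependent roulette and a fixed
  number of originals is re-selected each generation.
* **Glowworm swarm** (``gso_optimize``): agents carry a decaying luciferin
  level refreshed by the objective, move a fixed step toward a
  probabilistically chosen brighter neighbor inside an adaptive decision
  range, and stay put when locally brightest (which preserves multiple
  peaks).
* **Black hole** (``bh_optimize``): the best star is the black hole; all
  others fall toward it by a random fraction per coordinate, and any star
  inside the event-horizon radius R = G_bh / sum(G_j) is replaced by a
  fresh uniform star.
* **Monkey search** (``ms_optimize``): sign-of-pseudogradient climbing,
  a watch-jump local sampling within the eyesight radius, and a somersault
  reflection through the population-mean pivot.

All four use the maximization convention, share elitism (the best
position ever evaluated is retained, so the best-so-far history is
monotone non-decreasing), count every fitness call, and are fully
deterministic given their seed.

``select_feature_column`` applies any of them to reduce a 10-variant
feature matrix to a single column: the optimizer searches a weight vector
in [0, 1]^10 maximizing the Fisher class-separability ratio of the
weighted column combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import OptimizationError, ParameterError

__all__ = [
    "ObjectiveSpec",
    "AFConfig",
    "GSOConfig",
    "BHConfig",
    "MSConfig",
    "OptimizerResult",
    "SelectedFeature",
    "af_optimize",
    "gso_optimize",
    "bh_optimize",
    "ms_optimize",
    "optimize",
    "OPTIMIZERS",
    "fisher_separability",
    "select_feature_column",
]


@dataclass
class ObjectiveSpec:
    """A fitness to maximize over an axis-aligned box."""

    fitness: Callable[[np.ndarray], float]
    bounds: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ParameterError("each bound must satisfy lo < hi")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.hi - self.lo))


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray          # best-so-far fitness per iteration
    evaluations: int


class _Evaluator:
    """Wraps the fitness: counts calls, guards non-finite values, tracks the best."""

    def __init__(self, objective: ObjectiveSpec):
        self._f = objective.fitness
        self.count = 0
        self.best_x: np.ndarray | None = None
        self.best_f = -np.inf

    def __call__(self, x: np.ndarray) -> float:
        v = float(self._f(np.asarray(x, dtype=float)))
        self.count += 1
        if not np.isfinite(v):
            raise OptimizationError(f"non-finite fitness {v!r} at {np.asarray(x)!r}")
        if v > self.best_f:
            self.best_f = v
            self.best_x = np.array(x, dtype=float)
        return v

    def many(self, xs: np.ndarray) -> np.ndarray:
        return np.array([self(x) for x in xs])

    def result(self, history: list[float]) -> OptimizerResult:
        return OptimizerResult(
            best_position=np.array(self.best_x),
            best_fitness=self.best_f,
            history=np.asarray(history),
            evaluations=self.count,
        )


def _uniform_box(rng: np.random.Generator, objective: ObjectiveSpec, n: int) -> np.ndarray:
    return rng.uniform(objective.lo, objective.hi, size=(n, objective.dim))


def _shift_positive(f: np.ndarray) -> np.ndarray:
    # guard for ratio-based rules when fitness can be <= 0
    return f - f.min() + 1e-12


# ---------------------------------------------------------------------------
# artificial flora
# ---------------------------------------------------------------------------

@dataclass
class AFConfig:
    n_plants: int = 10
    branching: int = 5
    c1: float = 0.8
    c2: float = 0.8
    p_y: float = 0.5
    iterations: int = 100
    seed: int = 0
    spread_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.branching < 1:
            raise ParameterError("n_plants and branching must be >= 1")
        if not 0.0 < self.p_y < 1.0:
            raise ParameterError("p_y must lie in (0, 1)")


def af_optimize(objective: ObjectiveSpec, config: AFConfig | None = None) -> OptimizerResult:
    """Artificial Flora optimization.

    Per generation each original plant spreads ``branching`` Gaussian
    offspring with spread d_h = d1h*rand*c1 + d2h*rand*c2, where d1h/d2h
    are the grandparent/parent propagation distances (d1h' = d2h, d2h' =
    RMS offspring displacement).  Offspring survive with probability
    l = (F/F_max) * p_y^(h*m-1) (fitness shifted positive within the
    generation; h is the fitness rank of the parent, m the seed index);
    the next generation's originals are roulette-selected from the
    survivors, topped up by roulette over the remaining offspring, and a
    new original only replaces its slot's old plant when it improves on
    it.  The propagation distance is used as the Gaussian standard
    deviation by default (``spread_is_variance=True`` restores the
    variance reading, which stalls the spread dynamics near 1).
    """
    cfg = config or AFConfig()
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(objective)
    n, b, d = cfg.n_plants, cfg.branching, objective.dim
    lo, hi = objective.lo, objective.hi
    init_spread = float(np.mean(hi - lo)) / 2.0

    positions = _uniform_box(rng, objective, n)
    fitness = ev.many(positions)
    d1 = np.full(n, init_spread)
    d2 = np.full(n, init_spread)
    history = [ev.best_f]

    for _ in range(cfg.iterations):
        order = np.argsort(-fitness)  # rank best-first so the index penalty is rank-based
        positions, fitness, d1, d2 = positions[order], fitness[order], d1[order], d2[order]

        dh = d1 * rng.uniform(size=n) * cfg.c1 + d2 * rng.uniform(size=n) * cfg.c2
        sigma = np.sqrt(np.maximum(dh, 0.0)) if cfg.spread_is_variance else np.maximum(dh, 0.0)

        offspring = np.repeat(positions, b, axis=0) + rng.standard_normal((n * b, d)) * np.repeat(
            sigma, b
        )[:, None]
        offspring = np.clip(offspring, lo, hi)
        off_fit = ev.many(offspring)

        shifted = _shift_positive(off_fit)
        ranks = np.repeat(np.arange(1, n + 1), b)          # h: parent rank
        seeds = np.tile(np.arange(1, b + 1), n)            # m: seed index
        survival = (shifted / shifted.max()) * cfg.p_y ** (ranks * seeds - 1)
        alive = rng.uniform(size=n * b) < survival

        disp = offspring - np.repeat(positions, b, axis=0)
        rms = np.sqrt(np.mean(disp.reshape(n, b, d) ** 2, axis=(1, 2)))

        alive_idx = np.flatnonzero(alive)
        dead_idx = np.flatnonzero(~alive)
        chosen: list[int] = []
        if alive_idx.size:
            probs = shifted[alive_idx] / shifted[alive_idx].sum()
            take = min(n, alive_idx.size)
            chosen.extend(rng.choice(alive_idx, size=take, replace=False, p=probs).tolist())
        if len(chosen) < n:  # top up by roulette over the remaining offspring
            probs = shifted[dead_idx] / shifted[dead_idx].sum()
            chosen.extend(
                rng.choice(dead_idx, size=n - len(chosen), replace=False, p=probs).tolist()
            )
        chosen_arr = np.asarray(chosen)
        parents = chosen_arr // b
        new_pos = offspring[chosen_arr]
        new_fit = off_fit[chosen_arr]
        new_d1 = d2[parents]
        new_d2 = rms[parents]
        # a new original replaces its slot's old plant only on improvement
        worse = new_fit < fitness
        new_pos[worse] = positions[worse]
        new_fit[worse] = fitness[worse]
        new_d1[worse] = d1[worse]
        new_d2[worse] = d2[worse]
        positions, fitness, d1, d2 = new_pos, new_fit, new_d1, new_d2
        history.append(ev.best_f)

    return ev.result(history)


# ---------------------------------------------------------------------------
# glowworm swarm
# ---------------------------------------------------------------------------

@dataclass
class GSOConfig:
    n_glowworms: int = 40
    f0: float = 5.0                  # initial luciferin
    q0: float | None = None          # initial decision range (default q_st)
    step: float | None = None        # st; default 0.01 * box diagonal
    neighbor_threshold: int = 5      # i_n
    beta: float = 0.08               # decision-range update coefficient
    rho: float = 0.4                 # luciferin decay
    gamma: float = 0.6               # luciferin gain
    q_st: float | None = None        # maximum decision range (default box diagonal)
    iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glowworms < 1:
            raise ParameterError("n_glowworms must be >= 1")
        if not 0.0 < self.rho <= 1.0:
            raise ParameterError("rho must lie in (0, 1]")
        if self.step is not None and self.step <= 0:
            raise ParameterError("step must be > 0")
        if self.q0 is not None and self.q_st is not None and self.q0 > self.q_st:
            raise ParameterError("q0 must not exceed q_st")


def gso_optimize(objective: ObjectiveSpec, config: GSOConfig | None = None) -> OptimizerResult:
    """Glowworm swarm optimization.

    Luciferin update f_j <- (1 - rho) f_j + gamma H(y_j); the neighbor set
    of j holds brighter glowworms within its decision range; one neighbor
    is drawn with probability proportional to the luciferin excess and j
    moves a fixed step along the unit direction toward it.  The decision
    range is nudged by beta * (i_n - |neighbors|), clamped to [0, q_st].
    A glowworm with no brighter neighbor stays put, so separated peaks
    retain their local swarms.
    """
    cfg = config or GSOConfig()
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(objective)
    n = cfg.n_glowworms
    q_st = cfg.q_st if cfg.q_st is not None else objective.diagonal
    q = np.full(n, cfg.q0 if cfg.q0 is not None else q_st)
    st = cfg.step if cfg.step is not None else 0.01 * objective.diagonal
    lo, hi = objective.lo, objective.hi

    pos = _uniform_box(rng, objective, n)
    luci = np.full(n, float(cfg.f0))
    ev.many(pos)
    history = [ev.best_f]

    for _ in range(cfg.iterations):
        fit = ev.many(pos)
        luci = (1.0 - cfg.rho) * luci + cfg.gamma * fit
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        new_pos = pos.copy()
        for j in range(n):
            nbrs = np.flatnonzero((dist[j] < q[j]) & (luci > luci[j]))
            k = nbrs.size
            if k:
                w = luci[nbrs] - luci[j]
                probs = w / w.sum()
                h = rng.choice(nbrs, p=probs)
                direction = pos[h] - pos[j]
                norm = np.linalg.norm(direction)
                if norm > 0:
                    new_pos[j] = np.clip(pos[j] + st * direction / norm, lo, hi)
            q[j] = min(q_st, max(0.0, q[j] + cfg.beta * (cfg.neighbor_threshold - k)))
        pos = new_pos
        history.append(ev.best_f)

    return ev.result(history)


# ---------------------------------------------------------------------------
# black hole
# ---------------------------------------------------------------------------

@dataclass
class BHConfig:
    n_stars: int = 30
    iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stars < 2:
            raise ParameterError("n_stars must be >= 2")


def event_horizon_radius(fitness: np.ndarray, bh_index: int) -> float:
    """R = G_bh / sum_j G_j, computed from the raw fitness values.

    A zero denominator is guarded (R = 0).  With negative fitness sums the
    radius is non-positive and absorption simply never triggers.
    """
    total = float(np.sum(fitness))
    if total == 0.0:
        return 0.0
    return float(fitness[bh_index]) / total


def bh_optimize(objective: ObjectiveSpec, config: BHConfig | None = None) -> OptimizerResult:
    """Black hole optimization.

    Stars fall toward the current best (the black hole) by
    Y <- Y + rand * (Y_bh - Y) per coordinate; a star surpassing the black
    hole swaps roles, and a star within the event-horizon radius of the
    black hole is replaced by a fresh uniform star.
    """
    cfg = config or BHConfig()
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(objective)
    s = cfg.n_stars
    lo, hi = objective.lo, objective.hi

    pos = _uniform_box(rng, objective, s)
    fit = ev.many(pos)
    history = [ev.best_f]

    for _ in range(cfg.iterations):
        bh = int(np.argmax(fit))
        movers = np.arange(s) != bh
        r = rng.uniform(size=(movers.sum(), objective.dim))
        pos[movers] = pos[movers] + r * (pos[bh] - pos[movers])
        pos[movers] = np.clip(pos[movers], lo, hi)
        fit[movers] = ev.many(pos[movers])

        bh = int(np.argmax(fit))  # role swap if a star surpassed the hole
        radius = event_horizon_radius(fit, bh)
        if radius > 0:
            dist = np.linalg.norm(pos - pos[bh], axis=1)
            absorbed = (dist < radius) & (np.arange(s) != bh)
            k = int(absorbed.sum())
            if k:
                fresh = _uniform_box(rng, objective, k)
                pos[absorbed] = fresh
                fit[absorbed] = ev.many(fresh)
        history.append(ev.best_f)

    return ev.result(history)


# ---------------------------------------------------------------------------
# monkey search
# ---------------------------------------------------------------------------

@dataclass
class MSConfig:
    n_monkeys: int = 10
    climb_step: float | None = None      # s; default 0.005 * box diagonal
    eyesight: float | None = None        # e; default 0.05 * box diagonal
    climb_iterations: int = 30           # N_q
    watch_attempts: int = 5
    somersault_interval: tuple[float, float] = (-1.0, 1.0)
    iterations: int = 20
    seed: int = 0
    max_redraws: int = 20

    def __post_init__(self) -> None:
        if self.n_monkeys < 1:
            raise ParameterError("n_monkeys must be >= 1")
        if self.climb_step is not None and self.climb_step <= 0:
            raise ParameterError("climb_step must be > 0")
        if self.eyesight is not None and self.eyesight <= 0:
            raise ParameterError("eyesight must be > 0")
        q, dd = self.somersault_interval
        if not q < dd:
            raise ParameterError("somersault interval must satisfy q < d")


def ms_optimize(objective: ObjectiveSpec, config: MSConfig | None = None) -> OptimizerResult:
    """Monkey search optimization.

    Climb: a random +-s perturbation vector defines the pseudogradient
    (g(a + da) - g(a - da)) / (2 da_k); the monkey steps s * sign of it
    per coordinate.  Watch-jump: uniform samples within the eyesight box
    are accepted on improvement.  Somersault: theta ~ U[q, d] reflects the
    monkey through the population-mean pivot; infeasible proposals are
    redrawn up to ``max_redraws`` times, then clipped to the box.
    """
    cfg = config or MSConfig()
    rng = np.random.default_rng(cfg.seed)
    ev = _Evaluator(objective)
    m, d = cfg.n_monkeys, objective.dim
    lo, hi = objective.lo, objective.hi
    s = cfg.climb_step if cfg.climb_step is not None else 0.005 * objective.diagonal
    eye = cfg.eyesight if cfg.eyesight is not None else 0.05 * objective.diagonal

    pos = _uniform_box(rng, objective, m)
    fit = ev.many(pos)
    history = [ev.best_f]

    def feasible(x: np.ndarray) -> bool:
        return bool(np.all(x >= lo) and np.all(x <= hi))

    def climb(a: np.ndarray) -> np.ndarray:
        for _ in range(cfg.climb_iterations):
            da = s * rng.choice([-1.0, 1.0], size=d)
            g_plus = ev(np.clip(a + da, lo, hi))
            g_minus = ev(np.clip(a - da, lo, hi))
            pseudo = (g_plus - g_minus) / (2.0 * da)
            z = a + s * np.sign(pseudo)
            if feasible(z):
                a = z
        return a

    for _ in range(cfg.iterations):
        for j in range(m):
            a = climb(pos[j])
            fa = ev(a)
            for _ in range(cfg.watch_attempts):
                z = rng.uniform(a - eye, a + eye)
                if feasible(z):
                    fz = ev(z)
                    if fz > fa:
                        a, fa = z, fz
                        break
            pos[j], fit[j] = a, fa
        pivot = pos.mean(axis=0)
        for j in range(m):
            z = None
            for _ in range(cfg.max_redraws):
                theta = rng.uniform(*cfg.somersault_interval)
                cand = pos[j] + theta * (pivot - pos[j])
                if feasible(cand):
                    z = cand
                    break
            if z is None:
                theta = rng.uniform(*cfg.somersault_interval)
                z = np.clip(pos[j] + theta * (pivot - pos[j]), lo, hi)
            pos[j] = z
            fit[j] = ev(z)
        history.append(ev.best_f)

    return ev.result(history)


OPTIMIZERS: dict[str, tuple[Callable, type]] = {
    "af": (af_optimize, AFConfig),
    "gso": (gso_optimize, GSOConfig),
    "bh": (bh_optimize, BHConfig),
    "ms": (ms_optimize, MSConfig),
}


def optimize(objective: ObjectiveSpec, name: str, config=None, seed: int | None = None) -> OptimizerResult:
    """Run the named optimizer; ``seed`` overrides the config seed."""
    if name not in OPTIMIZERS:
        raise ParameterError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    fn, cfg_cls = OPTIMIZERS[name]
    cfg = config if config is not None else cfg_cls()
    if seed is not None:
        cfg = type(cfg)(**{**cfg.__dict__, "seed": int(seed)})
    return fn(objective, cfg)


# ---------------------------------------------------------------------------
# feature-column selection
# ---------------------------------------------------------------------------

def fisher_separability(weights, matrix0, matrix1) -> float:
    """Fisher ratio of the weighted column combination.

    Projects each class matrix onto ``weights`` and returns
    (mean1 - mean0)^2 / (var0 + var1); zero total variance returns 0.
    """
    w = np.asarray(weights, dtype=float).ravel()
    m0 = np.asarray(matrix0, dtype=float)
    m1 = np.asarray(matrix1, dtype=float)
    if m0.ndim != 2 or m1.ndim != 2 or m0.shape[1] != m1.shape[1]:
        raise ParameterError("class matrices must be 2-D with equal column counts")
    if w.size != m0.shape[1]:
        raise ParameterError("weights length must equal the column count")
    y0 = m0 @ w
    y1 = m1 @ w
    denom = float(np.var(y0) + np.var(y1))
    if denom <= 0.0:
        return 0.0
    return float((y1.mean() - y0.mean()) ** 2 / denom)


@dataclass
class SelectedFeature:
    """Optimizer-reduced single feature column for each class."""

    weights: np.ndarray          # renormalized to sum 1
    values0: np.ndarray          # class-0 rows projected, shape (rows0,)
    values1: np.ndarray
    optimizer: str
    result: OptimizerResult

    def project(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=float) @ self.weights


def select_feature_column(matrix0, matrix1, optimizer_name: str,
                          config=None, seed: int | None = None) -> SelectedFeature:
    """Reduce two class matrices to one column via separability-maximizing weights.

    The named optimizer maximizes :func:`fisher_separability` over the box
    [0, 1]^n_columns; the winning weight vector is renormalized to sum 1
    (uniform if it collapses to 0) and applied to both classes.
    """
    m0 = np.asarray(matrix0, dtype=float)
    m1 = np.asarray(matrix1, dtype=float)
    if m0.shape[1] != m1.shape[1]:
        raise ParameterError("class matrices must share the column count")
    ncol = m0.shape[1]
    objective = ObjectiveSpec(
        fitness=lambda w: fisher_separability(w, m0, m1),
        bounds=[(0.0, 1.0)] * ncol,
    )
    res = optimize(objective, optimizer_name, config=config, seed=seed)
    w = np.clip(res.best_position, 0.0, 1.0)
    total = w.sum()
    w = np.full(ncol, 1.0 / ncol) if total <= 0 else w / total
    return SelectedFeature(
        weights=w,
        values0=m0 @ w,
        values1=m1 @ w,
        optimizer=optimizer_name,
        result=res,
    )
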