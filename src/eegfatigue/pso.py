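"""Global-best particle swarm optimizer for the three RBF hyperparameters.

Shi-Eberhart formulation: inertia weight linearly decreasing over the run,
acceleration coefficients c1 = c2 = 2. Dimensions may be searched on a log10
scale (used for the regularization and D-optimality weights, which span seven
orders of magnitude); callers always see positions in natural units.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

#: default hyperparameter box: lambda, rho, beta
DEFAULT_BOUNDS = ((1e-7, 1.0), (1.0, 220.0), (1e-7, 1.0))
DEFAULT_SCALES = ("log", "linear", "log")


@dataclass
class SearchSpace:
    """Per-dimension bounds with a linear or log10 search scale."""

    bounds: Sequence[tuple] = DEFAULT_BOUNDS
    scales: Sequence[str] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.scales):
            raise ValueError("bounds and scales must have equal length")
        for (lo, hi), sc in zip(self.bounds, self.scales):
            if not lo < hi:
                raise ValueError(f"lower bound {lo} must be below upper {hi}")
            if sc not in ("linear", "log"):
                raise ValueError(f"scale must be 'linear' or 'log', got {sc!r}")
            if sc == "log" and lo <= 0:
                raise ValueError("log-scaled dimensions need positive bounds")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    def to_internal(self, pos: np.ndarray) -> np.ndarray:
        out = np.array(pos, dtype=float)
        for i, sc in enumerate(self.scales):
            if sc == "log":
                out[..., i] = np.log10(out[..., i])
        return out

    def to_natural(self, internal: np.ndarray) -> np.ndarray:
        out = np.array(internal, dtype=float)
        for i, sc in enumerate(self.scales):
            if sc == "log":
                out[..., i] = 10.0 ** out[..., i]
        return out

    def internal_bounds(self) -> np.ndarray:
        b = np.asarray(self.bounds, dtype=float)
        lo, hi = b[:, 0].copy(), b[:, 1].copy()
        for i, sc in enumerate(self.scales):
            if sc == "log":
                lo[i], hi[i] = np.log10(lo[i]), np.log10(hi[i])
        return np.column_stack([lo, hi])


@dataclass
class PSOResult:
    best_position: np.ndarray  # natural units
    best_fitness: float
    history: list  # global-best fitness after each iteration
    n_evaluations: int  # p * T (post-initialization)
    n_init_evaluations: int  # p
    positions_log: list = field(default_factory=list)


def optimize(
    fitness: Callable[[np.ndarray], float],
    space: SearchSpace,
    p: int = 15,
    T: int = 30,
    seed: int = 0,
    inertia=(0.9, 0.4),
    c1: float = 2.0,
    c2: float = 2.0,
    velocity_clamp: float = 0.2,
) -> PSOResult:
    """Minimize ``fitness`` over ``space``.

    Exactly ``p`` initialization evaluations plus ``p * T`` iteration
    evaluations are performed; the returned history (one global-best value
    per iteration) is non-increasing. Non-finite fitness values are treated
    as +inf with a warning. A single seeded RNG stream drives the whole run,
    consumed in fixed particle order, so results are reproducible.
    """
    if p < 2:
        raise ValueError("swarm size must be >= 2")
    if T < 1:
        raise ValueError("iteration count must be >= 1")
    rng = np.random.default_rng(seed)
    ib = space.internal_bounds()
    lo, hi = ib[:, 0], ib[:, 1]
    span = hi - lo
    vmax = velocity_clamp * span

    def _eval(u: np.ndarray) -> float:
        val = float(fitness(space.to_natural(u)))
        if not np.isfinite(val):
            warnings.warn("non-finite fitness treated as +inf", stacklevel=3)
            return np.inf
        return val

    x = lo + rng.random((p, space.ndim)) * span
    v = np.zeros((p, space.ndim))
    pbest = x.copy()
    pbest_f = np.array([_eval(x[i]) for i in range(p)])
    gi = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[gi].copy(), float(pbest_f[gi])

    history: list[float] = []
    n_evals = 0
    for t in range(T):
        w = inertia[0] if T == 1 else inertia[0] + (inertia[1] - inertia[0]) * t / (T - 1)
        for i in range(p):
            r1 = rng.random(space.ndim)
            r2 = rng.random(space.ndim)
            v[i] = w * v[i] + c1 * r1 * (pbest[i] - x[i]) + c2 * r2 * (gbest - x[i])
            v[i] = np.clip(v[i], -vmax, vmax)
            x[i] = x[i] + v[i]
            below, above = x[i] < lo, x[i] > hi
            x[i] = np.clip(x[i], lo, hi)
            v[i][below | above] = 0.0
            f = _eval(x[i])
            n_evals += 1
            if f < pbest_f[i]:
                pbest_f[i] = f
                pbest[i] = x[i].copy()
                if f < gbest_f:
                    gbest_f = float(f)
                    gbest = x[i].copy()
        history.append(gbest_f)
    return PSOResult(
        best_position=space.to_natural(gbest),
        best_fitness=gbest_f,
        history=history,
        n_evaluations=n_evals,
        n_init_evaluations=p,
    )
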