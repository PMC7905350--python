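"""Two-level training: swarm search over (lambda, rho, beta) wrapping the
orthogonal-forward-selection RBF learner; fitness is validation-set MSE."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import pso, rols
from .predict import predict
from .rols import EmptySelectionError, RBFNetwork
from .types import FeatureSet


@dataclass
class FitnessContext:
    """Shared state for one lower-level training problem."""

    train: FeatureSet
    val: FeatureSet
    max_terms: Optional[int] = None
    n_evaluations: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.val) < 1:
            raise ValueError("validation set must be non-empty")
        if self.train.n_features != self.val.n_features:
            raise ValueError("train/validation feature dimensions differ")


def fitness(K, ctx: FitnessContext) -> float:
    """Validation MSE of a network trained at K = [lambda, rho, beta].

    An empty lower-level selection penalizes the particle with +inf rather
    than aborting the search.
    """
    lam, rho, beta = float(K[0]), float(K[1]), float(K[2])
    ctx.n_evaluations += 1
    try:
        net, _ = rols.fit(ctx.train.X, ctx.train.y, lam, rho, beta, ctx.max_terms)
    except EmptySelectionError:
        return np.inf
    resid = ctx.val.y.astype(float) - predict(net, ctx.val.X)
    return float(np.mean(resid**2))


@dataclass
class TrainResult:
    network: RBFNetwork
    best_K: np.ndarray  # [lambda, rho, beta]
    best_fitness: float
    history: list
    n_lower_level_fits: int
    n_init_fits: int


def train(
    train_set: FeatureSet,
    val_set: FeatureSet,
    swarm_size: int = 15,
    iterations: int = 30,
    max_terms: Optional[int] = None,
    seed: int = 0,
    space: Optional[pso.SearchSpace] = None,
    pipeline_params: Optional[dict] = None,
) -> TrainResult:
    """Run the full two-level search and refit the final network at the best K.

    The refit is deterministic, so it reproduces the best particle's network
    exactly. Raises if every particle in every iteration was penalized.
    """
    if space is None:
        space = pso.SearchSpace()
    ctx = FitnessContext(train=train_set, val=val_set, max_terms=max_terms)
    result = pso.optimize(
        lambda K: fitness(K, ctx),
        space,
        p=swarm_size,
        T=iterations,
        seed=seed,
    )
    if not np.isfinite(result.best_fitness):
        raise RuntimeError(
            "every hyperparameter candidate failed at the lower level; "
            "widen the search space or raise max_terms"
        )
    lam, rho, beta = result.best_position
    if pipeline_params is None:
        pipeline_params = dict(train_set.params)
        if train_set.norm_stats is not None:
            pipeline_params["norm_stats"] = train_set.norm_stats
    net, _ = rols.fit(
        train_set.X, train_set.y, lam, rho, beta, max_terms, pipeline_params
    )
    return TrainResult(
        network=net,
        best_K=np.asarray(result.best_position),
        best_fitness=result.best_fitness,
        history=result.history,
        n_lower_level_fits=result.n_evaluations,
        n_init_fits=result.n_init_evaluations,
    )


def train_fixed(
    train_set: FeatureSet,
    lam: float,
    rho: float = 110.0,
    beta: float = 1e-4,
    max_terms: Optional[int] = None,
    pipeline_params: Optional[dict] = None,
) -> RBFNetwork:
    """Fixed-hyperparameter baseline pathway (no upper-level search)."""
    if pipeline_params is None:
        pipeline_params = dict(train_set.params)
        if train_set.norm_stats is not None:
            pipeline_params["norm_stats"] = train_set.norm_stats
    net, _ = rols.fit(train_set.X, train_set.y, lam, rho, beta, max_terms, pipeline_params)
    return net
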