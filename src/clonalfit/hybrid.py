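"""Hybrid clonal-selection / differential-evolution trainer for LR weights.

One optimization round clones every antibody ``alpha`` times, runs a DE-style
trial-vector move on each clone, greedily re-selects per antibody, refreshes
the worst ``round(P*B)`` antibodies, and records the population best.  The
loop guard checks the evaluation counter at the top, so a run always finishes
the round it started.

Budget accounting is literal to the published procedure: the initial
population *is* evaluated but the counter is reset to zero immediately
afterwards, so ``max_evaluations`` excludes those first ``P`` evaluations.
Each round then costs ``P*alpha + round(P*B)`` counted evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import lr_model
from .exceptions import ConfigurationError, InvalidInputError
from .metrics import EvalCounter, FitnessSpec, fitness

__all__ = [
    "OptimizerConfig",
    "TrainedModel",
    "round_half_away",
    "create_antibodies",
    "clone",
    "de_local_search",
    "select",
    "receptor_edit",
    "find_best",
    "fit_csa_de_lr",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters shared by all three trainers.

    ``clones`` / ``editing_rate`` are ignored by the plain-DE trainer,
    ``scaling_factor`` / ``crossover_rate`` by the classic clonal trainer.
    """

    lb: float = -64.0
    ub: float = 16.0
    population: int = 20
    clones: int = 3
    editing_rate: float = 0.1
    scaling_factor: float = 0.5
    crossover_rate: float = 0.9
    max_evaluations: int = 30_000
    seed: int = 0

    def validate(self, need_neighbors: bool = True, need_clones: bool = True) -> None:
        if not self.lb < self.ub:
            raise ConfigurationError(f"lb must be < ub, got [{self.lb}, {self.ub}]")
        min_pop = 4 if need_neighbors else 1
        if self.population < min_pop:
            raise ConfigurationError(f"population must be >= {min_pop}, got {self.population}")
        if need_clones:
            if self.clones < 1:
                raise ConfigurationError("clones must be >= 1")
            if not 0 <= self.editing_rate < 1:
                raise ConfigurationError("editing_rate must lie in [0, 1)")
            if round_half_away(self.population * self.editing_rate) >= self.population:
                raise ConfigurationError("round(population * editing_rate) must be < population")
        if need_neighbors:
            if self.scaling_factor <= 0:
                raise ConfigurationError("scaling_factor must be > 0")
            if not 0 <= self.crossover_rate <= 1:
                raise ConfigurationError("crossover_rate must lie in [0, 1]")
        if self.max_evaluations < 0:
            raise ConfigurationError("max_evaluations must be >= 0")

    def with_seed(self, seed: int) -> "OptimizerConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedModel:
    """Result of one optimizer run: the best parameter vector and its trace."""

    params: np.ndarray
    fitness: float
    evaluations_used: int
    best_trace: np.ndarray
    spec: FitnessSpec = field(default_factory=FitnessSpec)

    def predict_proba(self, X):
        return lr_model.predict_proba(self.params, X)

    def predict(self, X):
        return lr_model.predict_class(self.predict_proba(X))

    @property
    def bias(self) -> float:
        return float(self.params[0])

    @property
    def weights(self) -> np.ndarray:
        return self.params[1:]


def create_antibodies(count: int, dim: int, lb: float, ub: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform random candidates: ``lb + u * (ub - lb)`` with u on [0, 1)."""
    if not lb < ub:
        raise ConfigurationError(f"lb must be < ub, got [{lb}, {ub}]")
    if count < 1 or dim < 1:
        raise ConfigurationError("count and dim must be >= 1")
    return lb + rng.random((count, dim)) * (ub - lb)


def clone(W: np.ndarray, alpha: int) -> np.ndarray:
    """Stack ``alpha`` copies of each row: clone ``k`` belongs to antibody ``k // alpha``."""
    if alpha < 1:
        raise ConfigurationError("alpha must be >= 1")
    return np.repeat(np.asarray(W, dtype=float), alpha, axis=0)


def de_local_search(
    C: np.ndarray,
    P: int,
    alpha: int,
    sf: float,
    cr: float,
    lb: float,
    ub: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """DE/rand/1/bin move applied to every clone, in place.

    For clone ``i`` with owner ``j = i // alpha``, three distinct antibodies
    other than ``j`` donate one random clone each; the trial vector
    ``C[p0] + sf * (C[p2] - C[p1])`` replaces the coordinates whose uniform
    draw is <= ``cr``, clipped into ``[lb, ub]``.  There is no forced
    crossover coordinate, so a clone can survive a round unchanged.
    """
    if P < 4:
        raise ConfigurationError("de_local_search needs population >= 4 (three distinct donors)")
    D = C.shape[1]
    indices = np.arange(P)
    for i in range(P * alpha):
        j = i // alpha
        donors = rng.choice(np.delete(indices, j), size=3, replace=False)
        offsets = rng.integers(0, alpha, size=3)
        p0, p1, p2 = donors * alpha + offsets
        arr = C[p0] + sf * (C[p2] - C[p1])
        mask = rng.random(D) <= cr
        C[i, mask] = np.clip(arr[mask], lb, ub)
    return C


def select(W, fit, C, cfit, alpha: int):
    """Per-antibody greedy replacement by its best clone (strict improvement only)."""
    W = np.asarray(W)
    fit = np.asarray(fit)
    P = W.shape[0]
    if C.shape[0] != P * alpha or cfit.shape[0] != P * alpha:
        raise InvalidInputError("clone set shape inconsistent with population and alpha")
    best_offsets = cfit.reshape(P, alpha).argmax(axis=1)
    idxs = np.arange(P) * alpha + best_offsets
    better = cfit[idxs] > fit
    W[better, :] = C[idxs][better, :]
    fit[better] = cfit[idxs][better]
    return W, fit


def receptor_edit(
    W,
    fit,
    B: float,
    lb: float,
    ub: float,
    rng: np.random.Generator,
    fitness_fn: Callable[[np.ndarray], np.ndarray],
):
    """Replace the ``round(P*B)`` lowest-fitness antibodies with fresh draws.

    The replacements are evaluated immediately through ``fitness_fn`` (which
    is expected to advance the budget counter).
    """
    P, D = W.shape
    n = round_half_away(P * B)
    if n >= P:
        raise ConfigurationError("editing would replace the whole population")
    if n == 0:
        return W, fit
    worst = np.argsort(fit, kind="stable")[:n]
    fresh = create_antibodies(n, D, lb, ub, rng)
    W[worst, :] = fresh
    fit[worst] = fitness_fn(fresh)
    return W, fit


def find_best(W, fit):
    """(max fitness, copy of its row); lowest index wins ties."""
    fit = np.asarray(fit)
    if fit.size == 0:
        raise InvalidInputError("empty population")
    i = int(np.argmax(fit))
    return float(fit[i]), np.array(W[i], copy=True)


def _check_training_inputs(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be (M, N) and y a matching length-M vector")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all() or classes.size != 2:
        raise InvalidInputError("y must be binary with both classes present")
    return X, y.astype(np.int64)


def fit_csa_de_lr(
    X,
    y,
    config: OptimizerConfig,
    spec: FitnessSpec | None = None,
    on_iteration: Callable[[np.ndarray, np.ndarray], None] | None = None,
) -> TrainedModel:
    """Train LR parameters with the hybrid clonal-selection + DE loop.

    ``on_iteration(W, fit)`` is called at the end of every round with the
    current population and its fitness vector (read-only views for
    inspection; mutating them voids the training contract).
    """
    spec = spec or FitnessSpec()
    config.validate(need_neighbors=True, need_clones=True)
    X, y = _check_training_inputs(X, y)
    rng = np.random.default_rng(config.seed)
    counter = EvalCounter()
    fit_fn = lambda params: fitness(spec, params, X, y, counter)

    P, alpha = config.population, config.clones
    D = X.shape[1] + 1
    W = create_antibodies(P, D, config.lb, config.ub, rng)
    fit_v = fit_fn(W)
    counter.reset()  # budget excludes the initial population evaluations

    gmax, gpar = find_best(W, fit_v)
    trace = []
    while counter.count < config.max_evaluations:
        C = clone(W, alpha)
        de_local_search(C, P, alpha, config.scaling_factor, config.crossover_rate,
                        config.lb, config.ub, rng)
        cfit = fit_fn(C)
        select(W, fit_v, C, cfit, alpha)
        receptor_edit(W, fit_v, config.editing_rate, config.lb, config.ub, rng, fit_fn)
        gmax, gpar = find_best(W, fit_v)
        trace.append(gmax)
        if on_iteration is not None:
            on_iteration(W, fit_v)

    return TrainedModel(
        params=gpar,
        fitness=gmax,
        evaluations_used=counter.count,
        best_trace=np.asarray(trace, dtype=float),
        spec=spec,
    )
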