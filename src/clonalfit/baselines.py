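"""Ablation trainers: classic clonal selection (permutation hyper-mutation)
and plain generational DE/rand/1/bin, under the hybrid's fitness, bounds and
budget contracts."""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError
from .hybrid import (
    OptimizerConfig,
    TrainedModel,
    _check_training_inputs,
    clone,
    create_antibodies,
    find_best,
    receptor_edit,
)
from .metrics import EvalCounter, FitnessSpec, fitness

__all__ = ["inverse_mutation", "pairwise_mutation", "fit_csa_lr", "fit_de_lr"]


def inverse_mutation(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reverse a random contiguous segment of length >= 4.

    The endpoints j, l are drawn until |j - l| > 2.  For vectors shorter than
    4 coordinates that constraint is unsatisfiable and the operator falls back
    to a pairwise swap.  Either way the coordinate multiset is preserved.
    """
    c = np.asarray(c, dtype=float)
    D = c.size
    if D < 4:
        return pairwise_mutation(c, rng)
    while True:
        j, l = rng.integers(0, D, size=2)
        if abs(int(j) - int(l)) > 2:
            break
    lo, hi = min(j, l), max(j, l)
    out = c.copy()
    out[lo : hi + 1] = out[lo : hi + 1][::-1]
    return out


def pairwise_mutation(c: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Swap two distinct random coordinates."""
    c = np.asarray(c, dtype=float)
    if c.size < 2:
        raise ConfigurationError("pairwise mutation needs at least 2 coordinates")
    j, l = rng.choice(c.size, size=2, replace=False)
    out = c.copy()
    out[j], out[l] = out[l], out[j]
    return out


def fit_csa_lr(X, y, config: OptimizerConfig, spec: FitnessSpec | None = None,
               on_iteration=None) -> TrainedModel:
    """Classic clonal-selection training loop.

    Each round: clone alpha times and evaluate the clones, then per clone try
    an inverse mutation (accept iff strictly better) and otherwise a pairwise
    swap (same rule); assign each antibody its best clone; refresh the worst
    ``round(P*B)``.  Every mutation attempt costs one counted evaluation, the
    clone evaluation costs ``P*alpha`` and editing ``round(P*B)``.
    """
    spec = spec or FitnessSpec()
    config.validate(need_neighbors=False, need_clones=True)
    X, y = _check_training_inputs(X, y)
    rng = np.random.default_rng(config.seed)
    counter = EvalCounter()
    fit_fn = lambda params: fitness(spec, params, X, y, counter)

    P, alpha = config.population, config.clones
    D = X.shape[1] + 1
    W = create_antibodies(P, D, config.lb, config.ub, rng)
    fit_v = fit_fn(W)
    counter.reset()

    gmax, gpar = find_best(W, fit_v)
    trace = []
    while counter.count < config.max_evaluations:
        C = clone(W, alpha)
        cfit = fit_fn(C)
        for i in range(P * alpha):
            mutant = inverse_mutation(C[i], rng)
            mfit = float(fit_fn(mutant)[0])
            if mfit > cfit[i]:
                C[i], cfit[i] = mutant, mfit
                continue
            mutant = pairwise_mutation(C[i], rng)
            mfit = float(fit_fn(mutant)[0])
            if mfit > cfit[i]:
                C[i], cfit[i] = mutant, mfit
        # each antibody adopts its best clone (clones start as exact copies,
        # so this can never lower fitness)
        best_offsets = cfit.reshape(P, alpha).argmax(axis=1)
        idxs = np.arange(P) * alpha + best_offsets
        W = C[idxs].copy()
        fit_v = cfit[idxs].copy()
        receptor_edit(W, fit_v, config.editing_rate, config.lb, config.ub, rng, fit_fn)
        gmax, gpar = find_best(W, fit_v)
        trace.append(gmax)
        if on_iteration is not None:
            on_iteration(W, fit_v)

    return TrainedModel(params=gpar, fitness=gmax, evaluations_used=counter.count,
                        best_trace=np.asarray(trace, dtype=float), spec=spec)


def fit_de_lr(X, y, config: OptimizerConfig, spec: FitnessSpec | None = None,
              on_iteration=None) -> TrainedModel:
    """Plain generational DE/rand/1/bin training loop.

    Mutant = w[i1] + sf * (w[i3] - w[i2]) with three distinct donors other
    than the target; binomial crossover with no forced coordinate; mutated
    coordinates clipped to the bounds; the trial replaces its parent iff
    strictly better.  Initial-population evaluations are not counted, then
    ``P`` per generation.
    """
    spec = spec or FitnessSpec()
    config.validate(need_neighbors=True, need_clones=False)
    X, y = _check_training_inputs(X, y)
    rng = np.random.default_rng(config.seed)
    counter = EvalCounter()
    fit_fn = lambda params: fitness(spec, params, X, y, counter)

    P = config.population
    D = X.shape[1] + 1
    W = create_antibodies(P, D, config.lb, config.ub, rng)
    fit_v = fit_fn(W)
    counter.reset()

    gmax, gpar = find_best(W, fit_v)
    trace = []
    indices = np.arange(P)
    while counter.count < config.max_evaluations:
        trials = W.copy()
        for i in range(P):
            d0, d1, d2 = rng.choice(np.delete(indices, i), size=3, replace=False)
            arr = W[d0] + config.scaling_factor * (W[d2] - W[d1])
            mask = rng.random(D) <= config.crossover_rate
            trials[i, mask] = np.clip(arr[mask], config.lb, config.ub)
        tfit = fit_fn(trials)
        better = tfit > fit_v
        W[better, :] = trials[better, :]
        fit_v[better] = tfit[better]
        gmax, gpar = find_best(W, fit_v)
        trace.append(gmax)
        if on_iteration is not None:
            on_iteration(W, fit_v)

    return TrainedModel(params=gpar, fitness=gmax, evaluations_used=counter.count,
                        best_trace=np.asarray(trace, dtype=float), spec=spec)
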