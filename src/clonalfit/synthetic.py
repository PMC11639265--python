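"""Seeded generators with known logistic structure, for offline testing.

Features are drawn uniformly on [0, 1] to mirror the post-minmax scale the
optimizers see on real tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import Dataset
from .exceptions import GenerationError, InvalidInputError
from .lr_model import predict_proba
from .metrics import MetricReport

__all__ = ["SyntheticSpec", "make_logistic_data", "toy_fixture"]

_MAX_RETRIES = 100


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a logistic-model dataset.

    ``noise='bernoulli'`` samples labels from the model probability;
    ``noise='none'`` thresholds it at 0.5, giving a dataset that is linearly
    separable by ``true_theta`` by construction.  ``margin`` discards
    instances with ``|p - 0.5| < margin`` so separable sets have a fat
    separator.
    """

    n: int
    d: int
    true_theta: tuple[float, ...]
    noise: str = "bernoulli"
    seed: int = 0
    margin: float = 0.0

    def __post_init__(self):
        if self.n < 2 or self.d < 1:
            raise InvalidInputError("need n >= 2 and d >= 1")
        if len(self.true_theta) != self.d + 1:
            raise InvalidInputError("true_theta must have length d + 1 (bias first)")
        if self.noise not in ("bernoulli", "none"):
            raise InvalidInputError("noise must be 'bernoulli' or 'none'")
        if not 0 <= self.margin < 0.5:
            raise InvalidInputError("margin must lie in [0, 0.5)")


def make_logistic_data(spec: SyntheticSpec) -> Dataset:
    """Generate a :class:`Dataset` from a :class:`SyntheticSpec`.

    Deterministic in the spec's seed.  Raises :class:`GenerationError` if a
    sample with both classes (and outside the margin band) cannot be produced
    after a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.asarray(spec.true_theta, dtype=float)
    for _ in range(_MAX_RETRIES):
        X = np.empty((0, spec.d))
        # rejection-sample until n rows clear the margin band
        for _ in range(_MAX_RETRIES):
            batch = rng.random((max(spec.n, 64), spec.d))
            if spec.margin > 0:
                p = predict_proba(theta, batch)
                batch = batch[np.abs(p - 0.5) >= spec.margin]
            X = np.vstack([X, batch])
            if X.shape[0] >= spec.n:
                break
        else:
            raise GenerationError("margin band rejects nearly all instances")
        X = X[: spec.n]
        p = predict_proba(theta, X)
        if spec.noise == "bernoulli":
            y = (rng.random(spec.n) < p).astype(np.int64)
        else:
            y = (p >= 0.5).astype(np.int64)
        if y.min() == 0 and y.max() == 1:
            return Dataset(X=X, y=y,
                           feature_names=tuple(f"x{i}" for i in range(spec.d)),
                           name=f"synthetic-{spec.seed}")
    raise GenerationError("could not generate both classes; check true_theta")


# -- deterministic toy fixture ------------------------------------------------
#
# Metrics for _TOY_THETA on the table below were computed once with a literal
# four-way confusion enumeration and the O(M^2) pairwise AUC rule, and frozen.

_TOY_X = np.array([
    [0.10, 0.90],
    [0.80, 0.20],
    [0.35, 0.65],
    [0.90, 0.85],
    [0.50, 0.45],
    [0.15, 0.10],
    [0.70, 0.60],
    [0.25, 0.40],
])
_TOY_Y = np.array([0, 1, 0, 1, 0, 1, 1, 0])
_TOY_THETA = np.array([-1.0, 3.0, -2.0])

_TOY_REPORT = MetricReport(
    acc=0.75,
    f1=0.6666666666666666,
    mcc=0.5773502691896258,
    roc_auc=0.9375,
    fnr=0.5,
    fpr=0.0,
)


def toy_fixture() -> tuple[Dataset, np.ndarray, MetricReport]:
    """A byte-stable 8x2 dataset, a fixed parameter vector, and its metrics."""
    ds = Dataset(X=_TOY_X.copy(), y=_TOY_Y.copy(),
                 feature_names=("x0", "x1"), name="toy")
    return ds, _TOY_THETA.copy(), _TOY_REPORT
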