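"""Confusion-matrix metrics, ROC-AUC, error transforms and batched fitness.

All fitness variants are *maximized* by the optimizers and are finite for any
input; degenerate denominators resolve to 0 so the search objective stays
total (see the individual functions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import rankdata

from . import lr_model
from .exceptions import ConfigurationError, InvalidInputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "ErrorRates",
    "FitnessSpec",
    "EvalCounter",
    "confusion",
    "accuracy",
    "f1",
    "mcc",
    "error_rates",
    "roc_auc",
    "mean_error",
    "fitness",
]


class ConfusionCounts(NamedTuple):
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The six evaluation metrics reported for one model on one sample."""

    acc: float
    f1: float
    mcc: float
    roc_auc: float
    fnr: float
    fpr: float

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "f1": self.f1,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
            "fnr": self.fnr,
            "fpr": self.fpr,
        }


@dataclass(frozen=True)
class ErrorRates:
    """(FNR, FPR) pair; a rate with a zero denominator is 0 and flagged undefined."""

    fnr: float
    fpr: float
    fnr_undefined: bool = False
    fpr_undefined: bool = False

    def __iter__(self):
        return iter((self.fnr, self.fpr))


_FITNESS_IDS = ("f1", "mcc", "error", "xent")
_ERROR_MODES = ("absolute", "squared")


@dataclass(frozen=True)
class FitnessSpec:
    """Which objective the optimizer maximizes.

    ``id`` is one of ``f1``, ``mcc``, ``error`` (``1/(1+mean_error)``) or
    ``xent`` (``1/(1+J)`` with the summed cross-entropy cost).  ``error_mode``
    picks squared or absolute residuals and only matters for ``id='error'``;
    the default is ``squared``, the literal printed rule.
    """

    id: str = "f1"
    error_mode: str = "squared"

    def __post_init__(self):
        if self.id not in _FITNESS_IDS:
            raise ConfigurationError(f"unknown fitness id {self.id!r}; expected one of {_FITNESS_IDS}")
        if self.error_mode not in _ERROR_MODES:
            raise ConfigurationError(f"unknown error_mode {self.error_mode!r}; expected one of {_ERROR_MODES}")


@dataclass
class EvalCounter:
    """Counts fitness evaluations against the optimizer budget."""

    count: int = 0

    def add(self, n: int) -> None:
        self.count += int(n)

    def reset(self) -> None:
        self.count = 0


def _as_binary(name, arr):
    arr = np.asarray(arr)
    if arr.size == 0:
        raise InvalidInputError(f"{name} must be non-empty")
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise InvalidInputError(f"{name} must contain only 0/1 values, got {vals}")
    return arr.astype(np.int64).ravel()


def confusion(actual, predicted) -> ConfusionCounts:
    """Confusion counts (tp, tn, fp, fn) for binary label arrays."""
    actual = _as_binary("actual", actual)
    predicted = _as_binary("predicted", predicted)
    if actual.shape != predicted.shape:
        raise InvalidInputError("actual and predicted must have equal length")
    tp = int((predicted * actual).sum())
    fp = int(predicted.sum()) - tp
    fn = int(actual.sum()) - tp
    tn = actual.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(actual, predicted) -> float:
    c = confusion(actual, predicted)
    return (c.tp + c.tn) / c.total


def f1(actual, predicted) -> float:
    """Harmonic mean of precision and recall; 0 when tp = 0."""
    c = confusion(actual, predicted)
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2.0 * precision * recall / (precision + recall)


def mcc(actual, predicted) -> float:
    """Matthews correlation coefficient; 0 when any marginal count is 0."""
    c = confusion(actual, predicted)
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def error_rates(actual, predicted) -> ErrorRates:
    """False-negative and false-positive rates.

    FNR = fn / (tp + fn), FPR = fp / (tn + fp).  A rate whose denominator is
    zero (no actual positives / negatives) is reported as 0 and flagged.
    """
    c = confusion(actual, predicted)
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    return ErrorRates(
        fnr=c.fn / pos if pos else 0.0,
        fpr=c.fp / neg if neg else 0.0,
        fnr_undefined=pos == 0,
        fpr_undefined=neg == 0,
    )


def roc_auc(actual, scores, hard: bool = False) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2.

    With ``hard=True`` the scores are first rounded to 0/1 labels, mirroring
    the reading in which published AUC values track ``1 - (FNR + FPR) / 2``.
    """
    actual = _as_binary("actual", actual)
    scores = np.asarray(scores, dtype=float).ravel()
    if actual.shape != scores.shape:
        raise InvalidInputError("actual and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise InvalidInputError("scores must be finite")
    n_pos = int(actual.sum())
    n_neg = actual.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("roc_auc undefined: only one class present")
    if hard:
        scores = (scores >= 0.5).astype(float)
    ranks = rankdata(scores)
    return (ranks[actual == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def mean_error(actual, probabilities, mode: str = "squared") -> float:
    """Mean residual between labels and probabilities.

    ``mode='squared'`` averages squared residuals (the literal printed rule);
    ``mode='absolute'`` averages absolute residuals (the rule's stated name).
    """
    if mode not in _ERROR_MODES:
        raise ConfigurationError(f"unknown error mode {mode!r}")
    actual = np.asarray(actual, dtype=float).ravel()
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    if actual.size == 0:
        raise InvalidInputError("empty input")
    if actual.shape != probabilities.shape:
        raise InvalidInputError("length mismatch")
    if np.any(probabilities < 0) or np.any(probabilities > 1):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    resid = actual - probabilities
    return float(np.mean(resid**2 if mode == "squared" else np.abs(resid)))


def _batch_counts(y, predicted):
    # predicted: K x M of 0/1; returns per-row tp, tn, fp, fn as float arrays
    tp = (predicted * y).sum(axis=1)
    fp = predicted.sum(axis=1) - tp
    fn = y.sum() - tp
    tn = y.size - tp - fp - fn
    return tp, tn, fp, fn


def fitness(spec: FitnessSpec, params, X, y, counter: EvalCounter | None = None):
    """Fitness of each candidate row of ``params`` on ``(X, y)``; higher is better.

    Advances ``counter`` by the number of candidate rows evaluated.  A single
    1-D parameter vector counts as one evaluation and yields a length-1 array.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    y = _as_binary("y", y).astype(float)
    if counter is not None:
        counter.add(params.shape[0])

    if spec.id in ("f1", "mcc"):
        p = lr_model.predict_proba(params, X)
        predicted = (p >= 0.5).astype(float)
        tp, tn, fp, fn = _batch_counts(y, predicted)
        if spec.id == "f1":
            with np.errstate(divide="ignore", invalid="ignore"):
                precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
                recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
                out = np.where(
                    precision + recall > 0,
                    2.0 * precision * recall / np.maximum(precision + recall, 1e-300),
                    0.0,
                )
            out[tp == 0] = 0.0
        else:
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(np.maximum(denom, 1e-300)), 0.0)
        return out
    if spec.id == "error":
        p = lr_model.predict_proba(params, X)
        resid = y - p
        err = np.mean(resid**2 if spec.error_mode == "squared" else np.abs(resid), axis=1)
        return 1.0 / (err + 1.0)
    # xent
    j = np.atleast_1d(lr_model.cross_entropy_cost(params, X, y))
    return 1.0 / (1.0 + j)


def metric_report(actual, probabilities, roc_hard: bool = False) -> MetricReport:
    """All six metrics of one probability vector against binary labels."""
    probabilities = np.asarray(probabilities, dtype=float).ravel()
    predicted = lr_model.predict_class(probabilities)
    rates = error_rates(actual, predicted)
    return MetricReport(
        acc=accuracy(actual, predicted),
        f1=f1(actual, predicted),
        mcc=mcc(actual, predicted),
        roc_auc=roc_auc(actual, probabilities, hard=roc_hard),
        fnr=rates.fnr,
        fpr=rates.fpr,
    )
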