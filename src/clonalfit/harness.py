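"""Experiment orchestration: cross-validated evaluation, random-search
tuning, feature-weight export, paired Wilcoxon comparison and report files."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .baselines import fit_csa_lr, fit_de_lr
from .data_io import Dataset, apply_scaler, fit_scaler, kfold_split
from .exceptions import ConfigurationError, InvalidInputError, UndefinedMetricError
from .hybrid import OptimizerConfig, TrainedModel, fit_csa_de_lr
from .metrics import FitnessSpec, MetricReport, metric_report

__all__ = [
    "ALGORITHMS",
    "CVReport",
    "cross_validate",
    "random_search_tune",
    "mean_feature_weights",
    "wilcoxon_compare",
    "run_experiment",
]

ALGORITHMS = {
    "csa_de_lr": fit_csa_de_lr,
    "csa_lr": fit_csa_lr,
    "de_lr": fit_de_lr,
}

METRIC_NAMES = ("acc", "f1", "mcc", "roc_auc", "fnr", "fpr")

#: metrics printed as percentages (x100, 2 decimals) vs raw rates (3 decimals)
_PERCENT_METRICS = ("acc", "f1", "mcc", "roc_auc")


@dataclass
class CVReport:
    """Per-fold metrics plus mean/std summaries for one (algorithm, dataset) run."""

    dataset: str
    algorithm: str
    k: int
    fold_metrics: list[MetricReport]
    fold_params: list[np.ndarray]
    feature_names: tuple[str, ...]

    def values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, metric) for m in self.fold_metrics])

    def mean(self, metric: str) -> float:
        return float(self.values(metric).mean())

    def std(self, metric: str) -> float:
        # population std across folds (divisor k)
        return float(self.values(metric).std())

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in METRIC_NAMES}

    def format_row(self) -> dict[str, str]:
        """Mean +/- std formatted as in the published tables."""
        out = {}
        for m in METRIC_NAMES:
            mean, std = self.mean(m), self.std(m)
            if m in _PERCENT_METRICS:
                out[m] = f"{100 * mean:.2f} ± {std:.3f}"
            else:
                out[m] = f"{mean:.3f} ± {std:.3f}"
        return out

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "algorithm": self.algorithm,
            "k": self.k,
            "folds": [m.as_dict() for m in self.fold_metrics],
            "mean": {m: self.mean(m) for m in METRIC_NAMES},
            "std": {m: self.std(m) for m in METRIC_NAMES},
            "fold_params": [p.tolist() for p in self.fold_params],
            "feature_names": list(self.feature_names),
        }


def cross_validate(
    algorithm: str,
    config: OptimizerConfig,
    dataset: Dataset,
    k: int = 10,
    seed: int = 0,
    spec: FitnessSpec | None = None,
    scaler: str = "minmax",
    stratified: bool = True,
    roc_hard: bool = False,
) -> CVReport:
    """k-fold CV: scale per fold on training rows only, train, score held-out rows.

    Fold ``i`` trains with optimizer seed ``config.seed + i`` so folds are
    independent but the whole report is reproducible from ``(config, seed)``.
    """
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}; expected one of {sorted(ALGORITHMS)}")
    trainer = ALGORITHMS[algorithm]
    folds = kfold_split(dataset, k=k, seed=seed, stratified=stratified)
    all_idx = np.arange(dataset.n_instances)
    fold_metrics: list[MetricReport] = []
    fold_params: list[np.ndarray] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        sc = fit_scaler(dataset.X[train_idx], method=scaler)
        X_train = apply_scaler(sc, dataset.X[train_idx])
        X_test = apply_scaler(sc, dataset.X[test_idx])
        model: TrainedModel = trainer(X_train, dataset.y[train_idx],
                                      config.with_seed(config.seed + i), spec)
        proba = model.predict_proba(X_test)
        fold_metrics.append(metric_report(dataset.y[test_idx], proba, roc_hard=roc_hard))
        fold_params.append(model.params)
    return CVReport(dataset=dataset.name, algorithm=algorithm, k=k,
                    fold_metrics=fold_metrics, fold_params=fold_params,
                    feature_names=dataset.feature_names)


def _sample_config(space: dict, base: OptimizerConfig, rng: np.random.Generator) -> OptimizerConfig:
    draw = {}
    for name, (low, high, kind) in space.items():
        if kind == "int":
            draw[name] = int(rng.integers(int(low), int(high) + 1))
        elif kind == "float":
            draw[name] = float(low + rng.random() * (high - low))
        else:
            raise ConfigurationError(f"unknown parameter kind {kind!r} for {name!r}")
    return replace(base, **draw)


def random_search_tune(
    algorithm: str,
    space: dict,
    dataset: Dataset,
    iterations: int,
    seed: int = 0,
    k: int = 10,
    spec: FitnessSpec | None = None,
    scaler: str = "minmax",
    objective: str = "acc",
    base_config: OptimizerConfig | None = None,
) -> tuple[OptimizerConfig, list[dict]]:
    """Seeded uniform random search; score = mean k-fold CV of ``objective``.

    Integers are sampled inclusively, reals uniformly.  Returns the argmax
    configuration and the full trial log.
    """
    if iterations < 1:
        raise ConfigurationError("iterations must be >= 1")
    if not space:
        raise ConfigurationError("empty search space")
    if objective not in METRIC_NAMES:
        raise ConfigurationError(f"objective must be one of {METRIC_NAMES}")
    rng = np.random.default_rng(seed)
    base = base_config or OptimizerConfig()
    trials: list[dict] = []
    best_cfg, best_score = None, -np.inf
    for t in range(iterations):
        cfg = _sample_config(space, base, rng)
        need_neighbors = algorithm in ("csa_de_lr", "de_lr")
        need_clones = algorithm in ("csa_de_lr", "csa_lr")
        cfg.validate(need_neighbors=need_neighbors, need_clones=need_clones)
        report = cross_validate(algorithm, cfg, dataset, k=k, seed=seed,
                                spec=spec, scaler=scaler)
        score = report.mean(objective)
        trials.append({"trial": t, "config": dataclasses.asdict(cfg), "score": score})
        if score > best_score:
            best_cfg, best_score = cfg, score
    return best_cfg, trials


def mean_feature_weights(fold_params, feature_names):
    """Across-fold mean of per-feature weights plus the full fold x feature table.

    The bias (first parameter) is excluded from the table and returned
    separately in the means frame.
    """
    params = [np.asarray(p, dtype=float) for p in fold_params]
    lengths = {p.shape[0] for p in params}
    if len(lengths) != 1:
        raise InvalidInputError("fold parameter vectors have inconsistent lengths")
    (d,) = lengths
    if d != len(feature_names) + 1:
        raise InvalidInputError("parameter length must be n_features + 1")
    table = pd.DataFrame([p[1:] for p in params], columns=list(feature_names))
    table.index.name = "fold"
    means = pd.DataFrame({
        "mean_weight": table.mean(axis=0),
    })
    means.attrs["mean_bias"] = float(np.mean([p[0] for p in params]))
    return means, table


def wilcoxon_compare(sample_a, sample_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are removed first.  The null distribution is exact
    (enumeration over sign assignments, computed by convolution, valid with
    midranks) for n <= 25 remaining pairs; otherwise a normal approximation
    with tie correction and a continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 5:
        raise InvalidInputError("need paired samples of equal length >= 5")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise UndefinedMetricError("all paired differences are zero")
    ranks = rankdata(np.abs(diff))
    w_pos = float(ranks[diff > 0].sum())
    if n <= 25:
        # integerize midranks (x2) and convolve the sign-assignment distribution
        r2 = np.rint(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = dist + shifted
        dist /= 2.0**n
        w2 = int(np.rint(2 * w_pos))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def run_experiment(plan: dict, out_dir) -> dict:
    """Execute a cross-validation plan and write CSV/JSON report files.

    ``plan`` keys:

    - ``dataset``: a :class:`Dataset` (callers load or synthesize it)
    - ``algorithms``: list of ``{"name", "config": OptimizerConfig,
      "fitness": FitnessSpec | None}``
    - ``seeds``: list of integers (one CV run per seed)
    - ``folds``: fold count (default 10)
    - ``scaler``: scaling method (default ``minmax``)

    Writes ``metrics.csv`` (formatted mean +/- std per algorithm x seed),
    ``report.json`` (machine-readable per-fold values), and per-algorithm
    weight CSVs.  When two or more algorithms share the seed list, a Wilcoxon
    matrix of every algorithm against the first is added to the report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset: Dataset = plan["dataset"]
    seeds = list(plan.get("seeds", [0]))
    k = int(plan.get("folds", 10))
    scaler = plan.get("scaler", "minmax")

    report: dict = {"dataset": dataset.name, "folds": k, "seeds": seeds, "runs": []}
    rows = []
    per_algo_means: dict[str, dict[str, list[float]]] = {}
    for algo_spec in plan["algorithms"]:
        name = algo_spec["name"]
        config: OptimizerConfig = algo_spec["config"]
        spec = algo_spec.get("fitness")
        per_algo_means[name] = {m: [] for m in METRIC_NAMES}
        for seed in seeds:
            cv = cross_validate(name, config.with_seed(config.seed + 1000 * seed),
                                dataset, k=k, seed=seed, spec=spec, scaler=scaler)
            report["runs"].append({"seed": seed, **cv.to_dict()})
            rows.append({"algorithm": name, "seed": seed, **cv.format_row()})
            for m in METRIC_NAMES:
                per_algo_means[name][m].append(cv.mean(m))
        means, table = mean_feature_weights(
            [np.asarray(p) for r in report["runs"] if r["algorithm"] == name
             for p in r["fold_params"]],
            dataset.feature_names)
        means.to_csv(out_dir / f"weights_mean_{name}.csv")
        table.to_csv(out_dir / f"weights_folds_{name}.csv")

    if len(plan["algorithms"]) >= 2 and len(seeds) >= 5:
        ref = plan["algorithms"][0]["name"]
        comparisons = {}
        for algo_spec in plan["algorithms"][1:]:
            name = algo_spec["name"]
            comparisons[name] = {}
            for m in ("acc", "f1", "mcc"):
                try:
                    comparisons[name][m] = wilcoxon_compare(
                        per_algo_means[ref][m], per_algo_means[name][m])
                except UndefinedMetricError:
                    comparisons[name][m] = None
        report["wilcoxon_vs_" + ref] = comparisons

    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
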