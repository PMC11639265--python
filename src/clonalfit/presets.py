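"""Published tuned hyperparameter presets and the tuning search spaces.

The preset values are the per-dataset best configurations reported for each
trainer after 300 tuning iterations.  The evaluation budget is not part of
the published configuration; ``DEFAULT_MAX_EVALUATIONS`` is this package's
documented default.
"""

from __future__ import annotations

from .hybrid import OptimizerConfig
from .metrics import FitnessSpec

DEFAULT_MAX_EVALUATIONS = 30_000

#: (algorithm, dataset) -> tuned configuration
PRESETS: dict[tuple[str, str], OptimizerConfig] = {
    ("csa_de_lr", "statlog"): OptimizerConfig(
        lb=-48.353, ub=19.487, population=78, clones=4, editing_rate=0.198,
        scaling_factor=0.670, crossover_rate=0.577, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_de_lr", "cleveland"): OptimizerConfig(
        lb=-27.010, ub=24.245, population=27, clones=4, editing_rate=0.165,
        scaling_factor=0.070, crossover_rate=0.554, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_de_lr", "wbcd"): OptimizerConfig(
        lb=-36.035, ub=29.282, population=37, clones=3, editing_rate=0.132,
        scaling_factor=0.167, crossover_rate=0.333, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_de_lr", "wbco"): OptimizerConfig(
        lb=-63.765, ub=32.241, population=10, clones=5, editing_rate=0.053,
        scaling_factor=1.610, crossover_rate=0.958, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_lr", "statlog"): OptimizerConfig(
        lb=-60.839, ub=53.250, population=74, clones=4, editing_rate=0.050,
        max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_lr", "cleveland"): OptimizerConfig(
        lb=-47.767, ub=43.126, population=61, clones=3, editing_rate=0.162,
        max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_lr", "wbcd"): OptimizerConfig(
        lb=-44.305, ub=45.543, population=73, clones=4, editing_rate=0.104,
        max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("csa_lr", "wbco"): OptimizerConfig(
        lb=-61.344, ub=27.328, population=20, clones=5, editing_rate=0.194,
        max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("de_lr", "statlog"): OptimizerConfig(
        lb=-55.968, ub=22.412, population=53, scaling_factor=0.940,
        crossover_rate=0.755, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("de_lr", "cleveland"): OptimizerConfig(
        lb=-34.463, ub=22.809, population=29, scaling_factor=1.790,
        crossover_rate=0.432, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("de_lr", "wbcd"): OptimizerConfig(
        lb=-53.381, ub=38.460, population=70, scaling_factor=0.116,
        crossover_rate=0.651, max_evaluations=DEFAULT_MAX_EVALUATIONS),
    ("de_lr", "wbco"): OptimizerConfig(
        lb=-59.298, ub=53.334, population=50, scaling_factor=0.257,
        crossover_rate=0.884, max_evaluations=DEFAULT_MAX_EVALUATIONS),
}

#: winning optimization metric per replication dataset
BEST_FITNESS: dict[str, FitnessSpec] = {
    "statlog": FitnessSpec("f1"),
    "cleveland": FitnessSpec("mcc"),
    "wbcd": FitnessSpec("mcc"),
    "wbco": FitnessSpec("error"),
}

#: hyperparameter name -> (low, high, kind); kind is 'int' or 'float'
SEARCH_SPACES: dict[str, dict[str, tuple[float, float, str]]] = {
    "csa_de_lr": {
        "lb": (-64, -16, "float"),
        "ub": (16, 64, "float"),
        "population": (10, 80, "int"),
        "clones": (2, 6, "int"),
        "editing_rate": (0.05, 0.2, "float"),
        "scaling_factor": (0.01, 2, "float"),
        "crossover_rate": (0.01, 1, "float"),
    },
    "csa_lr": {
        "lb": (-64, -16, "float"),
        "ub": (16, 64, "float"),
        "population": (10, 80, "int"),
        "clones": (2, 6, "int"),
        "editing_rate": (0.05, 0.2, "float"),
    },
    "de_lr": {
        "lb": (-64, -16, "float"),
        "ub": (16, 64, "float"),
        "population": (10, 80, "int"),
        "scaling_factor": (0.01, 2, "float"),
        "crossover_rate": (0.01, 1, "float"),
    },
}


def get_preset(algorithm: str, dataset: str) -> OptimizerConfig:
    try:
        return PRESETS[(algorithm, dataset)]
    except KeyError:
        raise KeyError(
            f"no preset for algorithm={algorithm!r}, dataset={dataset!r}; "
            f"known: {sorted(PRESETS)}"
        ) from None
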