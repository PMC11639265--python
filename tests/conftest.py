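import numpy as np
import pytest

from clonalfit import OptimizerConfig, SyntheticSpec, make_logistic_data


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def separable_dataset():
    """n=200, d=2, margin 0.1 — linearly separable by construction."""
    return make_logistic_data(
        SyntheticSpec(n=200, d=2, true_theta=(-3.0, 2.0, 4.0),
                      noise="none", seed=7, margin=0.1)
    )


@pytest.fixture
def small_config():
    return OptimizerConfig(lb=-10, ub=10, population=10, clones=3,
                           editing_rate=0.1, scaling_factor=0.6,
                           crossover_rate=0.6, max_evaluations=600, seed=3)


def confusion_oracle(actual, predicted):
    """Literal four-way enumeration of (actual, predicted) pairs."""
    tp = tn = fp = fn = 0
    for a, p in zip(actual, predicted):
        if a == 1 and p == 1:
            tp += 1
        elif a == 0 and p == 0:
            tn += 1
        elif a == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
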