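# clonalfit

Derivative-free training of logistic-regression classifiers with
immune-inspired metaheuristics, plus the evaluation machinery to benchmark
them on clinical tabular data.

Three trainers share one configuration and budget contract:

- **`csa_de_lr`** — the hybrid: a population of candidate parameter vectors
  ("antibodies", bias-first layout `theta[0] = bias`) is cloned, each clone is
  moved by a DE/rand/1/bin trial vector built from three distinct donor
  antibodies, each antibody greedily adopts its best clone on strict
  improvement, and the worst `round(P*B)` antibodies are replaced by fresh
  random draws every round.
- **`csa_lr`** — classic clonal selection: clones are perturbed by segment
  reversal (inverse mutation) and coordinate swap (pairwise mutation),
  accepted only on strict improvement.
- **`de_lr`** — plain generational DE/rand/1/bin with greedy replacement.

Fitness is a classification metric evaluated on the training fold: `f1`,
`mcc`, `error` (`1/(1 + mean residual)`, squared or absolute), or `xent`
(`1/(1 + summed cross-entropy)`). All loops stop at a maximum-evaluation
budget checked at the top of each round; the initial population evaluation
is not counted against the budget.

## Library quick start

```python
from clonalfit import (OptimizerConfig, FitnessSpec, load_dataset,
                       cross_validate, get_preset)

ds = load_dataset("data/uci/breast-cancer-wisconsin.data", "wbco")
report = cross_validate("csa_de_lr", get_preset("csa_de_lr", "wbco"), ds,
                        k=10, seed=0, spec=FitnessSpec("error"), scaler="minmax")
print(report.format_row())          # mean ± std per metric
```

`get_preset(algorithm, dataset)` returns the published tuned hyperparameters
for `statlog | cleveland | wbcd | wbco`; `SEARCH_SPACES` holds the tuning
ranges used by `random_search_tune` (seeded uniform random search scored by
mean k-fold CV accuracy).

## CLI

```bash
clonalfit train    --dataset heart.dat --dialect statlog --preset statlog
clonalfit evaluate --dataset heart.dat --dialect statlog --preset statlog --folds 10
clonalfit tune     --dataset heart.dat --dialect statlog --algorithm csa_de_lr --iterations 20
clonalfit compare  --dataset heart.dat --dialect statlog --preset statlog \
                   --algorithms csa_de_lr,de_lr --repeats 30 --out results/cmp
clonalfit weights  --dataset heart.dat --dialect statlog --preset statlog --out results/w
clonalfit synth    --n 270 --d 13 --seed 3 --out synth.dat   # statlog-like table
```

Dialects: `cleveland` (comma, `?` markers, target 0 vs 1–4),
`statlog` (whitespace, labels {1,2}), `wbco` (comma, leading ID, `?` in
bare-nuclei, classes {2,4}), `wbcd` (comma, leading ID, diagnosis {B,M}).
Rows containing `?` are deleted and counted. Scaling is fit on training rows
only (min–max by default, z-score for `wbcd`).

## Repository layout

```
src/clonalfit/
  lr_model.py    sigmoid / probability / class prediction, cross-entropy cost
  metrics.py     confusion metrics, ROC-AUC, fitness transforms, eval counter
  hybrid.py      the hybrid trainer and its operators
  baselines.py   classic clonal-selection and plain-DE trainers
  data_io.py     UCI dialect loaders, scalers, k-fold split, feature dropping
  synthetic.py   seeded logistic-model data generators and the toy fixture
  harness.py     cross-validation, tuning, weight export, Wilcoxon, reports
  presets.py     published tuned configurations and search spaces
  cli.py         click command-line interface
tests/           pytest suite (unit, property, and acceptance tests)
scripts/acceptance.py
data/uci/        plain-text replication tables (see above)
```
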