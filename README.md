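# nutbreak

Surrogate modelling and five-objective optimization of **drying-assisted
walnut shell breaking**.

Cracking a walnut without crushing the kernel is a trade-off problem.
Drying the nut first (here: hot-air impingement at infrared temperature
*T*, air velocity *V*, down to a target moisture content *MC*, dry basis)
changes the shell's mechanics, and the axis along which force is applied
(loading direction *D*: sutural, longitudinal or vertical) changes the
outcome again.  Five responses describe one run of the process:

| symbol | response | units |
|---|---|---|
| DT  | drying time | min |
| SEC | specific energy consumption | MJ/kg |
| HR  | high kernel rate (kernels not crushed, classes A+B+C by mass) | % |
| WR  | whole kernel rate (intact kernels, class A) | % |
| SR  | shell-breaking rate (shells cracked over more than 3/4) | % |

A good process minimizes DT and SEC while maximizing HR, WR and SR —
five objectives that pull against each other (drying longer to a lower
*MC* improves breaking quality but costs time and energy).

This package is aimed at process engineers and students of surrogate-based
process optimization.  It provides:

* **A factorial data model** (4 × 4 × 4 × 3 = 192-run design over
  *T* ∈ [40, 55] °C, *V* ∈ [1, 4] m/s, *MC* ∈ [10, 25] %, *D* ∈ {1, 2, 3}),
  CSV round-tripping and a seeded 80/20 split (154 training / 38 test runs).
* **A GA-initialized neural-network surrogate** (GA-ANN): a 4–*j*–5
  feed-forward network, min–max normalized to (−1, 1),
  hᵼ = σ(Σᵢ wᵢⱼ xᵢ + bⱼ) with a logsig or tansig hidden layer and linear
  output, trained by full-batch back-propagation.  A real-coded genetic
  algorithm (population 200, 1000 generations, 90 % crossover, 10 %
  mutation, genes in (−3, 3)) first minimizes the network's training MSE
  over the flattened weight/threshold vector, and back-propagation refines
  the best genome — the classic GA-BP hybrid that avoids poor local minima
  from random starts.
* **A five-objective Pareto optimizer** over the operating window: an
  elitist nondominated-sorting GA with crowding distance, hybridized with
  coarse lattice enumeration and Pareto local search (the surrogate costs
  microseconds per evaluation, so the memetic refinement is nearly free),
  minimizing (DT, SEC, −HR, −WR, −SR).
* **A synthetic ground-truth surface**: the original 192-run measurement
  campaign is not publicly deposited, so a documented response surface with
  the reported qualitative trends plus Gaussian noise stands in for it —
  every pipeline stage is testable end to end, including parameter-recovery
  checks against the known truth.
* **Shipped report-table fixtures** with the published comparison numbers,
  and a `reproduce-tables` command that re-derives every printed percentage
  from the raw table values.

## Worked example

```python
import numpy as np
from nutbreak import (
    ANNSurrogate, MOOConfig, NoiseSpec, SurfaceParams,
    generate_dataset, run_nsga2, split_dataset, SplitSpec, evaluate,
)

# 1. simulate the 192-run factorial study
dataset = generate_dataset(SurfaceParams(), NoiseSpec(seed=0))
train_set, test_set = split_dataset(dataset, SplitSpec(seed=0))

# 2. fit the GA-initialized surrogate (reduced search budget)
model = ANNSurrogate(
    n_hidden=12, hidden_transfer="logsig",
    ga_population=60, ga_generations=100, random_state=0,
).fit(train_set.inputs(), train_set.responses())
scores = evaluate(model.params_, test_set)
print("hold-out R2:", {k: round(v, 3) for k, v in scores.r2.items()})

# 3. search the operating window for the Pareto set
front = run_nsga2(model.params_, MOOConfig(population_size=60, generations=150, seed=0))
print(front.to_frame().round(2).head(5).to_string(index=False))
print(f"{len(front)} nondominated process settings")
```

Output:

```
hold-out R2: {'DT': 0.999, 'SEC': 0.998, 'HR': 0.992, 'WR': 0.955, 'SR': 0.942}
 group     T    V   MC  D     DT   SEC    HR    WR    SR
     1 55.00 4.00 25.0  3  71.79  1.22 47.03 19.85 76.67
     2 55.00 4.00 25.0  1  69.07  1.20 52.45 22.91 69.92
     3 47.44 4.00 25.0  1  86.22  1.26 52.44 24.63 61.27
     4 55.00 1.80 10.0  1 916.40 14.24 88.95 51.85 93.62
     5 47.76 3.51 10.0  1 875.61 13.32 90.41 51.30 84.41
18 nondominated process settings
```

The surrogate recovers the synthetic truth with hold-out R² ≥ 0.94 on every
response (DT and SEC nearly perfectly; SR is the noisiest response relative
to its spread).  The front spans the whole trade-off: fast, cheap drying to
high moisture with modest kernel quality (groups 1–3) versus slow, costly
drying to 10 % moisture with intact kernels (groups 4–5).  Group 1 shows
the directional effect — vertical loading buys ~7 points of shell-breaking
rate at the cost of kernel integrity.

## Command line

Every stage is also a CLI subcommand driven by one YAML config with a
mandatory global seed:

```yaml
# config.yaml
seed: 1
output_dir: runs/demo
data: {synthetic: {}}
topology: {hidden_transfer: logsig, n_hidden: 12}
ga: {population_size: 60, generations: 100}
training: {max_epochs: 4000}
moo: {population_size: 60, generations: 150}
```

```sh
nutbreak simulate -c config.yaml          # seeded 192-run dataset CSV
nutbreak train    -c config.yaml          # BP + GA-ANN models and scores
nutbreak optimize -c config.yaml --model runs/demo/model.json
nutbreak validate -c config.yaml --model runs/demo/model.json \
    --condition 54.9 3.66 10.9 3
nutbreak reproduce-tables                 # re-derive the printed report numbers
```

Each stage writes a manifest (config hash, per-stage seeds, artifact
paths), and re-running a stage from the same config reproduces its outputs
byte for byte.

## Layout

```
src/nutbreak/
  dataset.py     factorial data model, CSV I/O, splitting
  metrics.py     process formulas, R²/RMSE, report arithmetic
  surface.py     synthetic ground-truth surface and generator
  network.py     4–j–5 network, training, evaluation, topology search
  estimators.py  scikit-learn estimator facade (ANNSurrogate)
  ga.py          real-coded GA, genome codec, GA-BP hybrid
  moo.py         dominance, NSGA-II-style optimizer, Pareto reports
  pipeline.py    config, seeding, manifests, stage runners
  cli.py         click CLI
  data/          shipped report-table fixtures (CSV)
docs/methods.md  model, assumptions, parameter choices, limitations
```
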