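"""Genetic-algorithm pre-optimization of the network's initial weights.

Plain back-propagation started from random weights is sensitive to the
starting point and can settle in a poor local minimum.  The hybrid here
first runs a real-coded GA over the flattened weight/threshold vector with
the network's training-set error as the fitness, then hands the best
genome to back-propagation for refinement.

Operators: binary tournament selection, per-gene arithmetic (blend)
crossover, per-gene Gaussian mutation with sigma = 10 % of the gene range
clipped back into the range, and elitism.  Fitness callables are
vectorized: they take a (population, length) array and return one fitness
per row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FactorialDataset, SplitSpec, ValidationError, split_dataset, RESPONSE_COLUMNS
from .metrics import EvaluationScores, rmse_reduction_percent
from .network import (
    NetworkParameters,
    NetworkTopology,
    NormalizationBounds,
    TrainingConfig,
    evaluate,
    forward_normalized,
    logsig,
    random_parameters,
    tansig,
    train,
)


@dataclass(frozen=True)
class GAConfig:
    """Real-coded GA settings (population 200, 1000 generations, 90 %
    crossover, 10 % mutation, genes in (-3, 3) by default)."""

    population_size: int = 200
    generations: int = 1000
    crossover_rate: float = 0.90
    mutation_rate: float = 0.10
    gene_range: tuple[float, float] = (-3.0, 3.0)
    elite_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 4 or self.population_size % 2:
            raise ValidationError("population size must be even and >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"{name}={r} outside [0, 1]")
        if self.gene_range[1] <= self.gene_range[0]:
            raise ValidationError("gene range must be nonempty")
        if not 0 <= self.elite_count <= self.population_size:
            raise ValidationError("elite count outside population")


def encode(params: NetworkParameters) -> np.ndarray:
    """Flatten weights and thresholds in the fixed order
    w_ih (row-major), b_h, w_ho (row-major), b_o."""
    return np.concatenate(
        [params.w_ih.ravel(), params.b_h, params.w_ho.ravel(), params.b_o]
    )


def decode(
    genome: np.ndarray,
    topology: NetworkTopology,
    bounds: NormalizationBounds,
) -> NetworkParameters:
    """Inverse of :func:`encode` for a given topology."""
    genome = np.asarray(genome, dtype=float)
    j, n, m = topology.n_hidden, topology.n_inputs, topology.n_outputs
    if genome.shape != (topology.genome_length,):
        raise ValidationError(
            f"genome length {genome.shape} does not match topology "
            f"({topology.genome_length},)"
        )
    pos = 0
    w_ih = genome[pos:pos + j * n].reshape(j, n); pos += j * n
    b_h = genome[pos:pos + j]; pos += j
    w_ho = genome[pos:pos + m * j].reshape(m, j); pos += m * j
    b_o = genome[pos:pos + m]
    return NetworkParameters(w_ih, b_h, w_ho, b_o, bounds, topology)


def _batch_forward_mse(
    genomes: np.ndarray,
    Xg: np.ndarray,
    Yg: np.ndarray,
    topology: NetworkTopology,
) -> np.ndarray:
    """Normalized-scale training MSE for every genome in one shot."""
    P = np.atleast_2d(genomes)
    j, n, m = topology.n_hidden, topology.n_inputs, topology.n_outputs
    pos = 0
    w_ih = P[:, pos:pos + j * n].reshape(-1, j, n); pos += j * n
    b_h = P[:, pos:pos + j]; pos += j
    w_ho = P[:, pos:pos + m * j].reshape(-1, m, j); pos += m * j
    b_o = P[:, pos:pos + m]
    f = logsig if topology.hidden_transfer == "logsig" else tansig
    with np.errstate(over="ignore", invalid="ignore"):
        H = f(np.einsum("pjn,sn->psj", w_ih, Xg) + b_h[:, None, :])
        O = np.einsum("pmj,psj->psm", w_ho, H) + b_o[:, None, :]
        err = np.mean((O - Yg[None, :, :]) ** 2, axis=(1, 2))
    return np.where(np.isfinite(err), err, np.inf)


def ga_fitness(
    genome: np.ndarray,
    training_set: FactorialDataset,
    topology: NetworkTopology,
    bounds: NormalizationBounds,
) -> float:
    """Fitness of one genome: training-set MSE of the decoded network on
    the normalized output scale (lower is fitter)."""
    Xg = bounds.normalize_x(training_set.inputs())
    Yg = bounds.normalize_y(training_set.responses())
    return float(_batch_forward_mse(np.asarray(genome)[None, :], Xg, Yg, topology)[0])


def make_batch_fitness(
    training_set: FactorialDataset,
    topology: NetworkTopology,
    bounds: NormalizationBounds,
):
    """Vectorized fitness over genome populations, for :func:`run_ga`."""
    Xg = bounds.normalize_x(training_set.inputs())
    Yg = bounds.normalize_y(training_set.responses())

    def fitness(population: np.ndarray) -> np.ndarray:
        return _batch_forward_mse(population, Xg, Yg, topology)

    return fitness


def run_ga(
    config: GAConfig,
    fitness,
    genome_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize ``fitness`` over real genomes.

    ``fitness`` maps a (population, genome_length) array to a (population,)
    array.  Returns the best genome and the per-generation best-so-far
    fitness history (monotone non-increasing whenever elites are kept).
    """
    if genome_length <= 0:
        raise ValidationError("genome length must be > 0")
    lo, hi = config.gene_range
    sigma = 0.1 * (hi - lo)
    rng = np.random.default_rng(config.seed)
    N = config.population_size

    pop = rng.uniform(lo, hi, (N, genome_length))
    fit = np.asarray(fitness(pop), dtype=float)
    if not np.any(np.isfinite(fit)):
        raise ValidationError("entire initial population has infinite fitness")

    best_idx = int(np.argmin(fit))
    best_genome = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = np.empty(config.generations)

    for gen in range(config.generations):
        # binary tournament selection of N parents
        a = rng.integers(0, N, N)
        b = rng.integers(0, N, N)
        parents = pop[np.where(fit[a] <= fit[b], a, b)]

        # per-gene arithmetic blend crossover on consecutive pairs
        offspring = parents.copy()
        pairs = N // 2
        do_cx = rng.random(pairs) < config.crossover_rate
        u = rng.random((pairs, genome_length))
        p1, p2 = parents[0::2], parents[1::2]
        c1 = u * p1 + (1.0 - u) * p2
        c2 = u * p2 + (1.0 - u) * p1
        offspring[0::2] = np.where(do_cx[:, None], c1, p1)
        offspring[1::2] = np.where(do_cx[:, None], c2, p2)

        # per-gene Gaussian mutation, clipped to the gene range
        mask = rng.random(offspring.shape) < config.mutation_rate
        noise = rng.normal(0.0, sigma, offspring.shape)
        offspring = np.clip(np.where(mask, offspring + noise, offspring), lo, hi)

        # elitism: carry over the fittest of the current population
        if config.elite_count:
            elite_idx = np.argsort(fit, kind="stable")[: config.elite_count]
            offspring[: config.elite_count] = pop[elite_idx]

        pop = offspring
        fit = np.asarray(fitness(pop), dtype=float)
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_genome = pop[gen_best].copy()
        history[gen] = best_fit

    return best_genome, history


@dataclass
class GAANNReport:
    """Paired comparison of back-propagation alone versus GA-initialized
    back-propagation on the same split."""

    bp_params: NetworkParameters
    ga_params: NetworkParameters
    bp_scores: EvaluationScores
    ga_scores: EvaluationScores
    rmse_reduction: dict[str, float]
    ga_history: np.ndarray


def train_ga_ann(
    dataset: FactorialDataset,
    topology: NetworkTopology,
    ga_config: GAConfig = GAConfig(),
    training_config: TrainingConfig = TrainingConfig(),
    split: SplitSpec | None = None,
) -> GAANNReport:
    """Run the full hybrid pipeline and its baseline side by side.

    Both branches share the split and the seed stream: back-propagation
    from a random start, and back-propagation from the GA's best genome.
    With zero GA generations the hybrid collapses to the baseline exactly.
    """
    split = split or SplitSpec(seed=ga_config.seed)
    train_set, test_set = split_dataset(dataset, split)
    bounds = NormalizationBounds.from_training(
        train_set.inputs(), train_set.responses()
    )
    ss = np.random.SeedSequence(ga_config.seed)
    init_seed, ga_seed = ss.spawn(2)

    bp_init = random_parameters(topology, bounds, np.random.default_rng(init_seed))
    bp_params, _ = train(train_set, topology, bp_init, training_config)
    bp_scores = evaluate(bp_params, test_set)

    if ga_config.generations == 0:
        ga_init = bp_init.copy()
        history = np.empty(0)
    else:
        fitness = make_batch_fitness(train_set, topology, bounds)
        ga_cfg = GAConfig(
            population_size=ga_config.population_size,
            generations=ga_config.generations,
            crossover_rate=ga_config.crossover_rate,
            mutation_rate=ga_config.mutation_rate,
            gene_range=ga_config.gene_range,
            elite_count=ga_config.elite_count,
            seed=int(ga_seed.generate_state(1)[0] % (2**31)),
        )
        best_genome, history = run_ga(ga_cfg, fitness, topology.genome_length)
        ga_init = decode(best_genome, topology, bounds)
    ga_params, _ = train(train_set, topology, ga_init, training_config)
    ga_scores = evaluate(ga_params, test_set)

    reduction = {
        c: rmse_reduction_percent(bp_scores.rmse[c], ga_scores.rmse[c])
        for c in RESPONSE_COLUMNS
    }
    return GAANNReport(
        bp_params=bp_params,
        ga_params=ga_params,
        bp_scores=bp_scores,
        ga_scores=ga_scores,
        rmse_reduction=reduction,
        ga_history=history,
    )
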