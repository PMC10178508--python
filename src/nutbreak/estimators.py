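"""scikit-learn estimator facade over the surrogate network.

``ANNSurrogate`` is a multioutput regressor: ``fit(X, y)`` learns the
min–max bounds from the training arrays, optionally pre-optimizes the
initial weights with the real-coded GA, then refines them by
back-propagation; ``predict(X)`` runs the denormalized forward pass.  It
composes with sklearn model selection and pipelines; the functional API in
:mod:`nutbreak.network` and :mod:`nutbreak.ga` exposes the same primitives
for scripted use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .ga import GAConfig, _batch_forward_mse, decode, run_ga
from .network import (
    NetworkParameters,
    NetworkTopology,
    NormalizationBounds,
    TrainingConfig,
    forward_array,
    random_parameters,
    train_arrays,
)


class ANNSurrogate(RegressorMixin, BaseEstimator):
    """GA-initialized back-propagation network regressor.

    Parameters
    ----------
    n_hidden : int, default=12
        Hidden-layer size j, 1 < j <= 13.
    hidden_transfer : {"logsig", "tansig"}, default="logsig"
        Hidden-layer transfer function; the output layer is linear.
    init : {"ga", "random"}, default="ga"
        Whether the starting weights come from a GA pre-optimization of the
        training error or from a uniform draw in ``gene_range``.
    max_epochs, error_goal, learning_rate, momentum
        Back-propagation settings (full-batch, variable learning rate).
    ga_population, ga_generations, ga_crossover, ga_mutation, ga_elite
        GA settings, used only when ``init="ga"``.
    gene_range : tuple, default=(-3, 3)
        Range of initial weights/thresholds (GA genes and random draws).
    random_state : int, default=0
        Seed for every source of randomness in the fit.

    Attributes
    ----------
    params_ : NetworkParameters
        Fitted weights, thresholds and normalization bounds.
    history_ : ndarray
        Best-so-far training MSE (normalized scale) per epoch.
    ga_history_ : ndarray
        Best-so-far GA fitness per generation (empty when ``init="random"``).
    """

    def __init__(
        self,
        n_hidden: int = 12,
        hidden_transfer: str = "logsig",
        init: str = "ga",
        max_epochs: int = 4000,
        error_goal: float = 1e-5,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        ga_population: int = 200,
        ga_generations: int = 1000,
        ga_crossover: float = 0.9,
        ga_mutation: float = 0.1,
        ga_elite: int = 2,
        gene_range: tuple[float, float] = (-3.0, 3.0),
        random_state: int = 0,
    ) -> None:
        self.n_hidden = n_hidden
        self.hidden_transfer = hidden_transfer
        self.init = init
        self.max_epochs = max_epochs
        self.error_goal = error_goal
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.ga_population = ga_population
        self.ga_generations = ga_generations
        self.ga_crossover = ga_crossover
        self.ga_mutation = ga_mutation
        self.ga_elite = ga_elite
        self.gene_range = gene_range
        self.random_state = random_state

    def fit(self, X, y) -> "ANNSurrogate":
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.ndim == 2 and y.shape[0] == 1 and X.shape[0] != 1:
            y = y.T
        if self.init not in ("ga", "random"):
            raise ValueError(f"init must be 'ga' or 'random', got {self.init!r}")

        topology = NetworkTopology(
            n_hidden=self.n_hidden,
            hidden_transfer=self.hidden_transfer,
            n_inputs=X.shape[1],
            n_outputs=y.shape[1],
        )
        bounds = NormalizationBounds.from_training(X, y)
        ss = np.random.SeedSequence(self.random_state)
        init_seed, ga_seed = ss.spawn(2)

        if self.init == "ga" and self.ga_generations > 0:
            Xg = bounds.normalize_x(X)
            Yg = bounds.normalize_y(y)
            cfg = GAConfig(
                population_size=self.ga_population,
                generations=self.ga_generations,
                crossover_rate=self.ga_crossover,
                mutation_rate=self.ga_mutation,
                gene_range=self.gene_range,
                elite_count=self.ga_elite,
                seed=int(ga_seed.generate_state(1)[0] % (2**31)),
            )
            genome, self.ga_history_ = run_ga(
                cfg,
                lambda P: _batch_forward_mse(P, Xg, Yg, topology),
                topology.genome_length,
            )
            init_params = decode(genome, topology, bounds)
        else:
            init_params = random_parameters(
                topology, bounds, np.random.default_rng(init_seed),
                scale=self.gene_range,
            )
            self.ga_history_ = np.empty(0)

        config = TrainingConfig(
            max_epochs=self.max_epochs,
            error_goal=self.error_goal,
            learning_rate=self.learning_rate,
            momentum=self.momentum,
        )
        self.params_, self.history_ = train_arrays(X, y, init_params, config)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return forward_array(self.params_, X)
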