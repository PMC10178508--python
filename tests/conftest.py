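"""Shared fixtures: one synthetic study, one trained surrogate, one front.

The expensive artefacts (GA-ANN training, the refined Pareto front) are
session-scoped so the recovery, optimizer and closure tests all exercise
the same seeded pipeline run.
"""

import numpy as np
import pytest
from hypothesis import settings

from nutbreak import (
    GAConfig,
    MOOConfig,
    NetworkTopology,
    NoiseSpec,
    SplitSpec,
    SurfaceParams,
    TrainingConfig,
    generate_dataset,
    run_nsga2,
)
from nutbreak.ga import train_ga_ann

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: seed of the study conditions used across the suite (fixed up front)
STUDY_SEED = 0


@pytest.fixture(scope="session")
def surface_params():
    return SurfaceParams()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default 192-run factorial dataset at the default noise level."""
    return generate_dataset(SurfaceParams(), NoiseSpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def gaann_report(synthetic_dataset):
    """BP versus GA-initialized training on the shared study, at the
    reduced GA budget (population 60, 100 generations)."""
    return train_ga_ann(
        synthetic_dataset,
        NetworkTopology(n_hidden=12, hidden_transfer="logsig"),
        GAConfig(population_size=60, generations=100, seed=STUDY_SEED),
        TrainingConfig(max_epochs=4000),
        SplitSpec(seed=STUDY_SEED),
    )


@pytest.fixture(scope="session")
def surrogate_model(gaann_report):
    return gaann_report.ga_params


@pytest.fixture(scope="session")
def pareto_front(surrogate_model):
    """Refined five-objective front at the reduced optimizer budget."""
    return run_nsga2(
        surrogate_model,
        MOOConfig(population_size=60, generations=150, seed=STUDY_SEED),
    )


@pytest.fixture(scope="session")
def evaluation_grid():
    """Dense sweep of the operating window used as a dominance oracle."""
    T = np.linspace(40, 55, 16)
    V = np.linspace(1, 4, 13)
    MC = np.linspace(10, 25, 16)
    return np.array(
        [(t, v, m, d) for t in T for v in V for m in MC for d in (1, 2, 3)]
    )
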