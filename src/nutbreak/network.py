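"""Three-layer feed-forward surrogate network (4 inputs, j hidden, 5 outputs).

Inputs and targets are min–max normalized to (-1, 1) against the training
data.  The hidden layer uses a logsig or tansig transfer; the output layer
is linear (purelin).  Training is full-batch gradient descent on the
normalized-scale MSE with momentum and an adaptive step: steps that
increase the loss by more than a few percent are rejected and the step
size shrinks, otherwise it slowly grows — the classic variable-learning-
rate scheme for small dense networks.  Everything is plain NumPy and fully
deterministic under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    FactorialDataset,
    ProcessCondition,
    ResponseVector,
    SplitSpec,
    ValidationError,
    RESPONSE_COLUMNS,
    split_dataset,
)
from .metrics import EvaluationScores, r_squared, rmse

HIDDEN_TRANSFERS = ("logsig", "tansig")


@dataclass(frozen=True)
class NetworkTopology:
    """4–j–5 topology with a sigmoidal hidden transfer and linear output."""

    n_hidden: int
    hidden_transfer: str = "logsig"
    n_inputs: int = 4
    n_outputs: int = 5

    def __post_init__(self) -> None:
        if not 1 < self.n_hidden <= 13:
            raise ValidationError(
                f"hidden neuron count must satisfy 1 < j <= 13, got {self.n_hidden}"
            )
        if self.hidden_transfer not in HIDDEN_TRANSFERS:
            raise ValidationError(
                f"hidden transfer must be one of {HIDDEN_TRANSFERS}"
            )

    @property
    def genome_length(self) -> int:
        j, n, m = self.n_hidden, self.n_inputs, self.n_outputs
        return j * n + j + m * j + m


def hidden_neuron_candidates(n_in: int, n_out: int) -> range:
    """Candidate hidden-layer sizes from the usual sizing heuristics.

    Union of j < n-1, j < sqrt(n+m) + a (a an integer 0..10), j = log2(n)
    rounded, and j = 2n+1, restricted to j > 1.  When sqrt(n+m) + 10 lands
    on an integer the bound is taken as closed, so a 4-input 5-output
    network gets candidates 2..13.
    """
    if n_in < 1 or n_out < 1:
        raise ValidationError("layer sizes must be >= 1")
    root = math.sqrt(n_in + n_out) + 10.0
    upper_root = int(root) if float(root).is_integer() else math.floor(root)
    candidates: set[int] = set()
    candidates.update(range(1, n_in - 1))            # j < n - 1
    candidates.update(range(1, upper_root + 1))      # j <= closure of sqrt bound
    candidates.add(round(math.log2(n_in)))
    candidates.add(2 * n_in + 1)
    candidates = {j for j in candidates if j > 1}
    lo, hi = min(candidates), max(candidates)
    assert candidates == set(range(lo, hi + 1))
    return range(lo, hi + 1)


def logsig(x):
    """1 / (1 + e^-x), the logistic sigmoid mapping into (0, 1)."""
    with np.errstate(over="ignore"):  # saturates cleanly at 0
        return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def tansig(x):
    """2 / (1 + e^-2x) - 1, the hyperbolic-tangent sigmoid into (-1, 1)."""
    with np.errstate(over="ignore"):
        return 2.0 / (1.0 + np.exp(-2.0 * np.asarray(x, dtype=float))) - 1.0


@dataclass(frozen=True)
class NormalizationBounds:
    """Per-variable min/max taken from the training data, for the (-1, 1)
    min–max transform and its inverse."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: np.ndarray
    y_max: np.ndarray

    def __post_init__(self) -> None:
        for lo, hi, tag in ((self.x_min, self.x_max, "x"), (self.y_min, self.y_max, "y")):
            if np.any(np.asarray(hi) <= np.asarray(lo)):
                raise ValidationError(f"degenerate {tag} bounds: max must exceed min")

    @classmethod
    def from_training(cls, X: np.ndarray, Y: np.ndarray) -> "NormalizationBounds":
        return cls(
            x_min=X.min(axis=0), x_max=X.max(axis=0),
            y_min=Y.min(axis=0), y_max=Y.max(axis=0),
        )

    def normalize_x(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    def normalize_y(self, Y: np.ndarray) -> np.ndarray:
        return 2.0 * (Y - self.y_min) / (self.y_max - self.y_min) - 1.0

    def denormalize_y(self, Yg: np.ndarray) -> np.ndarray:
        return (self.y_max - self.y_min) * (Yg + 1.0) / 2.0 + self.y_min


@dataclass
class NetworkParameters:
    """Weights and thresholds of the network plus its normalization bounds."""

    w_ih: np.ndarray  # (j, 4)
    b_h: np.ndarray   # (j,)
    w_ho: np.ndarray  # (5, j)
    b_o: np.ndarray   # (5,)
    bounds: NormalizationBounds
    topology: NetworkTopology

    def __post_init__(self) -> None:
        j = self.topology.n_hidden
        n, m = self.topology.n_inputs, self.topology.n_outputs
        shapes = {
            "w_ih": (self.w_ih.shape, (j, n)),
            "b_h": (self.b_h.shape, (j,)),
            "w_ho": (self.w_ho.shape, (m, j)),
            "b_o": (self.b_o.shape, (m,)),
        }
        for name, (got, want) in shapes.items():
            if got != want:
                raise ValidationError(f"{name} has shape {got}, expected {want}")
        for name in ("w_ih", "b_h", "w_ho", "b_o"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains non-finite values")

    def copy(self) -> "NetworkParameters":
        return NetworkParameters(
            self.w_ih.copy(), self.b_h.copy(), self.w_ho.copy(), self.b_o.copy(),
            self.bounds, self.topology,
        )

    def to_json(self, path: str | Path, provenance: dict | None = None) -> Path:
        path = Path(path)
        payload = {
            "topology": {
                "n_hidden": self.topology.n_hidden,
                "hidden_transfer": self.topology.hidden_transfer,
                "n_inputs": self.topology.n_inputs,
                "n_outputs": self.topology.n_outputs,
            },
            "w_ih": self.w_ih.tolist(),
            "b_h": self.b_h.tolist(),
            "w_ho": self.w_ho.tolist(),
            "b_o": self.b_o.tolist(),
            "bounds": {
                "x_min": np.asarray(self.bounds.x_min).tolist(),
                "x_max": np.asarray(self.bounds.x_max).tolist(),
                "y_min": np.asarray(self.bounds.y_min).tolist(),
                "y_max": np.asarray(self.bounds.y_max).tolist(),
            },
            "provenance": provenance or {},
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkParameters":
        payload = json.loads(Path(path).read_text())
        topo = NetworkTopology(**payload["topology"])
        b = payload["bounds"]
        bounds = NormalizationBounds(
            np.asarray(b["x_min"]), np.asarray(b["x_max"]),
            np.asarray(b["y_min"]), np.asarray(b["y_max"]),
        )
        return cls(
            np.asarray(payload["w_ih"]), np.asarray(payload["b_h"]),
            np.asarray(payload["w_ho"]), np.asarray(payload["b_o"]),
            bounds, topo,
        )


def random_parameters(
    topology: NetworkTopology,
    bounds: NormalizationBounds,
    rng: np.random.Generator,
    scale: tuple[float, float] = (-3.0, 3.0),
) -> NetworkParameters:
    """Uniform random weights/thresholds in the GA gene range, so plain
    back-propagation runs and GA-initialized runs start from comparable
    distributions."""
    j, n, m = topology.n_hidden, topology.n_inputs, topology.n_outputs
    lo, hi = scale
    return NetworkParameters(
        w_ih=rng.uniform(lo, hi, (j, n)),
        b_h=rng.uniform(lo, hi, j),
        w_ho=rng.uniform(lo, hi, (m, j)),
        b_o=rng.uniform(lo, hi, m),
        bounds=bounds,
        topology=topology,
    )


def _hidden(params: NetworkParameters, Xg: np.ndarray) -> np.ndarray:
    Z = Xg @ params.w_ih.T + params.b_h
    f = logsig if params.topology.hidden_transfer == "logsig" else tansig
    return f(Z)


def forward_normalized(params: NetworkParameters, Xg: np.ndarray) -> np.ndarray:
    """Forward pass on the normalized scale: (n, 4) -> (n, 5)."""
    H = _hidden(params, Xg)
    return H @ params.w_ho.T + params.b_o


def forward_array(params: NetworkParameters, X: np.ndarray) -> np.ndarray:
    """Forward pass on raw conditions: normalize, propagate, denormalize."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.topology.n_inputs:
        raise ValidationError(
            f"expected {params.topology.n_inputs} inputs, got {X.shape[1]}"
        )
    Yg = forward_normalized(params, params.bounds.normalize_x(X))
    return params.bounds.denormalize_y(Yg)


def forward(params: NetworkParameters, x: ProcessCondition) -> ResponseVector:
    """Surrogate prediction for one process condition."""
    y = forward_array(params, x.as_array()[None, :])[0]
    return ResponseVector(
        DT=max(y[0], np.finfo(float).tiny),
        SEC=max(y[1], np.finfo(float).tiny),
        HR=float(np.clip(y[2], 0.0, 100.0)),
        WR=float(np.clip(y[3], 0.0, min(100.0, max(y[2], 0.0)))),
        SR=float(np.clip(y[4], 0.0, 100.0)),
    )


@dataclass(frozen=True)
class TrainingConfig:
    """Back-propagation hyperparameters (the variable-learning-rate,
    momentum full-batch scheme)."""

    max_epochs: int = 4000
    error_goal: float = 1e-5      # MSE on the normalized scale
    learning_rate: float = 0.05
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_error_ratio: float = 1.04
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0:
            raise ValidationError("max_epochs must be >= 0")
        if self.error_goal < 0:
            raise ValidationError("error_goal must be >= 0")


def _mse(params: NetworkParameters, Xg: np.ndarray, Yg: np.ndarray) -> float:
    E = forward_normalized(params, Xg) - Yg
    return float(np.mean(E**2))


def _gradients(params, Xg, Yg):
    H = _hidden(params, Xg)
    O = H @ params.w_ho.T + params.b_o
    E = O - Yg
    n_terms = E.size
    dO = 2.0 * E / n_terms
    g_who = dO.T @ H
    g_bo = dO.sum(axis=0)
    dH = dO @ params.w_ho
    if params.topology.hidden_transfer == "logsig":
        dZ = dH * H * (1.0 - H)
    else:
        dZ = dH * (1.0 - H**2)
    g_wih = dZ.T @ Xg
    g_bh = dZ.sum(axis=0)
    loss = float(np.mean(E**2))
    return loss, (g_wih, g_bh, g_who, g_bo)


def train(
    training_set: FactorialDataset,
    topology: NetworkTopology,
    init: NetworkParameters,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkParameters, np.ndarray]:
    """Back-propagation refinement of ``init`` on the training set.

    Returns the best parameters seen (training MSE never above the initial
    MSE) and the per-epoch history of the best-so-far normalized MSE, which
    is monotone non-increasing by construction.
    """
    if len(training_set) == 0:
        raise ValidationError("training set is empty")
    if init.topology != topology:
        raise ValidationError("init parameters do not match the topology")
    X, Y = training_set.inputs(), training_set.responses()
    return train_arrays(X, Y, init, config)


def train_arrays(
    X: np.ndarray,
    Y: np.ndarray,
    init: NetworkParameters,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkParameters, np.ndarray]:
    """Array-level back-propagation core used by :func:`train` and the
    estimator facade."""
    Xg = init.bounds.normalize_x(X)
    Yg = init.bounds.normalize_y(Y)

    params = init.copy()
    arrays = ["w_ih", "b_h", "w_ho", "b_o"]
    velocity = [np.zeros_like(getattr(params, a)) for a in arrays]
    lr = config.learning_rate

    loss = _mse(params, Xg, Yg)
    best = params.copy()
    best_loss = loss
    history = np.empty(config.max_epochs)

    for epoch in range(config.max_epochs):
        if best_loss <= config.error_goal:
            history = history[:epoch]
            break
        cur_loss, grads = _gradients(params, Xg, Yg)
        trial = params.copy()
        for i, a in enumerate(arrays):
            velocity[i] = config.momentum * velocity[i] - lr * grads[i]
            setattr(trial, a, getattr(trial, a) + velocity[i])
        new_loss = _mse(trial, Xg, Yg)
        if not np.isfinite(new_loss):
            raise ValidationError(
                f"training diverged at epoch {epoch}: loss={new_loss}, lr={lr}"
            )
        if new_loss > cur_loss * config.max_error_ratio:
            # reject the step: shrink the rate and drop the momentum memory
            lr *= config.lr_decrease
            velocity = [np.zeros_like(v) for v in velocity]
        else:
            params = trial
            if new_loss < cur_loss:
                lr = min(lr * config.lr_increase, 50.0)
            if new_loss < best_loss:
                best_loss = new_loss
                best = params.copy()
        history[epoch] = best_loss

    return best, history


def evaluate(params: NetworkParameters, test_set: FactorialDataset) -> EvaluationScores:
    """Per-response R² and RMSE on the denormalized scale."""
    if len(test_set) == 0:
        raise ValidationError("test set is empty")
    Y = test_set.responses()
    P = forward_array(params, test_set.inputs())
    return EvaluationScores(
        r2={c: r_squared(Y[:, k], P[:, k]) for k, c in enumerate(RESPONSE_COLUMNS)},
        rmse={c: rmse(Y[:, k], P[:, k]) for k, c in enumerate(RESPONSE_COLUMNS)},
    )


@dataclass
class TopologySearchResult:
    """Mean scores per (hidden transfer, hidden size) candidate over
    replicate trainings, plus the selected pair."""

    table: pd.DataFrame
    selected: tuple[str, int]


def topology_search(
    dataset: FactorialDataset,
    candidates=None,
    replicates: int = 10,
    seed: int = 0,
    split: SplitSpec | None = None,
    config: TrainingConfig | None = None,
    transfers=HIDDEN_TRANSFERS,
) -> TopologySearchResult:
    """Grid the candidate topologies, train ``replicates`` fresh random
    initializations per candidate on one fixed split, and average the
    test-set R² and RMSE per response.

    Selection: smallest mean rank over the ten score columns (R² ranked
    descending, RMSE ascending); ties go to the smaller hidden layer.
    """
    if candidates is None:
        candidates = hidden_neuron_candidates(4, 5)
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("no topology candidates given")
    split = split or SplitSpec(seed=seed)
    config = config or TrainingConfig()
    train_set, test_set = split_dataset(dataset, split)
    bounds = NormalizationBounds.from_training(train_set.inputs(), train_set.responses())
    ss = np.random.SeedSequence(seed)

    rows = []
    for transfer in transfers:
        for j in candidates:
            topo = NetworkTopology(n_hidden=j, hidden_transfer=transfer)
            r2_acc = np.zeros(5)
            rmse_acc = np.zeros(5)
            for child in ss.spawn(replicates):
                rng = np.random.default_rng(child)
                init = random_parameters(topo, bounds, rng)
                fitted, _ = train(train_set, topo, init, config)
                scores = evaluate(fitted, test_set)
                r2_acc += [scores.r2[c] for c in RESPONSE_COLUMNS]
                rmse_acc += [scores.rmse[c] for c in RESPONSE_COLUMNS]
            row = {"hidden_transfer": transfer, "n_hidden": j}
            for k, c in enumerate(RESPONSE_COLUMNS):
                row[f"{c}_R2"] = r2_acc[k] / replicates
                row[f"{c}_RMSE"] = rmse_acc[k] / replicates
            rows.append(row)
    table = pd.DataFrame(rows)

    score_cols = [f"{c}_R2" for c in RESPONSE_COLUMNS] + [f"{c}_RMSE" for c in RESPONSE_COLUMNS]
    ranks = pd.DataFrame(index=table.index)
    for col in score_cols:
        ascending = col.endswith("_RMSE")
        ranks[col] = table[col].rank(ascending=ascending, method="min")
    mean_rank = ranks.mean(axis=1)
    order = sorted(
        table.index, key=lambda i: (mean_rank[i], table.loc[i, "n_hidden"])
    )
    best = table.loc[order[0]]
    return TopologySearchResult(
        table=table, selected=(str(best["hidden_transfer"]), int(best["n_hidden"]))
    )
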