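"""Five-objective Pareto optimization of the trained surrogate.

The decision vector is a process condition (T, V, MC continuous within the
operating window, loading direction D integer in {1, 2, 3}); the five
objectives are, in minimization convention, (DT, SEC, -HR, -WR, -SR).  The
optimizer is the elitist nondominated-sorting GA with crowding-distance
diversity: simulated-binary crossover and clipped Gaussian mutation for
the continuous genes, uniform inheritance and random-reset mutation for
the direction gene.  The returned Pareto set is the final nondominated
front, capped at ceil(fraction x population) members chosen by crowding
distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import (
    CONDITION_BOUNDS,
    COLUMNS,
    FactorialDataset,
    ProcessCondition,
    ResponseVector,
    ValidationError,
    RESPONSE_COLUMNS,
)
from .metrics import percent_change, relative_error_percent
from .network import NetworkParameters, forward_array

#: sign map from response space to minimization convention
_SIGNS = np.array([1.0, 1.0, -1.0, -1.0, -1.0])

_LOWER = np.array([CONDITION_BOUNDS["T"][0], CONDITION_BOUNDS["V"][0],
                   CONDITION_BOUNDS["MC"][0], 1.0])
_UPPER = np.array([CONDITION_BOUNDS["T"][1], CONDITION_BOUNDS["V"][1],
                   CONDITION_BOUNDS["MC"][1], 3.0])


class ConstraintError(ValidationError):
    """Condition violates the operating-window constraints."""


@dataclass(frozen=True)
class MOOConfig:
    """Nondominated-sorting GA settings (population 120, 1000 generations,
    front fraction 0.3 by default).

    ``lattice_enumeration`` and ``local_search_rounds`` control the memetic
    refinement around the GA: because one surrogate evaluation costs
    microseconds, the optimizer also enumerates a factorial lattice of the
    operating window at half the experimental level spacing and polishes
    the pooled nondominated set with a coordinate-probing Pareto local
    search.  Both strengthen convergence of the returned front and can be
    switched off for a bare GA run.
    """

    population_size: int = 120
    generations: int = 1000
    crossover_rate: float = 0.90
    mutation_rate: float = 0.10
    pareto_fraction: float = 0.3
    seed: int = 0
    lattice_enumeration: bool = True
    local_search_rounds: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.pareto_fraction <= 1.0:
            raise ValidationError("pareto fraction must lie in (0, 1]")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.population_size < 4:
            raise ValidationError("population size must be >= 4")


@dataclass(frozen=True)
class ParetoSolution:
    """A feasible condition with its surrogate-predicted responses."""

    condition: ProcessCondition
    predicted: ResponseVector


@dataclass
class ParetoSet:
    """Ordered collection of Pareto solutions.

    ``validate_nondominated`` enforces mutual nondomination; leave it off
    for sets reconstructed from rounded report tables, where ties
    introduced by printing can create spurious dominance.
    """

    solutions: list[ParetoSolution]

    def __init__(self, solutions, validate_nondominated: bool = False):
        self.solutions = list(solutions)
        if validate_nondominated:
            F = self.objectives()
            for i in range(len(F)):
                for k in range(len(F)):
                    if i != k and dominates(F[i], F[k]):
                        raise ValidationError(
                            f"solution {i} dominates solution {k}"
                        )

    def __len__(self) -> int:
        return len(self.solutions)

    def __getitem__(self, i) -> ParetoSolution:
        return self.solutions[i]

    def objectives(self) -> np.ndarray:
        """(n, 5) objective matrix in minimization convention."""
        Y = np.array([s.predicted.as_array() for s in self.solutions])
        return Y * _SIGNS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            np.concatenate([s.condition.as_array(), s.predicted.as_array()])
            for s in self.solutions
        ]
        frame = pd.DataFrame(rows, columns=COLUMNS)
        frame["D"] = frame["D"].astype(int)
        frame.insert(0, "group", np.arange(1, len(frame) + 1))
        return frame

    @classmethod
    def from_dataset(cls, dataset: FactorialDataset) -> "ParetoSet":
        return cls(
            ParetoSolution(condition=c, predicted=r)
            for c, r in dataset.records
        )


def objective_eval(
    condition: ProcessCondition, model: NetworkParameters
) -> np.ndarray:
    """Surrogate objectives at one condition: (DT, SEC, -HR, -WR, -SR)."""
    x = condition.as_array()
    if np.any(x < _LOWER) or np.any(x > _UPPER):
        raise ConstraintError(f"condition {x} outside the operating window")
    return forward_array(model, x[None, :])[0] * _SIGNS


def objective_eval_array(X: np.ndarray, model: NetworkParameters) -> np.ndarray:
    """Batch objectives for (n, 4) conditions."""
    return forward_array(model, X) * _SIGNS


def dominates(u: np.ndarray, v: np.ndarray) -> bool:
    """True iff u is no worse than v everywhere and strictly better
    somewhere (minimization)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError(f"shape mismatch: {u.shape} vs {v.shape}")
    return bool(np.all(u <= v) and np.any(u < v))


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """(n, n) boolean matrix: entry [i, k] true iff i dominates k."""
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    return le & lt


def fast_nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Partition objective vectors into ranked fronts F1, F2, ...

    F1 is the nondominated set; each later front is dominated only by
    members of earlier fronts.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if len(F) == 0:
        raise ValidationError("empty population")
    dom = _domination_matrix(F)
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # pragma: no cover - cannot happen for finite F
            raise RuntimeError("nondominated sort failed to progress")
        fronts.append(np.flatnonzero(current))
        remaining &= ~current
        n_dominators = dom[remaining].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front.

    Boundary members per objective get infinity; interior members get the
    sum over objectives of the neighbour gap normalized by the objective
    span.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    n, m = F.shape
    if n == 0:
        raise ValidationError("empty front")
    d = np.zeros(n)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        vals = F[order, k]
        span = vals[-1] - vals[0]
        d[order[0]] = np.inf
        d[order[-1]] = np.inf
        if span > 0 and n > 2:
            gaps = (vals[2:] - vals[:-2]) / span
            interior = order[1:-1]
            d[interior] = d[interior] + gaps
    return d


def _sbx_crossover(p1, p2, lo, hi, rng, eta: float = 15.0):
    """Simulated-binary crossover per gene, clipped to bounds."""
    u = rng.random(p1.shape)
    beta = np.where(
        u <= 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)),
        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)),
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _make_offspring(pop, rank, crowd, config, rng):
    N = len(pop)
    cont = slice(0, 3)

    def tournament():
        a = rng.integers(0, N, N)
        b = rng.integers(0, N, N)
        better = (rank[a] < rank[b]) | ((rank[a] == rank[b]) & (crowd[a] > crowd[b]))
        return pop[np.where(better, a, b)]

    parents = tournament()
    off = parents.copy()
    pairs = N // 2
    p1, p2 = parents[0::2], parents[1::2]
    do_cx = rng.random(pairs) < config.crossover_rate
    c1, c2 = _sbx_crossover(p1[:, cont], p2[:, cont], _LOWER[:3], _UPPER[:3], rng)
    off[0::2, cont] = np.where(do_cx[:, None], c1, p1[:, cont])
    off[1::2, cont] = np.where(do_cx[:, None], c2, p2[:, cont])
    # direction gene: uniform inheritance from either parent under crossover
    pick = rng.random(pairs) < 0.5
    off[0::2, 3] = np.where(do_cx, np.where(pick, p1[:, 3], p2[:, 3]), p1[:, 3])
    off[1::2, 3] = np.where(do_cx, np.where(pick, p2[:, 3], p1[:, 3]), p2[:, 3])

    # mutation: clipped Gaussian on continuous genes, random reset on D
    sigma = 0.1 * (_UPPER[:3] - _LOWER[:3])
    mask = rng.random((N, 3)) < config.mutation_rate
    noise = rng.normal(0.0, sigma, (N, 3))
    off[:, cont] = np.clip(
        np.where(mask, off[:, cont] + noise, off[:, cont]), _LOWER[:3], _UPPER[:3]
    )
    dmask = rng.random(N) < config.mutation_rate
    off[:, 3] = np.where(dmask, rng.integers(1, 4, N).astype(float), off[:, 3])
    return off


def _nondominated_subset(X: np.ndarray, F: np.ndarray, chunk: int = 2048):
    """Nondominated members of an arbitrary point set, by incremental
    archive insertion (fast when the archive stays much smaller than the
    input)."""
    keep_idx = np.empty(0, dtype=int)
    arch_F = np.empty((0, F.shape[1]))
    for i in range(0, len(F), chunk):
        blk_idx = np.arange(i, min(i + chunk, len(F)))
        blk_F = F[blk_idx]
        if len(arch_F):
            blk_keep = ~_dominated_by_pool(blk_F, arch_F)
            blk_idx, blk_F = blk_idx[blk_keep], blk_F[blk_keep]
        if not len(blk_idx):
            continue
        le = np.all(blk_F[None, :, :] <= blk_F[:, None, :], axis=2)
        lt = np.any(blk_F[None, :, :] < blk_F[:, None, :], axis=2)
        inner = (le & lt).any(axis=1)
        blk_idx, blk_F = blk_idx[~inner], blk_F[~inner]
        if len(arch_F):
            arch_keep = ~_dominated_by_pool(arch_F, blk_F)
            keep_idx, arch_F = keep_idx[arch_keep], arch_F[arch_keep]
        keep_idx = np.concatenate([keep_idx, blk_idx])
        arch_F = np.vstack([arch_F, blk_F])
    return X[keep_idx], F[keep_idx]


def _dominated_by_pool(F_cand: np.ndarray, F_pool: np.ndarray, chunk: int = 20000):
    """Mask of candidates dominated by any pool member."""
    dominated = np.zeros(len(F_cand), dtype=bool)
    for i in range(0, len(F_pool), chunk):
        blk = F_pool[i:i + chunk]
        le = np.all(blk[None, :, :] <= F_cand[:, None, :], axis=2)
        lt = np.any(blk[None, :, :] < F_cand[:, None, :], axis=2)
        dominated |= (le & lt).any(axis=1)
    return dominated


def _refinement_lattice() -> np.ndarray:
    """Factorial lattice of the operating window at the natural reporting
    resolution: T every 1 degC, V every 0.25 m/s, MC every 1 %, all three
    directions."""
    T = np.arange(_LOWER[0], _UPPER[0] + 1e-9, 1.0)
    V = np.arange(_LOWER[1], _UPPER[1] + 1e-9, 0.25)
    MC = np.arange(_LOWER[2], _UPPER[2] + 1e-9, 1.0)
    D = np.array([1.0, 2.0, 3.0])
    grids = np.meshgrid(T, V, MC, D, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _local_probes(X: np.ndarray) -> np.ndarray:
    """Coordinate-wise neighbourhood of each candidate: graded steps and
    bound snaps on T/V/MC, the two alternative directions for D."""
    out = []
    for x in X:
        for j in range(3):
            span = _UPPER[j] - _LOWER[j]
            for frac in (0.25, 0.05, 0.01):
                for sgn in (1.0, -1.0):
                    y = x.copy()
                    y[j] = np.clip(y[j] + sgn * frac * span, _LOWER[j], _UPPER[j])
                    out.append(y)
            for bound in (_LOWER[j], _UPPER[j]):
                y = x.copy()
                y[j] = bound
                out.append(y)
        for d in (1.0, 2.0, 3.0):
            if d != x[3]:
                y = x.copy()
                y[3] = d
                out.append(y)
    return np.unique(np.array(out), axis=0)


def run_nsga2(model: NetworkParameters, config: MOOConfig = MOOConfig()) -> ParetoSet:
    """Optimize the five surrogate objectives over the operating window.

    The search runs the nondominated-sorting GA, pools every evaluated
    point (plus the refinement lattice when enabled), polishes the pooled
    front by Pareto local search, and returns the nondominated set capped
    at ceil(pareto_fraction x population) members selected by crowding
    distance.  Every returned condition is feasible and no point evaluated
    anywhere during the run dominates a returned member.
    """
    rng = np.random.default_rng(config.seed)
    N = config.population_size

    pop = rng.uniform(_LOWER, _UPPER, (N, 4))
    pop[:, 3] = rng.integers(1, 4, N)
    F = objective_eval_array(pop, model)
    all_X, all_F = [pop.copy()], [F.copy()]
    rank, crowd = _rank_and_crowd(F)

    for _ in range(config.generations):
        off = _make_offspring(pop, rank, crowd, config, rng)
        off_F = objective_eval_array(off, model)
        all_X.append(off)
        all_F.append(off_F)
        pop, F = _environmental_selection(
            np.vstack([pop, off]), np.vstack([F, off_F]), N
        )
        rank, crowd = _rank_and_crowd(F)

    if config.lattice_enumeration:
        lattice = _refinement_lattice()
        all_X.append(lattice)
        all_F.append(objective_eval_array(lattice, model))

    cap = math.ceil(config.pareto_fraction * N)
    pool_cap = max(6 * cap, 2 * N)

    X_all = np.vstack(all_X)
    F_all = np.vstack(all_F)
    pool_X, pool_F = _nondominated_subset(X_all, F_all)
    pool_X, pool_F = _dedupe(pool_X, pool_F)
    if len(pool_X) > pool_cap:
        keep = np.sort(np.argsort(-crowding_distance(pool_F), kind="stable")[:pool_cap])
        pool_X, pool_F = pool_X[keep], pool_F[keep]

    for _ in range(max(config.local_search_rounds, 0)):
        probes = _local_probes(pool_X)
        probe_F = objective_eval_array(probes, model)
        all_X.append(probes)
        all_F.append(probe_F)
        new_X, new_F = _nondominated_subset(
            np.vstack([pool_X, probes]), np.vstack([pool_F, probe_F])
        )
        new_X, new_F = _dedupe(new_X, new_F)
        if len(new_X) > pool_cap:
            keep = np.sort(np.argsort(-crowding_distance(new_F), kind="stable")[:pool_cap])
            new_X, new_F = new_X[keep], new_F[keep]
        converged = len(new_X) == len(pool_X) and np.array_equal(
            np.sort(new_F, axis=0), np.sort(pool_F, axis=0)
        )
        pool_X, pool_F = new_X, new_F
        if converged:
            break

    # final guard: nothing evaluated during the whole run may dominate a
    # returned member
    F_all = np.vstack(all_F)
    bad = _dominated_by_pool(pool_F, F_all)
    front_pop, front_F = pool_X[~bad], pool_F[~bad]
    if len(front_pop) > cap:
        keep = np.argsort(-crowding_distance(front_F), kind="stable")[:cap]
        keep = np.sort(keep)
        front_pop, front_F = front_pop[keep], front_F[keep]

    solutions = []
    for x, f in zip(front_pop, front_F):
        cond = ProcessCondition(float(x[0]), float(x[1]), float(x[2]), int(round(x[3])))
        y = f * _SIGNS
        resp = ResponseVector(
            DT=max(float(y[0]), np.finfo(float).tiny),
            SEC=max(float(y[1]), np.finfo(float).tiny),
            HR=float(np.clip(y[2], 0.0, 100.0)),
            WR=float(np.clip(y[3], 0.0, np.clip(y[2], 0.0, 100.0))),
            SR=float(np.clip(y[4], 0.0, 100.0)),
        )
        solutions.append(ParetoSolution(cond, resp))
    return ParetoSet(solutions)


def _dedupe(X: np.ndarray, F: np.ndarray):
    """Collapse members with identical objective vectors."""
    _, idx = np.unique(F.round(10), axis=0, return_index=True)
    idx = np.sort(idx)
    return X[idx], F[idx]


def _rank_and_crowd(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = fast_nondominated_sort(F)
    rank = np.empty(len(F), dtype=int)
    crowd = np.empty(len(F))
    for r, front in enumerate(fronts):
        rank[front] = r
        crowd[front] = crowding_distance(F[front])
    return rank, crowd


def _environmental_selection(pop, F, N):
    """Standard elitist truncation of the combined parent+offspring pool."""
    fronts = fast_nondominated_sort(F)
    chosen: list[int] = []
    for front in fronts:
        if len(chosen) + len(front) <= N:
            chosen.extend(front.tolist())
        else:
            d = crowding_distance(F[front])
            order = front[np.argsort(-d, kind="stable")]
            chosen.extend(order[: N - len(chosen)].tolist())
            break
    idx = np.array(chosen)
    return pop[idx], F[idx]


def summarize_pareto(
    pareto: ParetoSet, reference: int, candidate: int
) -> dict:
    """Percent change of each response of ``candidate`` versus
    ``reference`` (1-based group ids), plus the per-response extremes of
    the whole set.  Changes are rounded to one decimal, as in process
    comparison reports."""
    n = len(pareto)
    for gid in (reference, candidate):
        if not 1 <= gid <= n:
            raise ValidationError(f"group id {gid} not in 1..{n}")
    ref = pareto[reference - 1].predicted.as_array()
    cand = pareto[candidate - 1].predicted.as_array()
    changes = {
        c: round(percent_change(cand[k], ref[k]), 1)
        for k, c in enumerate(RESPONSE_COLUMNS)
    }
    Y = np.array([s.predicted.as_array() for s in pareto.solutions])
    extremes = {}
    for k, c in enumerate(RESPONSE_COLUMNS):
        extremes[c] = {
            "min": {"group": int(np.argmin(Y[:, k])) + 1, "value": float(Y[:, k].min())},
            "max": {"group": int(np.argmax(Y[:, k])) + 1, "value": float(Y[:, k].max())},
        }
    return {
        "reference": reference,
        "candidate": candidate,
        "percent_change": changes,
        "extremes": extremes,
    }


def validate_optimum(
    predicted: ResponseVector, experimental: ResponseVector
) -> dict[str, float]:
    """Relative prediction error (%) per response, two-decimal rounding."""
    p = predicted.as_array()
    e = experimental.as_array()
    if np.any(e == 0):
        raise ZeroDivisionError("experimental responses must be nonzero")
    return {
        c: round(relative_error_percent(p[k], e[k]), 2)
        for k, c in enumerate(RESPONSE_COLUMNS)
    }


def hypervolume(F: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume (minimization) of a point set against a reference
    corner, by recursive slicing on the first objective.  Intended for the
    small fronts this package produces."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    ref = np.asarray(ref, dtype=float)
    pts = F[np.all(F <= ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    return _hv(pts, ref)


def _nondominated_filter(F: np.ndarray) -> np.ndarray:
    dom = _domination_matrix(F)
    # for duplicate rows keep only the first occurrence
    _, first = np.unique(F, axis=0, return_index=True)
    keep = np.zeros(len(F), dtype=bool)
    keep[first] = True
    return F[(~dom.any(axis=0)) & keep]


def _hv(F: np.ndarray, ref: np.ndarray) -> float:
    F = _nondominated_filter(F)
    if F.shape[1] == 1:
        return float(ref[0] - F[:, 0].min())
    order = np.argsort(F[:, 0], kind="stable")
    F = F[order]
    total = 0.0
    for i in range(len(F)):
        upper = F[i + 1, 0] if i + 1 < len(F) else ref[0]
        width = upper - F[i, 0]
        if width > 0:
            total += width * _hv(F[: i + 1, 1:], ref[1:])
    return total
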