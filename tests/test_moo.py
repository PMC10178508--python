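"""Dominance machinery, the optimizer's front, and the report arithmetic."""

import math

import numpy as np
import pytest

from nutbreak.dataset import ProcessCondition, ValidationError
from nutbreak.fixtures import load_table5_pareto, load_table6
from nutbreak.moo import (
    MOOConfig,
    _SIGNS,
    _nondominated_subset,
    crowding_distance,
    dominates,
    fast_nondominated_sort,
    hypervolume,
    objective_eval,
    objective_eval_array,
    run_nsga2,
    summarize_pareto,
    validate_optimum,
)
from nutbreak.network import forward_array
from nutbreak.surface import SurfaceParams, true_response_array


class TestDominance:
    def test_equal_vectors_do_not_dominate(self):
        assert not dominates([1, 1, 1], [1, 1, 1])

    def test_strictly_better_everywhere_dominates(self):
        assert dominates([1, 1, 1, 1, 1], [2, 2, 2, 2, 2])
        assert not dominates([2, 2, 2, 2, 2], [1, 1, 1, 1, 1])

    def test_incomparable_pair(self):
        assert not dominates([1, 3], [2, 2])
        assert not dominates([2, 2], [1, 3])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dominates([1, 2], [1, 2, 3])


class TestNondominatedSort:
    def test_identical_objectives_single_front(self):
        fronts = fast_nondominated_sort(np.ones((6, 3)))
        assert len(fronts) == 1 and len(fronts[0]) == 6

    def test_totally_ordered_chain_gives_singletons(self):
        F = np.arange(5)[:, None] * np.ones((1, 4))
        fronts = fast_nondominated_sort(F)
        assert [len(f) for f in fronts] == [1] * 5
        assert fronts[0][0] == 0

    def test_first_front_matches_exhaustive_filter(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 13))
            m = int(rng.integers(2, 6))
            F = rng.integers(0, 5, (n, m)).astype(float)
            fronts = fast_nondominated_sort(F)
            brute = {
                i for i in range(n)
                if not any(dominates(F[k], F[i]) for k in range(n) if k != i)
            }
            assert set(fronts[0].tolist()) == brute
            # fronts partition the population
            assert sorted(np.concatenate(fronts).tolist()) == list(range(n))

    def test_later_fronts_only_dominated_by_earlier(self):
        rng = np.random.default_rng(1)
        F = rng.random((12, 3))
        fronts = fast_nondominated_sort(F)
        rank = np.empty(len(F), dtype=int)
        for r, front in enumerate(fronts):
            rank[front] = r
        for i in range(len(F)):
            for k in range(len(F)):
                if dominates(F[i], F[k]):
                    assert rank[i] < rank[k]


class TestCrowding:
    def test_two_member_front_all_infinite(self):
        d = crowding_distance(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.all(np.isinf(d))

    def test_three_collinear_points_middle_distance(self):
        d = crowding_distance(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        F = rng.random((8, 3))
        perm = rng.permutation(8)
        d = crowding_distance(F)
        dp = crowding_distance(F[perm])
        np.testing.assert_allclose(dp, d[perm])


class TestObjectiveEval:
    def test_sign_convention(self, surrogate_model):
        cond = ProcessCondition(50, 2, 15, 1)
        f = objective_eval(cond, surrogate_model)
        y = forward_array(surrogate_model, cond.as_array()[None, :])[0]
        np.testing.assert_allclose(f, y * _SIGNS)
        assert f[2] == -y[2]  # maximizing HR means minimizing -HR

    def test_matches_forward_composition_on_random_conditions(self, surrogate_model):
        rng = np.random.default_rng(3)
        X = np.column_stack([
            rng.uniform(40, 55, 20), rng.uniform(1, 4, 20),
            rng.uniform(10, 25, 20), rng.integers(1, 4, 20).astype(float),
        ])
        np.testing.assert_allclose(
            objective_eval_array(X, surrogate_model),
            forward_array(surrogate_model, X) * _SIGNS,
        )

    def test_out_of_window_condition_rejected(self, surrogate_model):
        with pytest.raises(ValidationError):
            ProcessCondition(60.0, 2, 15, 1)


class TestFront:
    def test_front_internally_nondominated(self, pareto_front):
        F = pareto_front.objectives()
        for i in range(len(F)):
            for k in range(len(F)):
                if i != k:
                    assert not dominates(F[i], F[k])

    def test_front_feasible_and_capped(self, pareto_front):
        assert len(pareto_front) <= math.ceil(0.3 * 60)
        for sol in pareto_front.solutions:
            assert 40 <= sol.condition.T <= 55
            assert 1 <= sol.condition.V <= 4
            assert 10 <= sol.condition.MC <= 25
            assert sol.condition.D in (1, 2, 3)

    def test_seeded_run_reproducible(self, surrogate_model):
        cfg = MOOConfig(
            population_size=12, generations=5, seed=9,
            lattice_enumeration=False, local_search_rounds=1,
        )
        a = run_nsga2(surrogate_model, cfg)
        b = run_nsga2(surrogate_model, cfg)
        np.testing.assert_array_equal(a.objectives(), b.objectives())

    def test_front_reaches_true_grid_optima(
        self, pareto_front, surface_params, evaluation_grid
    ):
        """Closure: each objective's best front member comes within 5 % of
        the true-surface optimum over a dense grid."""
        X = np.array([s.condition.as_array() for s in pareto_front.solutions])
        front_true = true_response_array(X, surface_params) * _SIGNS
        grid_true = true_response_array(evaluation_grid, surface_params) * _SIGNS
        for k in range(5):
            opt = grid_true[:, k].min()
            best = front_true[:, k].min()
            assert abs(best - opt) <= 0.05 * abs(opt)


class TestHypervolume:
    def test_rectangle_cases(self):
        assert hypervolume(np.array([[0.0, 0.0]]), np.array([1.0, 1.0])) == 1.0
        assert hypervolume(
            np.array([[1.0, 2.0], [2.0, 1.0]]), np.array([3.0, 3.0])
        ) == pytest.approx(3.0)

    def test_dominated_points_do_not_change_volume(self):
        front = np.array([[1.0, 2.0], [2.0, 1.0]])
        padded = np.vstack([front, [[2.5, 2.5]]])
        ref = np.array([3.0, 3.0])
        assert hypervolume(padded, ref) == pytest.approx(hypervolume(front, ref))

    def test_monte_carlo_agreement_in_three_dimensions(self):
        rng = np.random.default_rng(4)
        F = rng.random((8, 3))
        ref = np.ones(3)
        exact = hypervolume(F, ref)
        samples = rng.random((200_000, 3))
        covered = np.zeros(len(samples), dtype=bool)
        for p in F:
            covered |= np.all(samples >= p, axis=1)
        assert exact == pytest.approx(covered.mean(), abs=5e-3)

    def test_optimizer_front_beats_random_search(self, surrogate_model, surface_params):
        """Image of the surrogate front under the true surface dominates
        more volume than an equal-budget random-search front in at least
        9 of 10 seeded trials (nadir: worst corner of the swept box)."""
        T = np.linspace(40, 55, 16)
        V = np.linspace(1, 4, 13)
        MC = np.linspace(10, 25, 16)
        box = np.array(
            [(t, v, m, d) for t in T for v in V for m in MC for d in (1, 2, 3)]
        )
        ref = (true_response_array(box, surface_params) * _SIGNS).max(axis=0)
        ref = ref * 1.001 + 1e-6
        wins = 0
        for t in range(10):
            # front fraction 0.75 keeps the cap above twice the objective
            # count, so crowding truncation cannot drop per-objective
            # extreme points from either method's front
            cfg = MOOConfig(
                population_size=24, generations=40, seed=300 + t,
                pareto_fraction=0.75, local_search_rounds=6,
            )
            front = run_nsga2(surrogate_model, cfg)
            Xf = np.array([s.condition.as_array() for s in front.solutions])
            hv_opt = hypervolume(
                true_response_array(Xf, surface_params) * _SIGNS, ref
            )
            rng = np.random.default_rng(400 + t)
            R = np.column_stack([
                rng.uniform(40, 55, 30_000), rng.uniform(1, 4, 30_000),
                rng.uniform(10, 25, 30_000), rng.integers(1, 4, 30_000).astype(float),
            ])
            Rx, Rf = _nondominated_subset(R, objective_eval_array(R, surrogate_model))
            cap = math.ceil(0.75 * 24)
            if len(Rx) > cap:
                keep = np.sort(
                    np.argsort(-crowding_distance(Rf), kind="stable")[:cap]
                )
                Rx = Rx[keep]
            hv_rand = hypervolume(
                true_response_array(Rx, surface_params) * _SIGNS, ref
            )
            wins += hv_opt >= hv_rand
        assert wins >= 9


class TestReports:
    def test_published_group_comparisons(self):
        pareto = load_table5_pareto()
        seven = summarize_pareto(pareto, reference=1, candidate=7)
        assert seven["percent_change"] == {
            "DT": -39.0, "SEC": -23.3, "HR": -8.2, "WR": -14.1, "SR": 7.5,
        }
        thirty = summarize_pareto(pareto, reference=1, candidate=30)
        assert thirty["percent_change"]["SEC"] == -95.2
        assert thirty["percent_change"]["DT"] == -90.9

    def test_self_comparison_is_all_zero(self):
        pareto = load_table5_pareto()
        same = summarize_pareto(pareto, reference=4, candidate=4)
        assert all(v == 0.0 for v in same["percent_change"].values())

    def test_unknown_group_rejected(self):
        with pytest.raises(ValidationError):
            summarize_pareto(load_table5_pareto(), reference=1, candidate=99)

    def test_extremes_identify_published_optima(self):
        report = summarize_pareto(load_table5_pareto(), 1, 7)
        assert report["extremes"]["DT"]["min"]["group"] == 30
        assert report["extremes"]["SR"]["max"]["group"] == 7
        assert report["extremes"]["HR"]["max"]["group"] == 1

    def test_validation_errors_of_published_optimum(self):
        _, predicted, experimental = load_table6()
        errors = validate_optimum(predicted, experimental)
        assert errors == {
            "DT": 3.56, "SEC": 3.88, "HR": 2.51, "WR": 3.32, "SR": 3.96,
        }

    def test_identical_vectors_zero_error(self):
        _, predicted, _ = load_table6()
        errors = validate_optimum(predicted, predicted)
        assert all(v == 0.0 for v in errors.values())

    def test_error_scale_invariance(self):
        from nutbreak.dataset import ResponseVector

        _, predicted, experimental = load_table6()
        scale = 0.5
        p = ResponseVector(*(predicted.as_array() * scale))
        e = ResponseVector(*(experimental.as_array() * scale))
        assert validate_optimum(p, e) == validate_optimum(predicted, experimental)
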