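"""Network core: transfers, normalization, forward pass, training, search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutbreak.dataset import (
    FactorialDataset,
    ProcessCondition,
    SplitSpec,
    ValidationError,
)
from nutbreak.metrics import r_squared
from nutbreak.network import (
    NetworkParameters,
    NetworkTopology,
    NormalizationBounds,
    TrainingConfig,
    evaluate,
    forward,
    forward_array,
    hidden_neuron_candidates,
    logsig,
    random_parameters,
    tansig,
    topology_search,
    train,
    train_arrays,
)
from nutbreak.surface import NoiseSpec, SurfaceParams, generate_dataset


def _bounds():
    return NormalizationBounds(
        x_min=np.array([40.0, 1.0, 10.0, 1.0]),
        x_max=np.array([55.0, 4.0, 25.0, 3.0]),
        y_min=np.array([80.0, 1.0, 45.0, 20.0, 60.0]),
        y_max=np.array([1200.0, 17.0, 90.0, 52.0, 100.0]),
    )


class TestCandidates:
    def test_paper_network_range(self):
        assert list(hidden_neuron_candidates(4, 5)) == list(range(2, 14))

    def test_twice_inputs_plus_one_included(self):
        assert 9 in hidden_neuron_candidates(4, 5)

    def test_small_network_governed_by_root_bound(self):
        assert list(hidden_neuron_candidates(2, 1)) == list(range(2, 12))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValidationError):
            hidden_neuron_candidates(0, 5)


class TestTransfers:
    def test_logsig_fixed_points(self):
        assert logsig(0.0) == pytest.approx(0.5)
        assert logsig(50.0) == pytest.approx(1.0)
        assert logsig(-50.0) == pytest.approx(0.0, abs=1e-12)

    @given(x=st.floats(-20, 20))
    def test_logsig_symmetry(self, x):
        assert logsig(x) + logsig(-x) == pytest.approx(1.0)

    @given(x=st.floats(-20, 20))
    def test_tansig_is_odd_and_matches_logsig_identity(self, x):
        assert tansig(-x) == pytest.approx(-tansig(x), abs=1e-12)
        assert tansig(x) == pytest.approx(2.0 * logsig(2.0 * x) - 1.0, abs=1e-12)


class TestNormalization:
    def test_bounds_map_extremes_and_midpoint(self):
        b = _bounds()
        lo = b.normalize_x(b.x_min[None, :])
        hi = b.normalize_x(b.x_max[None, :])
        mid = b.normalize_x(((b.x_min + b.x_max) / 2)[None, :])
        np.testing.assert_allclose(lo, -1.0)
        np.testing.assert_allclose(hi, 1.0)
        np.testing.assert_allclose(mid, 0.0, atol=1e-12)

    @given(
        y=st.tuples(
            st.floats(80, 1200), st.floats(1, 17), st.floats(45, 90),
            st.floats(20, 52), st.floats(60, 100),
        )
    )
    def test_denormalize_inverts_normalize(self, y):
        b = _bounds()
        arr = np.array(y)[None, :]
        np.testing.assert_allclose(
            b.denormalize_y(b.normalize_y(arr)), arr, rtol=1e-12, atol=1e-9
        )

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValidationError):
            NormalizationBounds(
                x_min=np.zeros(4), x_max=np.zeros(4),
                y_min=np.zeros(5), y_max=np.ones(5),
            )


class TestForward:
    def test_zero_network_predicts_training_midpoints(self):
        topo = NetworkTopology(3, "logsig")
        b = _bounds()
        params = NetworkParameters(
            w_ih=np.zeros((3, 4)), b_h=np.zeros(3),
            w_ho=np.zeros((5, 3)), b_o=np.zeros(5),
            bounds=b, topology=topo,
        )
        y = forward_array(params, np.array([[50.0, 2.0, 15.0, 1.0]]))[0]
        np.testing.assert_allclose(y, (b.y_min + b.y_max) / 2)

    def test_hand_computed_chain(self):
        """Two hidden neurons with hand-set weights, checked by pencil math."""
        topo = NetworkTopology(2, "logsig")
        b = _bounds()
        params = NetworkParameters(
            w_ih=np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]]),
            b_h=np.array([0.0, 0.5]),
            w_ho=np.vstack([np.array([1.0, -1.0])] + [np.zeros(2)] * 4),
            b_o=np.zeros(5),
            bounds=b, topology=topo,
        )
        x = np.array([47.5, 2.5, 17.5, 2.0])  # all factors at their midpoint
        h = np.array([logsig(0.0), logsig(0.5)])
        yg = h[0] - h[1]
        expected_dt = (1200.0 - 80.0) * (yg + 1.0) / 2 + 80.0
        got = forward_array(params, x[None, :])[0]
        assert got[0] == pytest.approx(expected_dt, rel=1e-12)
        np.testing.assert_allclose(got[1:], (b.y_min + b.y_max)[1:] / 2)

    @pytest.mark.parametrize("transfer", ["logsig", "tansig"])
    def test_matches_per_neuron_loop_oracle(self, transfer):
        rng = np.random.default_rng(8)
        b = _bounds()
        for _ in range(20):
            j = int(rng.integers(2, 14))
            topo = NetworkTopology(j, transfer)
            params = random_parameters(topo, b, rng)
            x = np.array([
                rng.uniform(40, 55), rng.uniform(1, 4),
                rng.uniform(10, 25), rng.integers(1, 4),
            ], dtype=float)
            xg = 2 * (x - b.x_min) / (b.x_max - b.x_min) - 1
            f = logsig if transfer == "logsig" else tansig
            hidden = [
                f(sum(params.w_ih[q, i] * xg[i] for i in range(4)) + params.b_h[q])
                for q in range(j)
            ]
            out = []
            for k in range(5):
                s = sum(params.w_ho[k, q] * hidden[q] for q in range(j))
                yg = s + params.b_o[k]
                out.append((b.y_max[k] - b.y_min[k]) * (yg + 1) / 2 + b.y_min[k])
            got = forward_array(params, x[None, :])[0]
            np.testing.assert_allclose(got, out, rtol=0, atol=1e-12)

    def test_condition_interface_returns_valid_responses(self):
        rng = np.random.default_rng(3)
        params = random_parameters(NetworkTopology(4), _bounds(), rng)
        resp = forward(params, ProcessCondition(50, 2, 15, 1))
        assert 0 <= resp.WR <= resp.HR <= 100 and resp.DT > 0

    def test_shape_mismatch_rejected(self):
        params = random_parameters(
            NetworkTopology(3), _bounds(), np.random.default_rng(0)
        )
        with pytest.raises(ValidationError):
            forward_array(params, np.ones((2, 3)))


def _noiseless_dataset():
    return generate_dataset(SurfaceParams(), NoiseSpec(sigma=(0,) * 5, seed=0))


class TestTraining:
    def test_zero_epochs_returns_init(self):
        ds = _noiseless_dataset()
        b = NormalizationBounds.from_training(ds.inputs(), ds.responses())
        topo = NetworkTopology(3)
        init = random_parameters(topo, b, np.random.default_rng(1))
        out, history = train(ds, topo, init, TrainingConfig(max_epochs=0))
        assert history.size == 0
        np.testing.assert_array_equal(out.w_ih, init.w_ih)
        np.testing.assert_array_equal(out.b_o, init.b_o)

    def test_identical_seeds_bitwise_identical(self):
        ds = _noiseless_dataset()
        b = NormalizationBounds.from_training(ds.inputs(), ds.responses())
        topo = NetworkTopology(4)
        runs = []
        for _ in range(2):
            init = random_parameters(topo, b, np.random.default_rng(2))
            runs.append(train(ds, topo, init, TrainingConfig(max_epochs=200)))
        np.testing.assert_array_equal(runs[0][0].w_ih, runs[1][0].w_ih)
        np.testing.assert_array_equal(runs[0][1], runs[1][1])

    def test_history_monotone_and_below_initial(self):
        ds = _noiseless_dataset()
        b = NormalizationBounds.from_training(ds.inputs(), ds.responses())
        topo = NetworkTopology(6)
        init = random_parameters(topo, b, np.random.default_rng(3))
        _, history = train(ds, topo, init, TrainingConfig(max_epochs=500))
        assert np.all(np.diff(history) <= 0)

    def test_representable_target_recovered(self):
        """A rank-two linear map fits within a two-neuron hidden layer."""
        rng = np.random.default_rng(0)
        X = _noiseless_dataset().inputs()
        u, v = rng.normal(size=4), rng.normal(size=4)
        C, c0 = rng.normal(size=(5, 2)), rng.normal(size=5)
        Y = np.column_stack([X @ u, X @ v]) @ C.T + c0
        topo = NetworkTopology(2, "logsig")
        b = NormalizationBounds.from_training(X, Y)
        init = random_parameters(topo, b, np.random.default_rng(1))
        params, _ = train_arrays(X, Y, init, TrainingConfig(max_epochs=8000))
        P = forward_array(params, X)
        for k in range(5):
            assert r_squared(Y[:, k], P[:, k]) > 0.999


class TestEvaluate:
    def test_exact_predictor_scores_perfectly(self):
        ds = _noiseless_dataset()
        b = NormalizationBounds.from_training(ds.inputs(), ds.responses())
        topo = NetworkTopology(5)
        init = random_parameters(topo, b, np.random.default_rng(4))
        predictions = forward_array(init, ds.inputs())
        fake = FactorialDataset(ds.frame.copy())
        fake.frame.loc[:, ["DT", "SEC", "HR", "WR", "SR"]] = predictions
        scores = evaluate(init, fake)
        for c in ("DT", "SEC", "HR", "WR", "SR"):
            assert scores.r2[c] == pytest.approx(1.0)
            assert scores.rmse[c] == pytest.approx(0.0, abs=1e-9)

    def test_agrees_with_metrics_module(self, gaann_report, synthetic_dataset):
        from nutbreak.dataset import split_dataset
        from nutbreak.metrics import rmse

        _, test_set = split_dataset(synthetic_dataset, SplitSpec(seed=0))
        scores = evaluate(gaann_report.ga_params, test_set)
        P = forward_array(gaann_report.ga_params, test_set.inputs())
        Y = test_set.responses()
        for k, c in enumerate(("DT", "SEC", "HR", "WR", "SR")):
            assert scores.rmse[c] == pytest.approx(rmse(Y[:, k], P[:, k]))
            assert scores.r2[c] == pytest.approx(r_squared(Y[:, k], P[:, k]))


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        params = random_parameters(
            NetworkTopology(7, "tansig"), _bounds(), np.random.default_rng(5)
        )
        path = params.to_json(tmp_path / "model.json", provenance={"seed": 1})
        back = NetworkParameters.from_json(path)
        np.testing.assert_array_equal(back.w_ih, params.w_ih)
        np.testing.assert_array_equal(back.w_ho, params.w_ho)
        assert back.topology == params.topology


class TestTopologySearch:
    def test_single_candidate_selected(self, synthetic_dataset):
        result = topology_search(
            synthetic_dataset, candidates=[3], replicates=1,
            transfers=("logsig",), seed=0,
            config=TrainingConfig(max_epochs=5),
        )
        assert result.selected == ("logsig", 3)
        assert len(result.table) == 1

    def test_full_candidate_grid_has_24_rows(self, synthetic_dataset):
        result = topology_search(
            synthetic_dataset, replicates=1, seed=0,
            config=TrainingConfig(max_epochs=2),
        )
        assert len(result.table) == 24
        assert set(result.table["hidden_transfer"]) == {"logsig", "tansig"}

    def test_larger_logsig_beats_smallest_tansig(self, synthetic_dataset):
        result = topology_search(
            synthetic_dataset, candidates=[2, 10], replicates=2, seed=1,
            config=TrainingConfig(max_epochs=800),
        )
        t = result.table.set_index(["hidden_transfer", "n_hidden"])
        r2_cols = [c for c in t.columns if c.endswith("_R2")]
        assert (
            t.loc[("logsig", 10), r2_cols].mean()
            > t.loc[("tansig", 2), r2_cols].mean()
        )
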