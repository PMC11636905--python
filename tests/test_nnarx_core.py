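import dataclasses

import numpy as np
import pytest

import glynarx as g
from glynarx.nnarx_core import ModelLoadError, horizon_steps
from _oracles import forward_oracle, random_model, recursion_oracle


def constant_network(bias_scaled, lo=0.0, hi=10.0):
    """All-zero weights with an output bias: predicts a constant."""
    cfg = g.ModelConfig(n_taps=4, hidden_sizes=(3, 2))
    sizes = cfg.layer_sizes
    weights = tuple(np.zeros((sizes[i + 1], sizes[i])) for i in range(3))
    biases = [np.zeros(sizes[i + 1]) for i in range(3)]
    biases[-1][0] = bias_scaled
    return g.NNARXModel(
        config=cfg, weights=weights, biases=tuple(biases), scaler=g.Scaler(lo=lo, hi=hi)
    )


class TestInitNetwork:
    def test_seeded_determinism(self):
        a = g.init_network(g.ModelConfig(seed=7))
        b = g.init_network(g.ModelConfig(seed=7))
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_layer_shapes(self):
        m = g.init_network(g.ModelConfig(n_taps=20, hidden_sizes=(20, 13)))
        assert [w.shape for w in m.weights] == [(20, 20), (13, 20), (1, 13)]
        assert [b.shape for b in m.biases] == [(20,), (13,), (1,)]

    def test_degenerate_hidden_size_rejected(self):
        with pytest.raises(ValueError):
            g.ModelConfig(hidden_sizes=(0, 13))


class TestForwardOneStep:
    def test_zero_network_outputs_scale_midpoint(self):
        m = constant_network(0.0, lo=0.0, hi=10.0)
        assert g.forward_one_step(m, np.array([1.0, 2.0, 3.0, 4.0])) == 5.0

    def test_constant_network_ignores_taps(self, rng):
        m = constant_network(0.3, lo=0.0, hi=10.0)
        expected = g.invert_scaler(m.scaler, 0.3)
        for _ in range(5):
            taps = rng.uniform(1, 9, 4)
            assert g.forward_one_step(m, taps) == pytest.approx(expected, abs=1e-12)

    def test_wrong_tap_count_rejected(self):
        m = constant_network(0.0)
        with pytest.raises(ValueError):
            g.forward_one_step(m, np.zeros(5))

    def test_matches_matrix_arithmetic_oracle(self, rng):
        for seed in range(20):
            m = random_model(seed)
            taps = rng.uniform(3.5, 15.5, m.config.n_taps)
            assert g.forward_one_step(m, taps) == pytest.approx(
                forward_oracle(m, taps), abs=1e-10
            )


class TestTrainOpenLoop:
    def test_constant_series_learned(self):
        seg = g.GlucoseSeries(np.arange(120) * 5.0, np.full(120, 6.0))
        windows = g.make_windows(seg)
        model = dataclasses.replace(
            g.init_network(g.ModelConfig(seed=0)), scaler=g.Scaler(lo=3.0, hi=9.0)
        )
        trained, _ = g.train_open_loop(model, windows, g.TrainConfig(seed=0))
        pred = g.forward_one_step(trained, np.full(20, 6.0))
        assert pred == pytest.approx(6.0, abs=1e-3)

    def test_sinusoid_one_step_capacity(self, trained_sinusoid):
        trained, report, series = trained_sinusoid
        v = series.values
        preds = np.array(
            [g.forward_one_step(trained, v[i : i + 20]) for i in range(0, 400, 4)]
        )
        truth = v[np.arange(0, 400, 4) + 20]
        assert np.sqrt(np.mean((preds - truth) ** 2)) < 0.05

    def test_seeded_training_is_reproducible(self, sinusoid_series):
        windows = g.make_windows(sinusoid_series)[:100]
        model = g.init_network(g.ModelConfig(seed=3))
        tc = g.TrainConfig(seed=3, max_epochs=40)
        t1, r1 = g.train_open_loop(model, windows, tc)
        t2, r2 = g.train_open_loop(model, windows, tc)
        assert r1 == r2
        for wa, wb in zip(t1.weights, t2.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_no_windows_rejected(self):
        model = g.init_network(g.ModelConfig())
        with pytest.raises(ValueError):
            g.train_open_loop(model, [], g.TrainConfig())

    def test_input_model_untouched(self, sinusoid_series):
        windows = g.make_windows(sinusoid_series)[:60]
        model = g.init_network(g.ModelConfig(seed=5))
        before = [w.copy() for w in model.weights]
        g.train_open_loop(model, windows, g.TrainConfig(seed=5, max_epochs=20))
        for wa, wb in zip(model.weights, before):
            np.testing.assert_array_equal(wa, wb)


class TestCloseLoop:
    def test_parameters_unchanged(self):
        m = random_model(0)
        c = g.close_loop(m)
        assert c.mode == "closed_loop"
        for wa, wb in zip(m.weights, c.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_forward_identical_before_and_after(self, rng):
        m = random_model(1)
        taps = rng.uniform(4, 14, m.config.n_taps)
        assert g.forward_one_step(m, taps) == g.forward_one_step(g.close_loop(m), taps)

    def test_closing_twice_rejected(self):
        c = g.close_loop(random_model(2))
        with pytest.raises(ValueError):
            g.close_loop(c)


class TestPredictRecursive:
    def test_single_step_equals_forward(self, rng):
        m = random_model(3)
        taps = rng.uniform(4, 14, m.config.n_taps)
        c = g.close_loop(m)
        assert g.predict_recursive(c, taps, 1)[0] == g.forward_one_step(m, taps)

    def test_constant_network_repeats_itself(self):
        c = g.close_loop(constant_network(0.2, lo=2.0, hi=12.0))
        preds = g.predict_recursive(c, np.array([5.0, 6.0, 7.0, 8.0]), 4)
        assert np.all(preds == preds[0])

    def test_open_loop_model_rejected(self):
        m = random_model(4)
        with pytest.raises(ValueError):
            g.predict_recursive(m, np.zeros(m.config.n_taps) + 7, 3)

    def test_horizon_capped_at_tap_count(self):
        c = g.close_loop(random_model(5))
        with pytest.raises(ValueError):
            g.predict_recursive(c, np.full(c.config.n_taps, 7.0), c.config.n_taps + 1)

    def test_matches_recursion_oracle(self, rng):
        for seed in range(10):
            m = g.close_loop(random_model(seed))
            taps = rng.uniform(3.5, 15.5, m.config.n_taps)
            got = g.predict_recursive(m, taps, m.config.n_taps)
            want = recursion_oracle(m, taps, m.config.n_taps)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_predictions_bounded_by_output_layer(self, rng):
        for seed in range(20):
            m = g.close_loop(random_model(seed))
            bound_scaled = np.abs(m.weights[-1]).sum() + abs(m.biases[-1][0])
            lo = g.invert_scaler(m.scaler, -bound_scaled)
            hi = g.invert_scaler(m.scaler, bound_scaled)
            taps = rng.uniform(3.5, 15.5, m.config.n_taps)
            preds = g.predict_recursive(m, taps, m.config.n_taps)
            assert np.all(preds >= lo - 1e-12) and np.all(preds <= hi + 1e-12)

    def test_recovers_heldout_sinusoid_continuation(self, trained_sinusoid):
        trained, _, series = trained_sinusoid
        v = series.values
        c = g.close_loop(trained)
        preds = g.predict_recursive(c, v[-40:-20], 20)
        assert np.sqrt(np.mean((preds - v[-20:]) ** 2)) < 0.3


class TestSaveLoad:
    def test_round_trip_is_bit_exact(self, tmp_path, trained_sinusoid):
        trained, _, series = trained_sinusoid
        path = tmp_path / "m.json"
        g.save_model(trained, path)
        back = g.load_model(path)
        for wa, wb in zip(trained.weights, back.weights):
            np.testing.assert_array_equal(wa, wb)
        taps = series.values[:20]
        a = g.predict_recursive(g.close_loop(trained), taps, 20)
        b = g.predict_recursive(g.close_loop(back), taps, 20)
        np.testing.assert_array_equal(a, b)

    def test_missing_scaler_field_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        g.save_model(random_model(0), path)
        import json

        doc = json.loads(path.read_text())
        del doc["scaler"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelLoadError, match="scaler"):
            g.load_model(path)

    def test_unknown_schema_version_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        g.save_model(random_model(0), path)
        import json

        doc = json.loads(path.read_text())
        doc["schema"] = "glynarx-nnarx-0"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelLoadError, match="schema"):
            g.load_model(path)


class TestHorizonSteps:
    def test_standard_horizons(self):
        assert horizon_steps(100, 5) == 20
        assert horizon_steps(5, 5) == 1

    def test_non_multiple_rejected(self):
        with pytest.raises(ValueError):
            horizon_steps(13, 5)
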