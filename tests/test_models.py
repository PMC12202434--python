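"""Forecaster architectures, training protocol and early stopping."""

import numpy as np
import pytest

from glucodiy import nn
from glucodiy.models import (
    ModelSpec,
    NaiveModel,
    TrainingConfig,
    build_model,
    early_stop_trace,
    naive_forecast,
    predict_window,
    save_model,
    load_model,
    train,
)
from glucodiy.preprocessing import PreprocessConfig, preprocess_series
from tests.conftest import make_periodic_series


def small_instances(n_days=6, window=24, h=2, step=2):
    cfg = PreprocessConfig(window_length=window, prediction_steps=h, step=step)
    return preprocess_series(make_periodic_series(n_days), cfg)


class TestNaive:
    def test_hold_repeats_last_value(self):
        np.testing.assert_array_equal(naive_forecast([110, 118, 120], 2, "hold"), [120, 120])

    def test_literal_outputs_final_h(self):
        np.testing.assert_array_equal(naive_forecast([110, 118, 120], 2, "literal"), [118, 120])

    def test_modes_agree_on_constant_window(self):
        w = [115.0] * 5
        np.testing.assert_array_equal(naive_forecast(w, 3, "hold"),
                                      naive_forecast(w, 3, "literal"))

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            naive_forecast([1.0, 2.0], 2, "nope")


class TestBuildModel:
    def test_lstm_parameter_count_closed_form(self):
        spec = ModelSpec("lstm", window_length=96, prediction_steps=2)
        m = build_model(spec, seed=0)
        U, D, h = 96, 2, 2
        expected = 4 * ((D + U) * U + U) + U * h + h
        assert nn.n_parameters(m.params()) == expected

    def test_stacked_lstm_has_a_few_times_more_parameters(self):
        lstm = build_model(ModelSpec("lstm", prediction_steps=2), seed=0)
        stacked = build_model(ModelSpec("stacked_lstm", prediction_steps=2), seed=0)
        ratio = nn.n_parameters(stacked.params()) / nn.n_parameters(lstm.params())
        assert 1.8 <= ratio <= 3.5

    def test_dil_unet_is_the_largest(self):
        unet = build_model(ModelSpec("dil_unet", prediction_steps=2), seed=0)
        stacked = build_model(ModelSpec("stacked_lstm", prediction_steps=2), seed=0)
        assert nn.n_parameters(unet.params()) > nn.n_parameters(stacked.params())

    def test_same_seed_identical_initial_weights(self):
        a = build_model(ModelSpec("stacked_lstm", prediction_steps=2), seed=9)
        b = build_model(ModelSpec("stacked_lstm", prediction_steps=2), seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_dil_unet_window_must_divide_by_16(self):
        with pytest.raises(ValueError):
            ModelSpec("dil_unet", window_length=90, prediction_steps=2)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("transformer")


class TestEarlyStopping:
    def test_patience_2_min_delta_trace(self):
        # improvements of exactly min_delta do not count as improvements
        assert early_stop_trace([10, 9, 8.9999, 8.9998]) == (4, "early_stop")

    def test_monotone_improvement_runs_out_the_trace(self):
        losses = list(np.linspace(10, 1, 20))
        assert early_stop_trace(losses) == (20, "max_epochs")

    def test_flat_trace_stops_at_patience(self):
        assert early_stop_trace([5.0, 5.0, 5.0, 5.0], patience=2) == (3, "early_stop")

    def test_recovery_resets_patience(self):
        assert early_stop_trace([10, 10, 8, 8, 8], patience=2) == (5, "early_stop")


class TestTrain:
    CFG = TrainingConfig(batch_size=32, max_epochs=2, loss="mse", seed=0)

    def test_empty_training_set_raises(self):
        inst = small_instances().subset(np.array([], dtype=int))
        m = build_model(ModelSpec("lstm", window_length=24, prediction_steps=2), seed=0)
        with pytest.raises(ValueError):
            train(m, inst, config=self.CFG)

    def test_loss_decreases_on_learnable_data(self):
        inst = small_instances()
        m = build_model(ModelSpec("lstm", window_length=24, prediction_steps=2), seed=0)
        tm = train(m, inst, config=TrainingConfig(batch_size=32, max_epochs=4, loss="mse", seed=0))
        assert tm.history.losses[-1] < tm.history.losses[0]
        assert len(tm.history.losses) == tm.history.stopped_epoch
        assert tm.history.stopped_epoch <= 4

    def test_equal_weights_reproduce_unweighted_training(self):
        inst = small_instances()
        spec = ModelSpec("lstm", window_length=24, prediction_steps=2)
        t1 = train(build_model(spec, seed=3), inst, weights=None, config=self.CFG)
        t2 = train(build_model(spec, seed=3), inst,
                   weights=np.ones(len(inst)), config=self.CFG)
        np.testing.assert_allclose(t1.history.losses, t2.history.losses, rtol=1e-12)

    def test_iso_loss_training_runs_and_decreases(self):
        inst = small_instances()
        m = build_model(ModelSpec("lstm", window_length=24, prediction_steps=2), seed=0)
        tm = train(m, inst, config=TrainingConfig(batch_size=32, max_epochs=3, loss="iso", seed=0))
        assert np.isfinite(tm.history.losses).all()
        assert tm.history.losses[-1] < tm.history.losses[0]

    def test_weighting_changes_the_optimization(self):
        inst = small_instances()
        spec = ModelSpec("lstm", window_length=24, prediction_steps=2)
        t1 = train(build_model(spec, seed=3), inst, config=self.CFG)
        w = np.ones(len(inst))
        w[::2] = 5.0
        t2 = train(build_model(spec, seed=3), inst, weights=w, config=self.CFG)
        assert t1.history.losses != t2.history.losses


class TestPredictWindow:
    def _trained(self):
        inst = small_instances()
        m = build_model(ModelSpec("lstm", window_length=24, prediction_steps=2), seed=0)
        return train(m, inst, config=TestTrain.CFG), inst

    def test_prediction_is_finite_and_plausible(self):
        tm, inst = self._trained()
        out = predict_window(tm, inst.X[0])
        assert out.shape == (2,) and np.all(np.isfinite(out))
        assert 0 < out[0] < 500

    def test_inference_is_deterministic(self):
        tm, inst = self._trained()
        np.testing.assert_array_equal(predict_window(tm, inst.X[0]),
                                      predict_window(tm, inst.X[0]))

    def test_shape_mismatch_and_nan_rejected(self):
        tm, inst = self._trained()
        with pytest.raises(ValueError):
            predict_window(tm, inst.X[0][:10])
        bad = inst.X[0].copy()
        bad[5, 0] = np.nan
        with pytest.raises(ValueError):
            predict_window(tm, bad)

    def test_naive_model_matches_naive_forecast(self):
        inst = small_instances()
        spec = ModelSpec("naive", window_length=24, prediction_steps=2)
        tm = train(NaiveModel(spec), inst, config=TestTrain.CFG)
        out = predict_window(tm, inst.X[0])
        from glucodiy.preprocessing import denormalize

        last = denormalize(inst.X[0, -1, 0], inst.norm)
        np.testing.assert_allclose(out, [last, last])

    def test_save_load_round_trip(self, tmp_path):
        tm, inst = self._trained()
        save_model(tm, tmp_path / "m")
        tm2 = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict_window(tm, inst.X[0]),
                                      predict_window(tm2, inst.X[0]))
        assert tm2.spec == tm.spec
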