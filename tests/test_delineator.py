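"""Delineator architecture, training behavior, prediction, fiducials."""

import numpy as np
import pytest

import ecgdelin as ed
from ecgdelin.delineator import (
    DelineatorModel,
    TrainConfig,
    build_model,
    fiducials_from_mask,
    predict,
    train,
)
from ecgdelin.errors import ValidationError
from ecgdelin.nn import BiLSTM


class TestArchitecture:
    def test_small_model_preserves_length_any_input(self):
        model = build_model([4, 8], 6, seed=0)
        for L in (50, 370, 123):
            outs = model.forward_hidden(np.zeros((1, L)))
            assert [o.shape[1] for o in outs] == [L] * len(outs)
        assert outs[-1].shape[2] == 5

    def test_recurrent_only_baseline(self):
        model = build_model([], 8, seed=0)
        assert isinstance(model.layers[0], BiLSTM)

    def test_unidirectional_variant_width(self):
        model = build_model([4], 8, bidirectional=False, seed=0)
        out = model.forward_hidden(np.zeros((1, 30)))[-2]
        assert out.shape[2] == 8  # one direction only

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            build_model([0, 8], 4)
        with pytest.raises(ValidationError):
            build_model([8], 0)
        with pytest.raises(ValidationError):
            build_model([8], 4, n_classes=1)


class TestTraining:
    def small_windows(self, n=4):
        return ed.generate_training_windows(n, seed=21)

    def test_history_length_equals_epochs(self):
        model = build_model([2], 3, seed=1)
        _, hist = train(model, self.small_windows(), TrainConfig(
            learning_rate=1e-3, epochs=1, validation_fraction=0.0, seed=1))
        assert len(hist["loss"]) == 1
        assert len(hist["accuracy"]) == 1

    def test_same_seed_reproduces_loss(self):
        losses = []
        for _ in range(2):
            model = build_model([2], 3, seed=1)
            _, hist = train(model, self.small_windows(), TrainConfig(
                learning_rate=1e-3, epochs=3, validation_fraction=0.0, seed=9))
            losses.append(hist["loss"][-1])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_too_few_windows_rejected(self):
        model = build_model([2], 3, seed=1)
        with pytest.raises(ValidationError):
            train(model, self.small_windows(1), TrainConfig(epochs=1))


class TestOverfit:
    """Memorization-capacity checks on a handful of windows."""

    @pytest.fixture(scope="class")
    def overfit(self):
        windows = ed.generate_training_windows(8, seed=42, af_fraction=0.0)
        model = build_model([8, 16], 24, seed=7)
        config = TrainConfig(learning_rate=1e-3, epochs=200, batch_size=2,
                             seed=7, validation_fraction=0.0)
        model, history = train(model, windows, config)
        return model, history, windows

    def test_final_training_accuracy(self, overfit):
        _, history, _ = overfit
        assert history["accuracy"][-1] >= 0.99

    def test_predicted_p_duration_matches_template(self, overfit):
        model, _, windows = overfit
        template_p = round(ed.BeatTemplate().p_duration * 250)
        checked = 0
        for w in windows:
            _, mask = predict(model, w)
            p_fids = [f for f in fiducials_from_mask(mask, w.samples, 250.0)
                      if f.wave == "P"]
            if not p_fids:
                continue
            longest = max(p_fids, key=lambda f: f.duration_s)
            assert abs((longest.offset - longest.onset) - template_p) <= 2
            checked += 1
        assert checked >= 6

    def test_single_window_memorized_exactly(self):
        windows = ed.generate_training_windows(1, seed=42, af_fraction=0.0) * 2
        model = build_model([8, 16], 24, seed=7)
        config = TrainConfig(learning_rate=3e-3, epochs=400, batch_size=2,
                             seed=7, validation_fraction=0.0)
        model, _ = train(model, windows, config)
        _, mask = predict(model, windows[0])
        assert np.array_equal(mask.classes, windows[0].mask.classes)


class TestPredict:
    def test_rows_sum_to_one(self):
        model = build_model([2], 3, seed=2)
        w = ed.generate_training_windows(1, seed=3)[0]
        probs, mask = predict(model, w, allow_untrained=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert len(mask) == 370

    def test_untrained_requires_flag(self):
        model = build_model([2], 3, seed=2)
        w = ed.generate_training_windows(1, seed=3)[0]
        with pytest.raises(ValidationError):
            predict(model, w)

    def test_argmax_tie_breaks_to_lowest_class(self):
        row = np.array([0.2, 0.2, 0.2, 0.2, 0.2])
        assert int(row.argmax()) == 0  # documented argmax convention


class TestFiducials:
    def test_all_nowave_empty(self):
        mask = ed.LabelMask(np.full(370, 3))
        assert fiducials_from_mask(mask, np.zeros(370), 250.0) == []

    def test_qrs_run_duration(self):
        classes = np.full(370, 3)
        classes[100:130] = 1
        samples = np.zeros(370)
        samples[115] = 2.0
        (f,) = fiducials_from_mask(ed.LabelMask(classes), samples, 250.0)
        assert f.wave == "QRS"
        assert f.duration_s == pytest.approx(0.12)
        assert f.peak_index == 115

    def test_spurious_short_runs_discarded(self):
        classes = np.full(370, 3)
        classes[10:13] = 0  # 12 ms < 20 ms floor
        assert fiducials_from_mask(ed.LabelMask(classes), np.zeros(370), 250.0) == []


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = build_model([2, 4], 3, seed=11)
        model.trained = True
        x = np.random.default_rng(0).normal(size=(1, 370))
        before = model.forward(x)
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        loaded = DelineatorModel.load(path)
        assert loaded.trained
        np.testing.assert_allclose(loaded.forward(x), before, atol=1e-12)


class TestEstimatorInterface:
    def test_get_set_params_clone_compatible(self):
        from sklearn.base import clone

        est = ed.CnnBiLstmDelineator(units_per_direction=4, epochs=1)
        cloned = clone(est)
        assert cloned.get_params()["units_per_direction"] == 4

    def test_fit_predict_shapes_and_score(self):
        windows = ed.generate_training_windows(6, seed=13)
        X = np.stack([w.samples for w in windows])
        y = np.stack([w.mask.classes for w in windows])
        est = ed.CnnBiLstmDelineator(conv_filters=(2,), units_per_direction=3,
                                     epochs=2, learning_rate=1e-3,
                                     validation_fraction=0.0, random_state=0)
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (6, 370, 5)
        pred = est.predict(X)
        assert pred.shape == (6, 370)
        assert 0.0 <= est.score(X, y) <= 1.0
        assert len(est.history_["loss"]) == 2

    def test_label_validation(self):
        est = ed.CnnBiLstmDelineator(epochs=1)
        X = np.zeros((2, 370))
        y = np.full((2, 370), 9)
        with pytest.raises(ValidationError):
            est.fit(X, y)
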