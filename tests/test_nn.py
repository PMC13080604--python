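"""CNN–BiLSTM scorer: shape contracts, arithmetic oracles, training."""

import numpy as np
import pytest

from vibroscreen.nn import (CNNBiLSTM, CNNBiLSTMClassifier, LSTMCell,
                            lstm_forward, sigmoid, videos_to_slices)
from vibroscreen.video import VideoCube


def tiny_net(seed=0):
    return CNNBiLSTM(in_channels=4, base_channels=4, feature_dim=8,
                     hidden_size=4, seed=seed)


def zero_params(net):
    for layer in net.layers:
        for sub in getattr(layer, "children", [layer]):
            for k in sub.params:
                sub.params[k][...] = 0.0


class TestEncoder:
    def test_one_vector_per_slice(self, rng):
        net = tiny_net()
        slices = rng.normal(size=(6, 4, 8, 8))
        z = net.encode(slices)
        assert z.shape == (6, 8)

    def test_zero_weights_give_zero_features(self, rng):
        net = tiny_net()
        zero_params(net)
        z = net.encode(rng.normal(size=(3, 4, 8, 8)))
        assert np.all(z == 0)

    def test_identical_slices_identical_features(self, rng):
        net = tiny_net()
        s = rng.normal(size=(1, 4, 8, 8))
        z = net.encode(np.concatenate([s, s]))
        np.testing.assert_array_equal(z[0], z[1])

    def test_undersized_input_rejected(self, rng):
        net = tiny_net()
        with pytest.raises(ValueError, match="receptive-field"):
            net.encode(rng.normal(size=(1, 4, 2, 2)))

    def test_slicing_shape_and_short_video_error(self, rng):
        frames = rng.uniform(0, 1, size=(20, 8, 8))
        cube = VideoCube(frames, frame_rate=32.0)
        slices = videos_to_slices([cube], slice_len=8)
        assert slices.shape == (1, 2, 8, 8, 8)  # trailing 4 frames dropped
        with pytest.raises(ValueError, match="shorter"):
            videos_to_slices([cube], slice_len=32)


class TestBiLSTM:
    def test_state_has_twice_hidden_size(self, rng):
        net = tiny_net()
        h = net.aggregate(rng.normal(size=(2, 5, 8)))
        assert h.shape == (2, 8)

    def test_single_step_matches_hand_unrolled_cell(self, rng):
        """One-step LSTM equals the gate equations applied by hand."""
        cell = LSTMCell(3, 2, rng=np.random.default_rng(7))
        x = rng.normal(size=(1, 1, 3))
        h, _ = lstm_forward(cell, x)
        z = x[0, 0] @ cell.params["Wx"].T + cell.params["b"]
        i, f, g, o = (sigmoid(z[:2]), sigmoid(z[2:4]), np.tanh(z[4:6]),
                      sigmoid(z[6:]))
        np.testing.assert_allclose(h[0], o * np.tanh(i * g), rtol=1e-12)

    def test_reversed_input_swaps_direction_halves(self, rng):
        net = tiny_net()
        # share weights between directions so the swap is exact
        for k in net.lstm_f.params:
            net.lstm_b.params[k] = net.lstm_f.params[k].copy()
        seq = rng.normal(size=(1, 6, 8))
        h_fwd = net.aggregate(seq)
        h_rev = net.aggregate(seq[:, ::-1])
        m = net.hidden_size
        np.testing.assert_allclose(h_rev[:, :m], h_fwd[:, m:], rtol=1e-10)
        np.testing.assert_allclose(h_rev[:, m:], h_fwd[:, :m], rtol=1e-10)


class TestHeads:
    def test_zero_weights_give_half_probability(self, rng):
        net = tiny_net()
        zero_params(net)
        out = net.heads(rng.normal(size=(4, 8)))
        np.testing.assert_array_equal(out["p_dep"], 0.5)
        np.testing.assert_array_equal(out["p_anx"], 0.5)

    def test_probabilities_in_unit_interval_for_any_weights(self, rng):
        net = tiny_net()
        for layer in (net.head_cls_dep, net.head_cls_anx):
            layer.params["W"] = rng.normal(0, 100, layer.params["W"].shape)
        out = net.heads(rng.normal(size=(10, 8)) * 50)
        for key in ("p_dep", "p_anx"):
            assert np.all((out[key] >= 0) & (out[key] <= 1))

    def test_matches_dot_product_logistic_oracle(self, rng):
        net = tiny_net()
        h = rng.normal(size=(5, 8))
        out = net.heads(h)
        w = net.head_cls_dep.params["W"][0]
        b = net.head_cls_dep.params["b"][0]
        expected = 1 / (1 + np.exp(-(h @ w + b)))
        np.testing.assert_allclose(out["p_dep"], expected, rtol=1e-12)

    def test_increasing_logit_increases_probability(self):
        net = tiny_net()
        h = np.zeros((2, 8))
        h[1, 0] = 1.0
        net.head_cls_dep.params["W"][0, :] = 0
        net.head_cls_dep.params["W"][0, 0] = 2.0
        out = net.heads(h)
        assert out["p_dep"][1] > out["p_dep"][0]

    def test_non_finite_state_rejected(self):
        net = tiny_net()
        h = np.full((1, 8), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            net.heads(h)

    def test_multitask_independence(self, rng):
        """Zeroing the anxiety head leaves depression scores unchanged."""
        net = tiny_net()
        h = rng.normal(size=(4, 8))
        before = net.heads(h)["p_dep"]
        net.head_cls_anx.params["W"][...] = 0
        net.head_cls_anx.params["b"][...] = 0
        after = net.heads(h)
        np.testing.assert_array_equal(after["p_dep"], before)
        np.testing.assert_array_equal(after["p_anx"], 0.5)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, rng):
        """Finite-difference check through conv, LSTM and heads."""
        net = tiny_net(seed=3)
        batch = rng.normal(size=(2, 3, 4, 8, 8))
        targets = {"p_dep": np.array([0.0, 1.0]), "p_anx": np.array([1.0, 0.0]),
                   "sev_dep": np.array([0.2, 0.8]), "sev_anx": None}

        def loss_at():
            out = net.forward(batch)
            b = out["p_dep"].shape[0]
            eps = 1e-7
            l = 0.0
            for name, w, kind in (("p_dep", 1.0, "bce"), ("p_anx", 1.0, "bce"),
                                  ("sev_dep", 0.5, "mse")):
                y = targets[name]
                p = out[name]
                if kind == "bce":
                    p = np.clip(p, eps, 1 - eps)
                    l += w * float(-np.mean(y * np.log(p) +
                                            (1 - y) * np.log(1 - p)))
                else:
                    l += w * float(np.mean((p - y) ** 2))
            return l

        for layer in net.layers:
            for sub in getattr(layer, "children", [layer]):
                sub.zero_grad()
        out = net.forward(batch)
        analytic_loss = net.loss_and_backward(out, targets)
        assert analytic_loss == pytest.approx(loss_at(), rel=1e-9)

        checks = [(net.stem, "W", (0, 0, 1, 1)), (net.lstm_f, "Wx", (2, 3)),
                  (net.head_cls_dep, "W", (0, 4)), (net.head_reg_dep, "b", (0,))]
        h = 1e-5
        for sub, key, idx in checks:
            orig = sub.params[key][idx]
            sub.params[key][idx] = orig + h
            up = loss_at()
            sub.params[key][idx] = orig - h
            down = loss_at()
            sub.params[key][idx] = orig
            numeric = (up - down) / (2 * h)
            assert sub.grads[key][idx] == pytest.approx(numeric, rel=2e-3,
                                                        abs=1e-7)


def _toy_videos(rng, n=8, amp_hi=4.0):
    cubes, labels = [], []
    for i in range(n):
        label = i % 2
        amp = amp_hi if label else 1.0
        t = np.arange(16) / 16
        frames = 10 + amp * np.sin(2 * np.pi * 2 * t)[:, None, None] * np.ones(
            (16, 8, 8)) + rng.normal(0, 0.1, (16, 8, 8))
        cubes.append(VideoCube(np.maximum(frames, 0), frame_rate=16.0))
        labels.append(label)
    return cubes, np.array(labels)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        cubes, labels = _toy_videos(rng)
        est = CNNBiLSTMClassifier(slice_len=4, base_channels=4, feature_dim=8,
                                  hidden_size=4, epochs=8, batch_size=4,
                                  random_state=0)
        est.fit(cubes, labels)
        assert est.loss_history_[-1] <= est.loss_history_[0]

    def test_same_seed_identical_weights_and_predictions(self, rng):
        cubes, labels = _toy_videos(rng)
        kw = dict(slice_len=4, base_channels=4, feature_dim=8, hidden_size=4,
                  epochs=2, batch_size=4, random_state=11)
        a = CNNBiLSTMClassifier(**kw).fit(cubes, labels)
        b = CNNBiLSTMClassifier(**kw).fit(cubes, labels)
        np.testing.assert_array_equal(a.net_.stem.params["W"],
                                      b.net_.stem.params["W"])
        np.testing.assert_array_equal(a.predict_proba(cubes),
                                      b.predict_proba(cubes))

    def test_prediction_is_pure_function_of_weights(self, rng):
        cubes, labels = _toy_videos(rng)
        est = CNNBiLSTMClassifier(slice_len=4, base_channels=4, feature_dim=8,
                                  hidden_size=4, epochs=1, random_state=0)
        est.fit(cubes, labels)
        np.testing.assert_array_equal(est.predict_scores(cubes).to_numpy(),
                                      est.predict_scores(cubes).to_numpy())

    def test_single_class_task_error_names_task(self, rng):
        cubes, _ = _toy_videos(rng, n=4)
        est = CNNBiLSTMClassifier(slice_len=4)
        with pytest.raises(ValueError, match="anxiety"):
            est.fit(cubes, {"dep": [0, 1, 0, 1], "anx": [1, 1, 1, 1]})

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        cubes, labels = _toy_videos(rng)
        est = CNNBiLSTMClassifier(slice_len=4, base_channels=4, feature_dim=8,
                                  hidden_size=4, epochs=1, random_state=0)
        est.fit(cubes, labels)
        path = tmp_path / "model.npz"
        est.save(path)
        loaded = CNNBiLSTMClassifier.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(cubes),
                                      est.predict_proba(cubes))

    def test_encode_and_aggregate_api(self, rng):
        cubes, labels = _toy_videos(rng, n=4)
        est = CNNBiLSTMClassifier(slice_len=4, base_channels=4, feature_dim=8,
                                  hidden_size=4, epochs=1, random_state=0)
        est.fit(cubes, labels)
        z = est.encode_frames(cubes[0])
        assert z.shape == (4, 8)  # 16 frames / slice_len 4 -> 4 slices
        h = est.aggregate_sequence(z)
        assert h.shape == (8,)  # 2 × hidden_size
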