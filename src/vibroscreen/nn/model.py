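"""Desk-scale CNN–BiLSTM dual-risk scorer.

A small residual CNN encodes each *time slice* (a short stack of
consecutive frames, default 8, presented to the convolution as input
channels so it can see motion) into a d-dimensional feature vector z_t.
A bidirectional LSTM consumes the sequence z_1..z_T; the concatenation
of its final forward and backward hidden states h ∈ R^{2m} feeds four
parallel heads:

* two classification heads — ``p = σ(W h + b)`` — yielding the
  depression and anxiety risk probabilities, and
* two linear regression heads yielding continuous severity scores
  (trained against 1–5 clinical ratings rescaled to [0, 1]).

Training minimises a weighted sum of two binary cross-entropies and two
squared-error terms (default weights 1 : 1 : 0.5 : 0.5) with Adam.  The
default width (d = 32, m = 32, two residual blocks) is deliberately
small; depth and width scale up by configuration.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..video import VideoCube
from .layers import (Adam, Conv2d, GlobalAvgPool, Linear, LSTMCell, ReLU,
                     ResidualBlock, lstm_backward, lstm_forward, sigmoid)

__all__ = ["CNNBiLSTM", "CNNBiLSTMClassifier", "videos_to_slices"]

_EPS = 1e-7


def videos_to_slices(videos, slice_len: int, normalize: bool = True) -> np.ndarray:
    """Stack video cubes into a (B, S, slice_len, H, W) slice tensor.

    Each slice is ``slice_len`` consecutive frames treated as channels;
    trailing frames that do not fill a slice are dropped.  All cubes
    must share geometry.  Normalisation subtracts each video's mean and
    applies a fixed 1/10 intensity scale — a shift-invariant transform
    that deliberately preserves between-video amplitude differences,
    which are part of the signal.
    """
    arrs = []
    shape = None
    for v in videos:
        frames = v.frames if isinstance(v, VideoCube) else np.asarray(v)
        s = frames.shape[0] // slice_len
        if s < 1:
            raise ValueError(
                f"video with {frames.shape[0]} frames is shorter than one "
                f"slice ({slice_len} frames)"
            )
        x = frames[: s * slice_len].reshape(s, slice_len, *frames.shape[1:])
        if shape is None:
            shape = x.shape
        elif x.shape != shape:
            raise ValueError("all videos must share frame count and geometry")
        if normalize:
            x = (x - frames.mean()) / 10.0
        arrs.append(x)
    return np.stack(arrs)


class CNNBiLSTM:
    """The raw network: parameters, forward pass, and backward pass."""

    def __init__(self, in_channels: int = 8, base_channels: int = 16,
                 feature_dim: int = 32, hidden_size: int = 32,
                 res_blocks_per_stage: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.feature_dim = feature_dim
        self.hidden_size = hidden_size
        self.stem = Conv2d(in_channels, base_channels, stride=2, rng=rng)
        self.relu1 = ReLU()
        self.stage1 = [ResidualBlock(base_channels, rng=rng)
                       for _ in range(res_blocks_per_stage)]
        self.conv2 = Conv2d(base_channels, feature_dim, stride=2, rng=rng)
        self.relu2 = ReLU()
        self.stage2 = [ResidualBlock(feature_dim, rng=rng)
                       for _ in range(res_blocks_per_stage)]
        self.pool = GlobalAvgPool()
        self.lstm_f = LSTMCell(feature_dim, hidden_size, rng=rng)
        self.lstm_b = LSTMCell(feature_dim, hidden_size, rng=rng)
        self.head_cls_dep = Linear(2 * hidden_size, 1, rng=rng)
        self.head_cls_anx = Linear(2 * hidden_size, 1, rng=rng)
        self.head_reg_dep = Linear(2 * hidden_size, 1, rng=rng)
        self.head_reg_anx = Linear(2 * hidden_size, 1, rng=rng)

    @property
    def layers(self):
        return [self.stem, *self.stage1, self.conv2, *self.stage2,
                self.lstm_f, self.lstm_b, self.head_cls_dep,
                self.head_cls_anx, self.head_reg_dep, self.head_reg_anx]

    # -- forward -----------------------------------------------------------

    #: smallest H and W the two stride-2 stages can usefully downsample
    MIN_INPUT_SIZE = 8

    def encode(self, slices: np.ndarray) -> np.ndarray:
        """(N, C, H, W) slice stack -> (N, d) feature vectors z."""
        if min(slices.shape[2], slices.shape[3]) < self.MIN_INPUT_SIZE:
            raise ValueError(
                f"slice geometry {slices.shape[2]}×{slices.shape[3]} is below "
                f"the encoder's receptive-field minimum "
                f"({self.MIN_INPUT_SIZE}×{self.MIN_INPUT_SIZE})"
            )
        x = self.relu1.forward(self.stem.forward(slices))
        for blk in self.stage1:
            x = blk.forward(x)
        x = self.relu2.forward(self.conv2.forward(x))
        for blk in self.stage2:
            x = blk.forward(x)
        return self.pool.forward(x)

    def encode_backward(self, dz: np.ndarray) -> None:
        d = self.pool.backward(dz)
        for blk in reversed(self.stage2):
            d = blk.backward(d)
        d = self.conv2.backward(self.relu2.backward(d))
        for blk in reversed(self.stage1):
            d = blk.backward(d)
        self.stem.backward(self.relu1.backward(d))

    def aggregate(self, features: np.ndarray):
        """(B, S, d) feature sequences -> (B, 2m) temporal state h."""
        h_f, cache_f = lstm_forward(self.lstm_f, features)
        h_b, cache_b = lstm_forward(self.lstm_b, features[:, ::-1])
        self._lstm_caches = (cache_f, cache_b)
        return np.concatenate([h_f, h_b], axis=1)

    def aggregate_backward(self, dh: np.ndarray) -> np.ndarray:
        m = self.hidden_size
        cache_f, cache_b = self._lstm_caches
        dx_f = lstm_backward(self.lstm_f, dh[:, :m], cache_f)
        dx_b = lstm_backward(self.lstm_b, dh[:, m:], cache_b)
        return dx_f + dx_b[:, ::-1]

    def heads(self, h: np.ndarray) -> dict[str, np.ndarray]:
        if not np.isfinite(h).all():
            raise ValueError("non-finite temporal state h")
        return {
            "p_dep": sigmoid(self.head_cls_dep.forward(h)[:, 0]),
            "p_anx": sigmoid(self.head_cls_anx.forward(h)[:, 0]),
            "sev_dep": self.head_reg_dep.forward(h)[:, 0],
            "sev_anx": self.head_reg_anx.forward(h)[:, 0],
        }

    def forward(self, batch: np.ndarray) -> dict[str, np.ndarray]:
        """batch: (B, S, C, H, W) -> risk scores per video."""
        b, s, c, hh, ww = batch.shape
        z = self.encode(batch.reshape(b * s, c, hh, ww))
        self._bs = (b, s)
        h = self.aggregate(z.reshape(b, s, -1))
        self._h = h
        return self.heads(h)

    # -- loss and backward -------------------------------------------------

    def loss_and_backward(self, out, targets, weights=(1.0, 1.0, 0.5, 0.5)):
        """Weighted BCE + MSE loss; accumulates all parameter gradients.

        ``targets`` maps head name -> array (classification targets in
        {0,1}, regression targets in [0,1]); a head absent from targets
        is skipped.  Returns the scalar loss.
        """
        b = self._h.shape[0]
        loss = 0.0
        dh = np.zeros_like(self._h)
        specs = [
            ("p_dep", self.head_cls_dep, weights[0], "bce"),
            ("p_anx", self.head_cls_anx, weights[1], "bce"),
            ("sev_dep", self.head_reg_dep, weights[2], "mse"),
            ("sev_anx", self.head_reg_anx, weights[3], "mse"),
        ]
        for name, head, w, kind in specs:
            if name not in targets or targets[name] is None:
                continue
            y = np.asarray(targets[name], dtype=np.float64)
            pred = out[name]
            if kind == "bce":
                p = np.clip(pred, _EPS, 1 - _EPS)
                loss += w * float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
                dlogit = w * (pred - y)[:, None] / b  # σ+BCE composite gradient
            else:
                loss += w * float(np.mean((pred - y) ** 2))
                dlogit = w * 2 * (pred - y)[:, None] / b
            dh += head.backward(dlogit)
        dx = self.aggregate_backward(dh)
        bsz, s = self._bs
        self.encode_backward(dx.reshape(bsz * s, -1))
        return loss


class CNNBiLSTMClassifier(BaseEstimator):
    """sklearn-style estimator wrapping the CNN–BiLSTM dual-risk scorer.

    ``fit(X, y)`` trains on a list of :class:`VideoCube` (or raw T×H×W
    arrays).  ``y`` is either a 1-D binary vector (applied to both risk
    heads) or a DataFrame/dict with any of the columns ``dep``, ``anx``
    (binary) and ``sev_dep``, ``sev_anx`` (clinical 1–5 severities,
    rescaled internally to [0, 1]).  Each supplied classification task
    must contain both classes.

    ``predict_scores`` returns a DataFrame of calibratable risk
    probabilities and severity scores; ``predict_proba``/``predict``
    expose the depression-or-primary head in sklearn's binary layout.

    Parameters
    ----------
    slice_len : int, default 8
        Frames per time slice (the encoder's input channels).
    base_channels, feature_dim, hidden_size : int
        Network width; defaults 16 / 32 / 32 (desk scale).
    res_blocks_per_stage : int, default 1
        Residual blocks in each of the two encoder stages.
    loss_weights : tuple, default (1, 1, 0.5, 0.5)
        (cls dep, cls anx, reg dep, reg anx) loss weights.
    epochs, batch_size, lr : training schedule.
    random_state : int
        Seeds initialisation and batch shuffling; fits are reproducible.
    """

    def __init__(self, slice_len: int = 8, base_channels: int = 16,
                 feature_dim: int = 32, hidden_size: int = 32,
                 res_blocks_per_stage: int = 1,
                 loss_weights: tuple = (1.0, 1.0, 0.5, 0.5),
                 epochs: int = 30, batch_size: int = 16, lr: float = 3e-3,
                 random_state: int = 0):
        self.slice_len = slice_len
        self.base_channels = base_channels
        self.feature_dim = feature_dim
        self.hidden_size = hidden_size
        self.res_blocks_per_stage = res_blocks_per_stage
        self.loss_weights = loss_weights
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    # -- target handling ---------------------------------------------------

    @staticmethod
    def _coerce_targets(y, n: int) -> dict[str, np.ndarray | None]:
        if isinstance(y, (pd.DataFrame, dict)):
            get = (lambda k: np.asarray(y[k]) if k in y else None)
            if isinstance(y, pd.DataFrame):
                get = (lambda k: y[k].to_numpy() if k in y.columns else None)
            t = {"p_dep": get("dep"), "p_anx": get("anx"),
                 "sev_dep": get("sev_dep"), "sev_anx": get("sev_anx")}
        else:
            arr = np.asarray(y)
            if arr.ndim != 1:
                raise ValueError("array targets must be 1-D binary labels")
            t = {"p_dep": arr, "p_anx": arr, "sev_dep": None, "sev_anx": None}
        for key, task in (("p_dep", "depression"), ("p_anx", "anxiety")):
            if t[key] is not None:
                labels = np.unique(np.asarray(t[key], dtype=float))
                if labels.size < 2:
                    raise ValueError(
                        f"{task} classification task has a single class; "
                        "need both classes to train"
                    )
        for key in ("sev_dep", "sev_anx"):
            if t[key] is not None:
                t[key] = (np.asarray(t[key], dtype=float) - 1.0) / 4.0
        if t["p_dep"] is None and t["p_anx"] is None:
            raise ValueError("at least one classification target is required")
        for key in t:
            if t[key] is not None and len(t[key]) != n:
                raise ValueError(f"target {key} length != number of videos")
        return t

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        slices = videos_to_slices(X, self.slice_len)
        n = slices.shape[0]
        targets = self._coerce_targets(y, n)
        rng = np.random.default_rng(self.random_state)
        self.net_ = CNNBiLSTM(
            in_channels=self.slice_len, base_channels=self.base_channels,
            feature_dim=self.feature_dim, hidden_size=self.hidden_size,
            res_blocks_per_stage=self.res_blocks_per_stage,
            seed=int(rng.integers(2**31 - 1)),
        )
        opt = Adam(self.net_.layers, lr=self.lr)
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            if _epoch == (2 * self.epochs) // 3:
                opt.lr = self.lr * 0.3  # step decay to settle the optimum
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                out = self.net_.forward(slices[idx])
                batch_t = {k: (v[idx] if v is not None else None)
                           for k, v in targets.items()}
                epoch_loss += self.net_.loss_and_backward(
                    out, batch_t, self.loss_weights) * len(idx)
                opt.step()
            self.loss_history_.append(epoch_loss / n)
        self.n_features_in_ = n
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise AttributeError("CNNBiLSTMClassifier is not fitted")

    def encode_frames(self, video) -> np.ndarray:
        """Feature sequence z_1..z_S (S × d) of one video."""
        self._check_fitted()
        slices = videos_to_slices([video], self.slice_len)[0]
        return self.net_.encode(slices)

    def aggregate_sequence(self, features: np.ndarray) -> np.ndarray:
        """BiLSTM temporal state h (length 2m) of one feature sequence."""
        self._check_fitted()
        return self.net_.aggregate(np.asarray(features)[None])[0]

    def predict_scores(self, X) -> pd.DataFrame:
        """Risk probabilities and severity scores, one row per video."""
        self._check_fitted()
        out = self.net_.forward(videos_to_slices(X, self.slice_len))
        sev = {k: np.clip(out[k], 0, 1) * 4 + 1 for k in ("sev_dep", "sev_anx")}
        return pd.DataFrame({"p_dep": out["p_dep"], "p_anx": out["p_anx"],
                             "sev_dep": sev["sev_dep"], "sev_anx": sev["sev_anx"]})

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_scores(X)["p_dep"].to_numpy()
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- portable checkpoints ---------------------------------------------

    def _param_entries(self):
        entries = []
        for i, layer in enumerate(self.net_.layers):
            for j, sub in enumerate(getattr(layer, "children", [layer])):
                for key in sub.params:
                    entries.append((f"l{i}_{j}_{key}", sub, key))
        return entries

    def save(self, path) -> None:
        """Write a portable checkpoint (.npz: hyperparameters + weights)."""
        self._check_fitted()
        arrays = {name: sub.params[key] for name, sub, key in self._param_entries()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.get_params()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "CNNBiLSTMClassifier":
        """Restore an estimator from a checkpoint written by :meth:`save`."""
        with np.load(path) as data:
            config = json.loads(bytes(data["__config__"]).decode())
            config["loss_weights"] = tuple(config["loss_weights"])
            est = cls(**config)
            est.net_ = CNNBiLSTM(
                in_channels=est.slice_len, base_channels=est.base_channels,
                feature_dim=est.feature_dim, hidden_size=est.hidden_size,
                res_blocks_per_stage=est.res_blocks_per_stage,
                seed=est.random_state,
            )
            for name, sub, key in est._param_entries():
                sub.params[key] = data[name]
        return est
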