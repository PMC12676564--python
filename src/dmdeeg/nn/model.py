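"""The 3D CNN classifier for 50x50x12x1 feature tensors.

Architecture (three conv blocks, then a two-layer fully connected head):

    input (z-score)
    -> [conv3d 16 @ 3x3x3, BN, ReLU, maxpool 2x2x2]
    -> [conv3d 32 @ 3x3x3, BN, ReLU, maxpool 2x2x2]
    -> [conv3d 64 @ 3x3x3, BN, ReLU, maxpool 2x2x2]
    -> dropout 0.25 -> flatten (7*7*2*64 = 6272)
    -> dense 128, ReLU, dropout 0.20
    -> dense 64, ReLU, dropout 0.25
    -> dense n_classes, softmax

Training uses Adam at lr 5e-4, mini-batches of 16, at most 75 epochs, with
cross-entropy loss.  z-score normalization statistics (per-voxel mean/std) are
computed on the training set only and frozen for inference.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (Adam, BatchNorm, Conv3D, Dense, Dropout, Flatten,
                     MaxPool3D, ReLU, cross_entropy, softmax, F32)


@dataclass
class ModelConfig:
    input_shape: tuple = (50, 50, 12, 1)      # height x width x depth x channel
    conv_filters: tuple = (16, 32, 64)
    kernel: int = 3
    conv_dropout: float = 0.25
    fc_units: tuple = (128, 64)
    fc_dropouts: tuple = (0.20, 0.25)
    n_classes: int = 2

    def __post_init__(self):
        for p in (self.conv_dropout, *self.fc_dropouts):
            if not 0 <= p < 1:
                raise ValueError("dropout rates must be in [0, 1)")
        if list(self.conv_filters) != sorted(set(self.conv_filters)):
            raise ValueError("conv filter counts must be strictly increasing")
        if len(self.input_shape) != 4:
            raise ValueError("input_shape must be H x W x D x C")


@dataclass
class TrainConfig:
    max_epochs: int = 75
    batch_size: int = 16
    learning_rate: float = 5e-4
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.max_epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.optimizer != "adam" or self.loss != "cross_entropy":
            raise ValueError("only adam + cross-entropy are supported")


def _pooled(extent, n_pools):
    for _ in range(n_pools):
        extent = -(-extent // 2)  # ceil division
    return extent


class CNN3D:
    """Feed-forward 3D CNN with explicit forward/backward passes."""

    def __init__(self, cfg: ModelConfig = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.norm_mean = None
        self.norm_std = None
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self):
        cfg = self.cfg
        h, w, d, c = cfg.input_shape
        layers, names = [], []
        in_ch = c
        for nf in cfg.conv_filters:
            layers += [Conv3D(in_ch, nf, cfg.kernel, rng=self.rng),
                       BatchNorm(nf), ReLU(), MaxPool3D()]
            names += [f"conv3d({nf}, {cfg.kernel}x{cfg.kernel}x{cfg.kernel})",
                      f"batchnorm({nf})", "relu", "maxpool(2x2x2, stride 2)"]
            in_ch = nf
        n_pools = len(cfg.conv_filters)
        flat = (_pooled(h, n_pools) * _pooled(w, n_pools) * _pooled(d, n_pools)
                * cfg.conv_filters[-1])
        self.flat_len = flat
        layers += [Dropout(cfg.conv_dropout, self.rng), Flatten()]
        names += [f"dropout({cfg.conv_dropout})", "flatten"]
        n_in = flat
        for units, p in zip(cfg.fc_units, cfg.fc_dropouts):
            layers += [Dense(n_in, units, rng=self.rng), ReLU(),
                       Dropout(p, self.rng)]
            names += [f"dense({units})", "relu", f"dropout({p})"]
            n_in = units
        layers += [Dense(n_in, cfg.n_classes, rng=self.rng)]
        names += [f"dense({cfg.n_classes})", "softmax"]
        self.layers, self.layer_names = layers, names

    def summary(self) -> list:
        """Ordered layer descriptions (input z-score stage included)."""
        return ["input(z-score)"] + list(self.layer_names)

    # -- data plumbing -----------------------------------------------------

    def _to_network(self, X) -> np.ndarray:
        """(N, 50, 50, 12) or (N, 50, 50, 12, 1) -> (N, 1, 12, 50, 50) float32."""
        X = np.asarray(X, dtype=F32)
        if X.ndim == 4:
            X = X[..., None]
        h, w, d, c = self.cfg.input_shape
        if X.shape[1:] != (h, w, d, c):
            raise ValueError(f"input shape {X.shape[1:]} != expected {(h, w, d, c)}")
        return np.ascontiguousarray(X.transpose(0, 4, 3, 1, 2))

    def _normalize(self, X):
        return (X - self.norm_mean) / self.norm_std

    def _forward(self, X, train=False):
        out = X
        for layer in self.layers:
            out = layer.forward(out, train=train)
        return out

    # -- training ----------------------------------------------------------

    def fit(self, X, y, train_cfg: TrainConfig = None):
        """Train on tensors X (N x 50 x 50 x 12[,1]) with integer labels y.

        Returns a history dict with per-epoch ``loss`` and ``accuracy``.
        """
        cfg = train_cfg or TrainConfig()
        y = np.asarray(y, dtype=np.int64)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least 2 classes")
        X = self._to_network(X)
        self.norm_mean = X.mean(axis=0, keepdims=True)
        self.norm_std = np.maximum(X.std(axis=0, keepdims=True), 1e-8).astype(F32)
        X = self._normalize(X)
        rng = np.random.default_rng(cfg.seed)
        # reseed dropout streams for reproducible training
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng(rng.integers(2 ** 31))
        opt = Adam(self.layers, lr=cfg.learning_rate)
        n = X.shape[0]
        history = {"loss": [], "accuracy": []}
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(X[idx], train=True)
                loss, dlogits = cross_entropy(logits, y[idx])
                losses.append(loss * len(idx))
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                opt.step()
            history["loss"].append(sum(losses) / n)
            history["accuracy"].append(correct / n)
        return history

    # -- persistence -------------------------------------------------------

    def save(self, path):
        """Checkpoint parameters, batch-norm statistics, and normalization."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.params.items():
                arrays[f"p{i}_{key}"] = val
            if isinstance(layer, BatchNorm):
                arrays[f"rm{i}"] = layer.running_mean
                arrays[f"rv{i}"] = layer.running_var
        if self.norm_mean is not None:
            arrays["norm_mean"] = self.norm_mean
            arrays["norm_std"] = self.norm_std
        np.savez(path, seed=self.seed, **arrays)

    @classmethod
    def load(cls, path, cfg: ModelConfig = None):
        with np.load(path) as data:
            model = cls(cfg, seed=int(data["seed"]))
            for i, layer in enumerate(model.layers):
                for key in layer.params:
                    layer.params[key] = data[f"p{i}_{key}"]
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"rm{i}"]
                    layer.running_var = data[f"rv{i}"]
            if "norm_mean" in data:
                model.norm_mean = data["norm_mean"]
                model.norm_std = data["norm_std"]
        return model

    # -- inference ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Per-sample class probabilities (rows sum to 1)."""
        if self.norm_mean is None:
            raise RuntimeError("model is untrained: call fit() first")
        X = self._normalize(self._to_network(X))
        return softmax(self._forward(X, train=False))

    def predict(self, X) -> np.ndarray:
        """Hard labels: argmax probability, ties toward the lower class index."""
        return self.predict_proba(X).argmax(axis=1)


def build_model(cfg: ModelConfig = None, seed: int = 0) -> CNN3D:
    """Construct an initialized (untrained) classifier."""
    return CNN3D(cfg, seed=seed)
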