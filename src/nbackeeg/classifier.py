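"""Channel-wise convolutional classifier.

Architecture (for either 8x6 representation):

    input (6 positions x 8 channels)
      -> 1-D convolution along the 6-position axis, kernel size 1,
         128 filters - each filter mixes the 8 channel values at one
         position; kernel 1 means no temporal receptive field, so the
         conv is position-equivariant
      -> ReLU
      -> flatten (6 x 128 = 768)
      -> fully connected, 32 units (linear)
      -> softmax over 2 classes

Trained with categorical cross-entropy and Adam (the protocol names no
optimizer; Adam at 1e-3 is the de-facto default) for a fixed number of
epochs - no early stopping.  Implemented directly in numpy: the model
has ~26k parameters and trains in seconds on a CPU, and an explicit
forward/backward keeps the arithmetic reproducible bit-for-bit under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["CNNConfig", "ChannelwiseCNN", "build_model", "train", "predict"]


@dataclass(frozen=True)
class CNNConfig:
    """Hyperparameters; defaults follow the published protocol."""

    conv_filters: int = 128
    conv_kernel: int = 1
    dense_units: int = 32
    n_classes: int = 2
    epochs: int = 1000
    batch_size: int = 128
    learning_rate: float = 1e-3
    validation_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_kernel != 1:
            raise ValueError("the channel-wise architecture uses kernel size 1")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ChannelwiseCNN:
    """Numpy implementation of the kernel-1 channel-mixing CNN.

    Inputs are (n, positions, channels) arrays - positions is the
    6-value feature axis, channels the 8 electrodes.  ``fit`` holds out
    ``validation_fraction`` of the provided training data for per-epoch
    monitoring only (no early stopping).
    """

    def __init__(self, config: CNNConfig, n_positions: int = 6, n_channels: int = 8):
        self.config = config
        self.n_positions = n_positions
        self.n_channels = n_channels
        init_rng, self._fit_seed = self._derive_streams(config.seed)
        f, d, c = config.conv_filters, config.dense_units, config.n_classes
        flat = n_positions * f
        self.Wc = _glorot(init_rng, n_channels, f, (n_channels, f))
        self.bc = np.zeros(f)
        self.Wd = _glorot(init_rng, flat, d, (flat, d))
        self.bd = np.zeros(d)
        self.Wo = _glorot(init_rng, d, c, (d, c))
        self.bo = np.zeros(c)
        self.history: dict[str, list[float]] = {}

    @staticmethod
    def _derive_streams(seed: int):
        ss = np.random.SeedSequence(seed)
        init_ss, fit_ss = ss.spawn(2)
        return np.random.default_rng(init_ss), fit_ss

    # -- architecture ----------------------------------------------------

    @property
    def parameters(self) -> list[np.ndarray]:
        return [self.Wc, self.bc, self.Wd, self.bd, self.Wo, self.bo]

    @property
    def n_parameters(self) -> int:
        """Total trainable parameter count."""
        return int(sum(p.size for p in self.parameters))

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.n_positions, self.n_channels):
            raise ValueError(
                f"expected (n, {self.n_positions}, {self.n_channels}) input, "
                f"got {X.shape}"
            )
        return X

    def _forward(self, X: np.ndarray):
        # conv kernel 1: same (channels -> filters) map at each position
        Z = X @ self.Wc + self.bc            # (n, pos, filters)
        A = np.maximum(Z, 0.0)               # ReLU
        flat = A.reshape(X.shape[0], -1)     # (n, pos*filters)
        D = flat @ self.Wd + self.bd         # (n, dense)
        logits = D @ self.Wo + self.bo       # (n, classes)
        return Z, A, flat, D, _softmax(logits)

    def conv_activations(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU convolution output, (n, positions, filters)."""
        return self._forward(self._check_input(X))[1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(self._check_input(X))[4]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax labels; a tie goes to class 0 (argmax takes the first)."""
        return np.argmax(self.predict_proba(X), axis=1)

    # -- training --------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> dict[str, list[float]]:
        """Minimize cross-entropy with Adam for exactly ``epochs`` epochs."""
        cfg = self.config
        X = self._check_input(X)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")

        rng = np.random.default_rng(self._fit_seed)
        n = X.shape[0]
        n_val = int(round(cfg.validation_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if np.unique(y[tr_idx]).size < 2:  # tiny-data corner: keep it trainable
            tr_idx, val_idx = perm, perm[:0]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        batch = min(cfg.batch_size, len(tr_idx))
        params = self.parameters
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        hist: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }
        onehot = np.eye(cfg.n_classes)

        for _ in range(cfg.epochs):
            order = rng.permutation(len(Xtr))
            for lo in range(0, len(Xtr), batch):
                idx = order[lo : lo + batch]
                xb, yb = Xtr[idx], ytr[idx]
                grads = self._backward(xb, yb, onehot)
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g * g - vi)
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            tr_loss, tr_acc = self._evaluate(Xtr, ytr)
            hist["loss"].append(tr_loss)
            hist["accuracy"].append(tr_acc)
            if len(Xval):
                va_loss, va_acc = self._evaluate(Xval, yval)
            else:
                va_loss, va_acc = float("nan"), float("nan")
            hist["val_loss"].append(va_loss)
            hist["val_accuracy"].append(va_acc)
        self.history = hist
        return hist

    def _backward(self, X: np.ndarray, y: np.ndarray, onehot: np.ndarray):
        Z, A, flat, D, P = self._forward(X)
        n = X.shape[0]
        dlogits = (P - onehot[y]) / n
        gWo = D.T @ dlogits
        gbo = dlogits.sum(axis=0)
        dD = dlogits @ self.Wo.T
        gWd = flat.T @ dD
        gbd = dD.sum(axis=0)
        dflat = dD @ self.Wd.T
        dA = dflat.reshape(A.shape)
        dZ = dA * (Z > 0)
        gWc = np.einsum("npc,npf->cf", X, dZ)
        gbc = dZ.sum(axis=(0, 1))
        return [gWc, gbc, gWd, gbd, gWo, gbo]

    def _evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        P = self._forward(X)[4]
        loss = float(-np.log(np.clip(P[np.arange(len(y)), y], 1e-12, None)).mean())
        acc = float((np.argmax(P, axis=1) == y).mean())
        return loss, acc


def build_model(config: CNNConfig, n_positions: int = 6, n_channels: int = 8) -> ChannelwiseCNN:
    """Construct an untrained model (weights initialized from the seed)."""
    return ChannelwiseCNN(config, n_positions, n_channels)


def train(
    model: ChannelwiseCNN, X: np.ndarray, y: np.ndarray
) -> ChannelwiseCNN:
    """Fit in place and return the model (keeps the pipeline fluent).

    ``X`` may be (n, 8, 6) channel-major feature matrices; they are
    transposed to the (n, positions, channels) layout the network uses.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3 and X.shape[1:] == (model.n_channels, model.n_positions):
        X = X.transpose(0, 2, 1)
    model.fit(X, y)
    return model


def predict(model: ChannelwiseCNN, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, labels) for channel-major or position-major input."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 3 and X.shape[1:] == (model.n_channels, model.n_positions):
        X = X.transpose(0, 2, 1)
    proba = model.predict_proba(X)
    return proba, np.argmax(proba, axis=1)
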