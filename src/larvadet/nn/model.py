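"""Sequential model with a fused sigmoid + binary-cross-entropy head.

The loss is evaluated from the final pre-activation (logits) as
``mean(softplus(z) - y*z)``, and the backward pass starts from the exact
logit gradient ``(sigmoid(z) - y) / batch``, so training never divides by
a saturated sigmoid.  All randomness (weight init, shuffling, dropout) is
seeded; two fits with identical data, configuration and seed are
bit-identical.
"""

from __future__ import annotations

import time

import numpy as np

from ..exceptions import ConfigurationError, InputError
from .layers import Dense, Dropout, Layer
from .optim import Optimizer, get_optimizer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.built = False
        last = layers[-1]
        self._bce_head = isinstance(last, Dense) and last.activation == "sigmoid"
        # first trainable conv does not need an input gradient
        for lyr in layers:
            if hasattr(lyr, "first_layer"):
                lyr.first_layer = False
        if layers and hasattr(layers[0], "first_layer"):
            layers[0].first_layer = True

    # -- construction -----------------------------------------------------

    def build(self, input_shape: tuple, seed: int = 0, dtype=np.float32) -> "Sequential":
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype).type
        shape = tuple(input_shape)
        for lyr in self.layers:
            lyr.dtype = self.dtype
            shape = lyr.build(shape, rng)
        self.input_shape = tuple(input_shape)
        self.built = True
        return self

    def logical_rows(self, input_shape: tuple | None = None) -> list[tuple[str, tuple]]:
        """Layer-by-layer rows (name, output shape), one per tabulated layer."""
        shape = tuple(input_shape or self.input_shape)
        rows = []
        for lyr in self.layers:
            lrows = lyr.logical_shapes(shape)
            rows.extend(lrows)
            shape = lrows[-1][1]
        return rows

    @property
    def layer_count(self) -> int:
        return len(self.logical_rows())

    def n_params(self) -> int:
        return sum(p.size for lyr in self.layers for p, _ in lyr.params_and_grads())

    # -- inference --------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = x
        for lyr in self.layers:
            out = lyr.forward(out, training)
        return out

    def predict_proba(self, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
        if not self.built:
            raise ConfigurationError("model is not built")
        probs = []
        for i in range(0, len(X), batch_size):
            probs.append(self.forward(np.asarray(X[i : i + batch_size], self.dtype)))
        return np.concatenate(probs).ravel()

    def evaluate(self, X: np.ndarray, y: np.ndarray, batch_size: int = 32) -> tuple[float, float]:
        """(binary cross-entropy, accuracy at threshold 0.5)."""
        losses, correct, n = 0.0, 0, len(X)
        yv = np.asarray(y, np.float32).ravel()
        for i in range(0, n, batch_size):
            xb = np.asarray(X[i : i + batch_size], self.dtype)
            yb = yv[i : i + batch_size]
            self.forward(xb)
            z = self.layers[-1].z.ravel() if self._bce_head else None
            if z is not None:
                losses += float(np.sum(np.logaddexp(0.0, z) - yb * z))
                correct += int(np.sum((z > 0) == (yb > 0.5)))
            else:
                raise ConfigurationError("evaluate requires a sigmoid output head")
        return losses / n, correct / n

    # -- training ---------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        optimizer: str | Optimizer = "adam",
        lr: float = 1e-3,
        seed: int = 0,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        shuffle: bool = True,
        verbose: bool = False,
    ) -> dict:
        """Train with mini-batch gradient descent on binary cross-entropy.

        Returns a history dict with per-epoch train/validation accuracy and
        loss, the wall-clock ``training_seconds`` and a ``diverged`` flag.
        A non-finite epoch loss stops training early (the divergence is
        recorded, not raised).
        """
        if not self._bce_head:
            raise ConfigurationError("fit requires a Dense(1, sigmoid) output head")
        if len(X) != len(y) or len(X) == 0:
            raise InputError("X and y must be non-empty and the same length")
        opt = get_optimizer(optimizer, lr) if isinstance(optimizer, str) else optimizer
        rng = np.random.default_rng(seed)
        for lyr in self.layers:
            if isinstance(lyr, Dropout):
                lyr.rng = np.random.default_rng(rng.integers(2**31 - 1))
        yv = np.asarray(y, np.float32).ravel()
        n = len(X)
        history = {"epoch": [], "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
        diverged = False
        t0 = time.perf_counter()
        for epoch in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            ep_loss, ep_correct = 0.0, 0
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb = np.asarray(X[idx], self.dtype)
                yb = yv[idx]
                p = self.forward(xb, training=True).ravel()
                z = self.layers[-1].z.ravel()
                ep_loss += float(np.sum(np.logaddexp(0.0, z) - yb * z))
                ep_correct += int(np.sum((z > 0) == (yb > 0.5)))
                delta = ((p - yb) / len(idx)).astype(self.dtype).reshape(-1, 1)
                g = delta
                for li in range(len(self.layers) - 1, -1, -1):
                    g = self.layers[li].backward(g, pre=(li == len(self.layers) - 1))
                opt.step([pg for lyr in self.layers for pg in lyr.params_and_grads()])
            train_loss = ep_loss / n
            train_acc = ep_correct / n
            if validation_data is not None and np.isfinite(train_loss):
                val_loss, val_acc = self.evaluate(*validation_data, batch_size=batch_size)
            else:
                val_loss, val_acc = float("nan"), float("nan")
            history["epoch"].append(epoch + 1)
            history["train_loss"].append(train_loss)
            history["train_acc"].append(train_acc)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if verbose:
                print(
                    f"epoch {epoch + 1}/{epochs} loss {train_loss:.4f} acc {train_acc:.3f}"
                    + (f" val_loss {val_loss:.4f} val_acc {val_acc:.3f}"
                       if validation_data else "")
                )
            if not np.isfinite(train_loss):
                diverged = True
                break
        history["training_seconds"] = time.perf_counter() - t0
        history["diverged"] = diverged
        return history
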