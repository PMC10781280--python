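"""Optimizers: Adam, plain SGD and RMSprop, over (param, grad) pairs.

The Adam update for large tensors runs through a fused numba kernel (one
pass over parameter, gradient and moment arrays); with tens of millions of
dense-layer parameters the update is bandwidth-bound, and the fused form
avoids re-reading the arrays once per elementwise operation.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError

try:  # fused kernels; numpy fallback keeps results equivalent
    import numba

    @numba.njit(fastmath=True)
    def _adam_fused(p, g, m, v, b1, b2, lr_t, eps_t):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps_t)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class Optimizer:
    def __init__(self, lr: float):
        self.lr = float(lr)
        self.state: dict[int, dict] = {}
        self.t = 0

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(params_and_grads):
            self._update(i, p, g)

    def _update(self, i: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, lr: float, momentum: float = 0.0):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, i, p, g):
        if self.momentum:
            if i not in self.state:
                self.state[i] = {"v": np.zeros_like(p)}
            v = self.state[i]["v"]
            v *= self.momentum
            v -= self.lr * g
            p += v
        else:
            p -= self.lr * g


class RMSprop(Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, i, p, g):
        if i not in self.state:
            self.state[i] = {"s": np.zeros_like(p), "t1": np.empty_like(p)}
        st = self.state[i]
        s, t1 = st["s"], st["t1"]
        s *= self.rho
        np.multiply(g, g, out=t1)
        t1 *= 1.0 - self.rho
        s += t1
        np.sqrt(s, out=t1)
        t1 += self.eps
        np.divide(g, t1, out=t1)
        t1 *= self.lr
        p -= t1


class Adam(Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, i, p, g):
        # epsilon-hat formulation: bias corrections folded into the step size
        if i not in self.state:
            self.state[i] = {"m": np.zeros_like(p), "v": np.zeros_like(p)}
        st = self.state[i]
        m, v = st["m"], st["v"]
        bc2 = np.sqrt(1.0 - self.beta2**self.t)
        lr_t = self.lr * bc2 / (1.0 - self.beta1**self.t)
        eps_t = self.eps * bc2
        if _HAVE_NUMBA and p.size >= 4096 and p.flags.c_contiguous and g.flags.c_contiguous:
            _adam_fused(p.ravel(), g.ravel(), m.ravel(), v.ravel(),
                        p.dtype.type(self.beta1), p.dtype.type(self.beta2),
                        p.dtype.type(lr_t), p.dtype.type(eps_t))
            return
        m *= self.beta1
        m += (1.0 - self.beta1) * g
        v *= self.beta2
        v += (1.0 - self.beta2) * g * g
        p -= lr_t * m / (np.sqrt(v) + eps_t)


def get_optimizer(name: str, lr: float) -> Optimizer:
    table = {"adam": Adam, "sgd": SGD, "rmsprop": RMSprop}
    key = name.lower()
    if key not in table:
        raise ConfigurationError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[key](lr)
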