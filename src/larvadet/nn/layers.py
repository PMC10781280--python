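"""Layers: valid conv (optionally fused with ReLU + 2x2 max-pool), dense,
dropout, flatten and a standalone max-pool.

Array layout is channels-last, float32.  Each layer reports its logical
rows via ``logical_shapes`` — a fused Conv2D-with-pool reports two rows
(Conv2D, MaxPooling), matching how such architectures are conventionally
tabulated layer by layer.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ConfigurationError, InputError


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, out=x)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Minimal layer protocol; see concrete subclasses."""

    trainable = False
    dtype = np.float32  # overridden by Sequential.build

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        raise NotImplementedError

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray, pre: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params_and_grads(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []

    def logical_shapes(self, input_shape: tuple) -> list[tuple[str, tuple]]:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, buf: np.ndarray) -> np.ndarray:
    """Sliding 3x3 (or kxk) patches of one image as a (oh*ow, k*k*C) matrix.

    Built from k*k contiguous slice copies, which is far cheaper on a
    bandwidth-limited machine than a generic strided gather.
    """
    H, W, C = x.shape
    oh, ow = H - k + 1, W - k + 1
    v = buf.reshape(oh, ow, k * k * C)
    idx = 0
    for ki in range(k):
        for kj in range(k):
            v[:, :, idx * C : (idx + 1) * C] = x[ki : ki + oh, kj : kj + ow]
            idx += 1
    return buf.reshape(oh * ow, k * k * C)


class Conv2D(Layer):
    """Unpadded kxk convolution + activation, optionally fused 2x2 max-pool.

    ``pool=2`` appends a 2x2, stride-2 max-pool (odd trailing rows/columns
    dropped).  ReLU commutes with max, so pooling is applied to the
    pre-activation and ReLU to the pooled map; gradients are routed back
    through the pooled argmax.  The backward pass recomputes the im2col
    matrix from the stored layer input instead of caching it, trading a
    little arithmetic for a large cut in memory traffic.
    """

    trainable = True

    def __init__(self, filters: int, kernel: int = 3, activation: str | None = "relu",
                 pool: int | None = None):
        if activation not in (None, "relu"):
            raise ConfigurationError(f"Conv2D supports relu/None, got {activation!r}")
        if pool not in (None, 2):
            raise ConfigurationError("Conv2D pool fusion supports pool=2 only")
        self.filters = int(filters)
        self.kernel = int(kernel)
        self.activation = activation
        self.pool = pool
        self.first_layer = False  # set by Sequential; skips dx when True

    def build(self, input_shape, rng):
        H, W, C = input_shape
        k = self.kernel
        oh, ow = H - k + 1, W - k + 1
        if oh < 1 or ow < 1:
            raise ConfigurationError(f"conv input {H}x{W} too small for kernel {k}")
        self.in_channels = C
        fan_in, fan_out = k * k * C, k * k * self.filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, size=(k * k * C, self.filters)).astype(self.dtype)
        self.b = np.zeros(self.filters, dtype=self.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.conv_shape = (oh, ow, self.filters)
        if self.pool:
            ph, pw = oh // 2, ow // 2
            if ph < 1 or pw < 1:
                raise ConfigurationError(f"conv output {oh}x{ow} too small to pool")
            self.out_shape = (ph, pw, self.filters)
        else:
            self.out_shape = self.conv_shape
        self._cols = None
        return self.out_shape

    def logical_shapes(self, input_shape):
        H, W, C = input_shape
        k = self.kernel
        oh, ow = H - k + 1, W - k + 1
        rows = [("Conv2D", (oh, ow, self.filters))]
        if self.pool:
            rows.append(("MaxPooling", (oh // 2, ow // 2, self.filters)))
        return rows

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _scatter_base(self, ph, pw, ow, F):
        # linear index of pooled cell (2i, 2j, f) in the (oh, ow, F) grid
        key = (ph, pw, ow, F)
        if getattr(self, "_sbase_key", None) != key:
            i = np.arange(ph)[:, None, None]
            j = np.arange(pw)[None, :, None]
            f = np.arange(F)[None, None, :]
            self._sbase = ((2 * i) * ow + 2 * j) * F + f
            self._sbase_key = key
        return self._sbase

    def _col_buf(self, H, W):
        k = self.kernel
        oh, ow = H - k + 1, W - k + 1
        n = oh * ow * k * k * self.in_channels
        if self._cols is None or self._cols.size != n or self._cols.dtype != self.dtype:
            self._cols = np.empty(n, dtype=self.dtype)
        return self._cols

    def forward(self, x, training):
        N, H, W, C = x.shape
        k = self.kernel
        oh, ow, F = self.conv_shape
        self.x = x
        out = np.empty((N,) + self.out_shape, dtype=self.dtype)
        buf = self._col_buf(H, W)
        if self.pool:
            ph, pw = self.out_shape[:2]
            self.amax = np.empty((N, ph, pw, F), dtype=np.uint8)
            self.mask = np.empty((N, ph, pw, F), dtype=bool)
        else:
            self.mask = np.empty((N, oh, ow, F), dtype=bool)
        zbuf = np.empty((oh * ow, F), dtype=self.dtype)
        for n in range(N):
            cols = _im2col(x[n], k, buf)
            np.dot(cols, self.W, out=zbuf)
            z = zbuf.reshape(oh, ow, F)
            if self.pool:
                ph, pw = self.out_shape[:2]
                # two-stage max: rows first, then columns; the bias is
                # added after pooling (max(z) + b == max(z + b) per filter)
                r0, r1 = z[0 : ph * 2 : 2], z[1 : ph * 2 : 2]
                rw = r1 > r0  # row-offset bit of the argmax
                zr = np.maximum(r0, r1)
                zc0, zc1 = zr[:, 0 : pw * 2 : 2], zr[:, 1 : pw * 2 : 2]
                cw = zc1 > zc0  # column-offset bit
                zp = np.maximum(zc0, zc1)
                zp += self.b
                code = np.where(
                    cw, rw[:, 1 : pw * 2 : 2], rw[:, 0 : pw * 2 : 2]
                ).astype(np.uint8)
                code <<= 1
                code += cw
                self.amax[n] = code
                if self.activation == "relu":
                    self.mask[n] = zp > 0
                    out[n] = np.maximum(zp, 0.0)
                else:
                    self.mask[n] = True
                    out[n] = zp
            else:
                z += self.b
                if self.activation == "relu":
                    self.mask[n] = z > 0
                    out[n] = np.maximum(z, 0.0)
                else:
                    self.mask[n] = True
                    out[n] = z
        return out

    def _wflip(self):
        k, C, F = self.kernel, self.in_channels, self.filters
        w = self.W.reshape(k, k, C, F)[::-1, ::-1]  # spatial flip
        return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(k * k * F, C)

    def backward(self, g, pre=False):
        x = self.x
        N, H, W, C = x.shape
        k = self.kernel
        oh, ow, F = self.conv_shape
        self.dW[:] = 0.0
        self.db[:] = 0.0
        need_dx = not self.first_layer
        dx = np.empty_like(x) if need_dx else None
        wflip = self._wflip() if need_dx else None
        buf = self._col_buf(H, W)
        gz = np.zeros((oh, ow, F), dtype=self.dtype)
        if need_dx:
            pad = np.zeros((oh + 2 * (k - 1), ow + 2 * (k - 1), F), dtype=self.dtype)
            pbuf = np.empty(H * W * k * k * F, dtype=self.dtype)
        for n in range(N):
            if self.pool:
                ph, pw = self.out_shape[:2]
                gp = g[n] * self.mask[n]
                gz[:] = 0.0
                code = self.amax[n].astype(np.int64)
                # scatter gp to its argmax positions via linear indices
                lin = self._scatter_base(ph, pw, ow, F)
                lin = lin + (code >> 1) * (ow * F) + (code & 1) * F
                gz.reshape(-1)[lin.reshape(-1)] = gp.reshape(-1)
                self.db += gp.sum(axis=(0, 1))
            else:
                gz = g[n] * self.mask[n]
                self.db += gz.sum(axis=(0, 1))
            gflat = gz.reshape(oh * ow, F)
            cols = _im2col(x[n], k, buf)
            self.dW += cols.T @ gflat
            if need_dx:
                pad[k - 1 : k - 1 + oh, k - 1 : k - 1 + ow] = gz
                pcols = _im2colF(pad, k, pbuf, F)
                np.dot(pcols, wflip, out=dx[n].reshape(H * W, C))
        return dx

    # expose pooled/unpooled output shape for analytic checks
    @property
    def output_shape(self):
        return self.out_shape


def _im2colF(x: np.ndarray, k: int, buf: np.ndarray, C: int) -> np.ndarray:
    H, W, _ = x.shape
    oh, ow = H - k + 1, W - k + 1
    v = buf[: oh * ow * k * k * C].reshape(oh, ow, k * k * C)
    idx = 0
    for ki in range(k):
        for kj in range(k):
            v[:, :, idx * C : (idx + 1) * C] = x[ki : ki + oh, kj : kj + ow]
            idx += 1
    return v.reshape(oh * ow, k * k * C)


class MaxPool2D(Layer):
    """Standalone 2x2, stride-2 max-pool (odd trailing rows/columns dropped)."""

    def __init__(self, size: int = 2):
        if size != 2:
            raise ConfigurationError("MaxPool2D supports size=2")
        self.size = size

    def build(self, input_shape, rng):
        H, W, C = input_shape
        if H < 2 or W < 2:
            raise ConfigurationError(f"pool input {H}x{W} too small")
        self.out_shape = (H // 2, W // 2, C)
        return self.out_shape

    def logical_shapes(self, input_shape):
        H, W, C = input_shape
        return [("MaxPooling", (H // 2, W // 2, C))]

    def forward(self, x, training):
        N, H, W, C = x.shape
        h, w = H // 2, W // 2
        self.in_shape = x.shape
        v = x[:, : h * 2, : w * 2].reshape(N, h, 2, w, 2, C)
        cand = np.stack((v[:, :, 0, :, 0], v[:, :, 0, :, 1], v[:, :, 1, :, 0], v[:, :, 1, :, 1]),
                        axis=-1)
        self.code = cand.argmax(axis=-1)
        return np.take_along_axis(cand, self.code[..., None], axis=-1)[..., 0]

    def backward(self, g, pre=False):
        N, H, W, C = self.in_shape
        h, w = H // 2, W // 2
        dx = np.zeros(self.in_shape, dtype=self.dtype)
        for a in range(2):
            for b in range(2):
                sel = self.code == (a * 2 + b)
                dx[:, a : h * 2 : 2, b : w * 2 : 2][sel] = g[sel]
        return dx


class Flatten(Layer):
    def build(self, input_shape, rng):
        self.in_shape = input_shape
        n = int(np.prod(input_shape))
        self.out_shape = (n,)
        return self.out_shape

    def logical_shapes(self, input_shape):
        return [("Flatten", (int(np.prod(input_shape)),))]

    def forward(self, x, training):
        self.n = x.shape[0]
        return x.reshape(self.n, -1)

    def backward(self, g, pre=False):
        return g.reshape((self.n,) + self.in_shape)


class Dense(Layer):
    """Fully connected layer with optional relu/sigmoid activation.

    ``backward(..., pre=True)`` accepts a gradient already taken with
    respect to the pre-activation (used by the fused sigmoid + binary
    cross-entropy head for numerical stability).
    """

    trainable = True

    def __init__(self, units: int, activation: str | None = None):
        if activation not in (None, "relu", "sigmoid"):
            raise ConfigurationError(f"unsupported activation {activation!r}")
        self.units = int(units)
        self.activation = activation

    def build(self, input_shape, rng):
        (n_in,) = input_shape
        limit = np.sqrt(6.0 / (n_in + self.units))
        self.W = rng.uniform(-limit, limit, size=(n_in, self.units)).astype(self.dtype)
        self.b = np.zeros(self.units, dtype=self.dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.out_shape = (self.units,)
        return self.out_shape

    def logical_shapes(self, input_shape):
        return [("Dense", (self.units,))]

    def params_and_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training):
        self.x = x
        self.z = x @ self.W + self.b
        if self.activation == "relu":
            return np.maximum(self.z, 0.0)
        if self.activation == "sigmoid":
            self.p = _sigmoid(self.z)
            return self.p
        return self.z

    def backward(self, g, pre=False):
        if pre or self.activation is None:
            gz = g
        elif self.activation == "relu":
            gz = g * (self.z > 0)
        else:  # sigmoid
            gz = g * self.p * (1.0 - self.p)
        gz = gz.astype(self.dtype, copy=False)
        np.dot(self.x.T, gz, out=self.dW)
        np.sum(gz, axis=0, out=self.db)
        return gz @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)  # reseeded by Sequential.fit

    def build(self, input_shape, rng):
        self.out_shape = input_shape
        return input_shape

    def logical_shapes(self, input_shape):
        return [("Dropout", input_shape)]

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(self.dtype) / keep
        return x * self.mask

    def backward(self, g, pre=False):
        if self.mask is None:
            return g
        return g * self.mask
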