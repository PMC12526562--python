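"""Minimal 3D convolutional network layers with explicit backpropagation.

The segmentation network is small and static, so rather than a general
autodiff graph each layer implements ``forward``/``backward`` analytically,
with 3x3x3 convolutions lowered to im2col + BLAS matrix products.  Arrays
are channel-first ``(C, X, Y, Z)`` float32 throughout.  Layers cache
activations only when ``training=True``; inference is cache-free.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def num_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


def _im2col3(x):
    """(C, D, H, W) -> (C*27, D*H*W) patch matrix for a same-padded 3^3 conv.

    Built as 27 shifted-slice copies, which is far cheaper than gathering a
    7D sliding-window view.  Row order is (channel, kernel offset), matching
    ``weight.reshape(c_out, c_in * 27)``.
    """
    c, d, h, w = x.shape
    n = d * h * w
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((c, 27, n), dtype=x.dtype)
    k = 0
    for a in range(3):
        for b in range(3):
            for cc in range(3):
                cols[:, k, :] = xp[:, a:a + d, b:b + h, cc:cc + w].reshape(c, n)
                k += 1
    return cols.reshape(c * 27, n)


class Conv3d(Module):
    """Same-padded stride-1 convolution, kernel size 1 or 3."""

    def __init__(self, c_in, c_out, kernel=3, bias=True, name="conv"):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.weight = Param(f"{name}.w", np.zeros((c_out, c_in) + (kernel,) * 3))
        self.bias = Param(f"{name}.b", np.zeros(c_out)) if bias else None
        self._cache = None

    def init(self, rng):
        fan_in = self.c_in * self.kernel ** 3
        self.weight.value = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=self.weight.value.shape).astype(F32)
        if self.bias is not None:
            self.bias.value[:] = 0

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        spatial = x.shape[1:]
        if self.kernel == 1:
            wmat = self.weight.value.reshape(self.c_out, self.c_in)
            y = wmat @ x.reshape(self.c_in, -1)
            if training:
                self._cache = (x.reshape(self.c_in, -1), spatial)
        else:
            cols = _im2col3(x)
            wmat = self.weight.value.reshape(self.c_out, -1)
            y = wmat @ cols
            if training:
                self._cache = (cols, spatial)
        if self.bias is not None:
            y += self.bias.value[:, None]
        return y.reshape((self.c_out,) + spatial)

    def backward(self, dy):
        cache, spatial = self._cache
        dyf = dy.reshape(self.c_out, -1)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=1)
        if self.kernel == 1:
            xf = cache
            self.weight.grad += (dyf @ xf.T).reshape(self.weight.value.shape)
            wmat = self.weight.value.reshape(self.c_out, self.c_in)
            dx = wmat.T @ dyf
        else:
            cols = cache
            self.weight.grad += (dyf @ cols.T).reshape(self.weight.value.shape)
            # full correlation with the flipped kernel gives dx for stride-1
            wrot = self.weight.value[:, :, ::-1, ::-1, ::-1]
            w2 = np.ascontiguousarray(wrot.transpose(1, 0, 2, 3, 4)).reshape(self.c_in, -1)
            cols_dy = _im2col3(dy)
            dx = w2 @ cols_dy
        self._cache = None
        return dx.reshape((self.c_in,) + spatial)


class ConvTranspose3d(Module):
    """Learned stride-2 upsampling with a 2x2x2 kernel (non-overlapping)."""

    def __init__(self, c_in, c_out, bias=True, name="up"):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(f"{name}.w", np.zeros((c_in, c_out, 2, 2, 2)))
        self.bias = Param(f"{name}.b", np.zeros(c_out)) if bias else None
        self._cache = None

    def init(self, rng):
        self.weight.value = rng.normal(
            0.0, np.sqrt(2.0 / self.c_in), size=self.weight.value.shape).astype(F32)
        if self.bias is not None:
            self.bias.value[:] = 0

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        d, h, w = x.shape[1:]
        t = np.tensordot(x, self.weight.value, axes=([0], [0]))  # (D,H,W,O,2,2,2)
        y = np.ascontiguousarray(t.transpose(3, 0, 4, 1, 5, 2, 6)).reshape(
            self.c_out, 2 * d, 2 * h, 2 * w)
        if self.bias is not None:
            y += self.bias.value[:, None, None, None]
        if training:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        d, h, w = x.shape[1:]
        r = dy.reshape(self.c_out, d, 2, h, 2, w, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(1, 2, 3))
        self.weight.grad += np.tensordot(x, r, axes=([1, 2, 3], [0, 1, 2]))
        dx = np.tensordot(r, self.weight.value, axes=([3, 4, 5, 6], [1, 2, 3, 4]))
        self._cache = None
        return np.ascontiguousarray(dx.transpose(3, 0, 1, 2))


class MaxPool3dStride2(Module):
    """2x2x2 stride-2 downsampling; input spatial dims must be even."""

    def forward(self, x, training=False):
        c, d, h, w = x.shape
        r = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = np.ascontiguousarray(r.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            c, d // 2, h // 2, w // 2, 8)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, shape = self._cache
        c, d, h, w = shape
        dr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=F32)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        dr = dr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        self._cache = None
        return np.ascontiguousarray(dr).reshape(shape)


class MaxPool3dSame(Module):
    """3x3x3 stride-1 max pool with same padding (inception side branch).

    The maximum is computed with three separable 1D max filters.  The
    gradient of a tied maximum is split equally among the tied positions
    (the usual subgradient choice); away from ties this equals routing to
    the argmax.
    """

    def forward(self, x, training=False):
        from scipy.ndimage import maximum_filter1d
        stages = []
        y = x
        for axis in (1, 2, 3):
            z = maximum_filter1d(y, size=3, axis=axis, mode="constant",
                                 cval=-np.inf).astype(x.dtype)
            if training:
                stages.append((y, z, axis))
            y = z
        if training:
            self._cache = stages
        return y

    @staticmethod
    def _backward_1d(dy, x, y, axis):
        pad = [(0, 0)] * 4
        pad[axis] = (1, 1)
        n = x.shape[axis]
        xpad = np.pad(x, pad, constant_values=-np.inf)
        sl = [slice(None)] * 4

        def shifted(arr, a):
            s = list(sl)
            s[axis] = slice(a, a + n)
            return arr[tuple(s)]

        wcnt = np.zeros(y.shape, dtype=F32)
        for a in range(3):
            wcnt += y == shifted(xpad, a)
        share = np.pad(dy / wcnt, pad)
        ypad = np.pad(y, pad, constant_values=np.inf)
        dx = np.zeros(x.shape, dtype=F32)
        for a in range(3):
            dx += shifted(share, a) * (x == shifted(ypad, a))
        return dx

    def backward(self, dy):
        stages = self._cache
        self._cache = None
        for x, y, axis in reversed(stages):
            dy = self._backward_1d(dy, x, y, axis)
        return dy


class InstanceNorm(Module):
    """Per-channel normalization over the spatial axes of one sample."""

    def __init__(self, channels, affine=True, eps=1e-5, name="inorm"):
        self.channels, self.eps = channels, eps
        self.gamma = Param(f"{name}.g", np.ones(channels)) if affine else None
        self.beta = Param(f"{name}.b", np.zeros(channels)) if affine else None

    def init(self, rng):
        if self.gamma is not None:
            self.gamma.value[:] = 1
            self.beta.value[:] = 0

    def params(self):
        return [] if self.gamma is None else [self.gamma, self.beta]

    def forward(self, x, training=False):
        c = x.shape[0]
        xf = x.reshape(c, -1)
        mu = xf.mean(axis=1, keepdims=True)
        var = xf.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xf - mu) * inv
        y = xhat if self.gamma is None else self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return y.reshape(x.shape).astype(F32)

    def backward(self, dy):
        xhat, inv, shape = self._cache
        c = shape[0]
        dyf = dy.reshape(c, -1)
        if self.gamma is not None:
            self.gamma.grad += (dyf * xhat).sum(axis=1)
            self.beta.grad += dyf.sum(axis=1)
            dxhat = dyf * self.gamma.value[:, None]
        else:
            dxhat = dyf
        n = xhat.shape[1]
        dx = (inv / n) * (n * dxhat - dxhat.sum(axis=1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=1, keepdims=True))
        self._cache = None
        return dx.reshape(shape).astype(F32)


class ReLU(Module):
    def forward(self, x, training=False):
        y = np.maximum(x, 0)
        if training:
            self._cache = x > 0
        return y

    def backward(self, dy):
        mask = self._cache
        self._cache = None
        return dy * mask


class Sigmoid(Module):
    def forward(self, x, training=False):
        from scipy.special import expit
        y = expit(x)
        if training:
            self._cache = y
        return y

    def backward(self, dy):
        y = self._cache
        self._cache = None
        return dy * y * (1.0 - y)


class Dropout(Module):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate):
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._cache = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate).astype(F32) / (1.0 - self.rate)
        self._cache = mask
        return x * mask

    def backward(self, dy):
        mask = self._cache
        self._cache = None
        return dy if mask is None else dy * mask


class Dense(Module):
    def __init__(self, n_in, n_out, bias=True, name="fc"):
        self.n_in, self.n_out = n_in, n_out
        self.weight = Param(f"{name}.w", np.zeros((n_out, n_in)))
        self.bias = Param(f"{name}.b", np.zeros(n_out)) if bias else None

    def init(self, rng):
        self.weight.value = rng.normal(
            0.0, np.sqrt(2.0 / self.n_in), size=(self.n_out, self.n_in)).astype(F32)
        if self.bias is not None:
            self.bias.value[:] = 0

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        if training:
            self._cache = x
        y = self.weight.value @ x
        return y + self.bias.value if self.bias is not None else y

    def backward(self, dy):
        x = self._cache
        self._cache = None
        self.weight.grad += np.outer(dy, x)
        if self.bias is not None:
            self.bias.grad += dy
        return self.weight.value.T @ dy


class Softmax(Module):
    """Channel-wise softmax over a (C, D, H, W) lattice."""

    def forward(self, x, training=False):
        z = x - x.max(axis=0, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=0, keepdims=True)
        if training:
            self._cache = p
        return p

    def backward(self, dp):
        p = self._cache
        self._cache = None
        return p * (dp - (dp * p).sum(axis=0, keepdims=True))


class Adam:
    """Adam with the standard moment defaults and bias correction."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
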