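"""Minimal numpy neural-network core: 3D convolution, pooling, batch
normalization, dropout, linear layers, and Adam.

All layers share a tiny protocol: ``forward(x, training=..., rng=...)``,
``backward(dout) -> dx``, and ``params() -> list[Param]``.  Gradients are
hand-written and verified against central finite differences in the test
suite (run the checks in float64; float32 is the default compute dtype).

Convolution uses a shift-and-GEMM scheme: for each kernel offset the input
is sliced (a nearly-contiguous copy) and the whole batch is reduced with one
BLAS matmul.  The per-offset slices are cached during training forwards so
the weight gradient is a single GEMM against the cached column tensor.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _sfft

__all__ = [
    "Param",
    "Conv3d",
    "MaxPool3d",
    "BatchNorm3d",
    "BatchNorm1d",
    "LeakyReLU",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "uniform_fan_in_init",
]

DEFAULT_DTYPE = np.float32


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def uniform_fan_in_init(shape, fan_in: int, rng: np.random.Generator, dtype=DEFAULT_DTYPE) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax (max subtraction along the softmax axis)."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over a batch of two-or-more-class logits.

    Parameters
    ----------
    logits : (B, n_classes) array
    targets : (B,) integer class indices

    Returns
    -------
    loss : float
    dlogits : (B, n_classes) gradient of the mean loss
    """
    b = logits.shape[0]
    p = softmax(logits.astype(np.float64), axis=1)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(b), targets] + eps))
    d = p
    d[np.arange(b), targets] -= 1.0
    d /= b
    return float(loss), d.astype(logits.dtype)


class _Layer:
    def params(self):
        return []

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


_PHASE_CACHE: dict = {}


def _flip_phase(fft_shape, support, dtype):
    """Per-frequency phase factors mapping FFT(x) to FFT of the spatially
    flipped x, for a real x supported on ``support`` and padded to ``fft_shape``:
    FFT(flip(x)) = phase * conj(FFT(x)).
    """
    key = (fft_shape, support, np.dtype(dtype).name)
    p = _PHASE_CACHE.get(key)
    if p is None:
        l0, l1, l2 = fft_shape
        f0 = np.arange(l0)
        f1 = np.arange(l1)
        f2 = np.arange(l2 // 2 + 1)  # rfft half-spectrum on the last axis
        s0, s1, s2 = support
        p0 = np.exp(-2j * np.pi * f0 * (s0 - 1) / l0)
        p1 = np.exp(-2j * np.pi * f1 * (s1 - 1) / l1)
        p2 = np.exp(-2j * np.pi * f2 * (s2 - 1) / l2)
        p = (p0[:, None, None] * p1[None, :, None] * p2[None, None, :]).astype(dtype)
        _PHASE_CACHE[key] = p
    return p


def _freq_contract(A, Bm):
    """Per-frequency matrix contraction sum_c A[x, c, f] * B[y, c, f] -> (x, y, f).

    A: (X, C, *F) complex, Bm: (Y, C, *F) complex.
    """
    X, C = A.shape[0], A.shape[1]
    Y = Bm.shape[0]
    fshape = A.shape[2:]
    Fn = int(np.prod(fshape))
    At = np.ascontiguousarray(A.reshape(X, C, Fn).transpose(2, 0, 1))   # (F, X, C)
    Bt = np.ascontiguousarray(Bm.reshape(Y, C, Fn).transpose(2, 1, 0))  # (F, C, Y)
    R = np.matmul(At, Bt)                                               # (F, X, Y)
    return np.ascontiguousarray(R.transpose(1, 2, 0)).reshape(X, Y, *fshape)


class Conv3d(_Layer):
    """3D cross-correlation (conv without kernel flip) with optional stride.

    Weight shape (out_channels, in_channels, k, k, k).  Two compute paths:

    - ``fft``: overlap-free FFT products, used for training — far less memory
      traffic than explicit column matrices at these feature-map sizes.  The
      valid output region is alias-free for FFT lengths >= the input extent.
    - ``gemm``: shift-and-matmul columns, bit-reproducible simple arithmetic,
      used for evaluation paths that demand tight numerical agreement
      (dense/patchwise equivalence is asserted at 1e-5 in float64).

    1x1x1 kernels always take a plain channel-matmul fast path.
    """

    def __init__(self, in_channels, out_channels, kernel, stride=1, pad=0,
                 bias=True, rng=None, dtype=DEFAULT_DTYPE, need_dx=True,
                 method="fft"):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = int(kernel)
        self.stride = int(stride)
        self.pad = int(pad)
        self.need_dx = need_dx
        self.method = method
        fan_in = in_channels * self.k ** 3
        self.W = Param(uniform_fan_in_init(
            (out_channels, in_channels, self.k, self.k, self.k), fan_in, rng, dtype), "conv.W")
        self.b = Param(uniform_fan_in_init((out_channels,), fan_in, rng, dtype), "conv.b") if bias else None
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def out_shape(self, spatial):
        k, s, p = self.k, self.stride, self.pad
        out = tuple((d + 2 * p - k) // s + 1 for d in spatial)
        return out

    def _offsets(self):
        k = self.k
        return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def forward(self, x, training=False, rng=None):
        if self.pad:
            p = self.pad
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        B, C, D, H, W = x.shape
        od = (D - self.k) // self.stride + 1
        oh = (H - self.k) // self.stride + 1
        ow = (W - self.k) // self.stride + 1
        if min(od, oh, ow) < 1:
            raise ValueError(
                f"Conv3d: input spatial {(D, H, W)} too small for kernel {self.k} stride {self.stride}")
        if self.k == 1 and self.stride == 1:
            return self._forward_1x1(x, training)
        if self.method == "fft":
            return self._forward_fft(x, training, (od, oh, ow))
        return self._forward_gemm(x, training, (od, oh, ow))

    def backward(self, dout):
        if self._cache is None:
            raise RuntimeError("Conv3d.backward called without a training-mode forward")
        mode = self._cache[0]
        if mode == "1x1":
            return self._backward_1x1(dout)
        if mode == "fft":
            return self._backward_fft(dout)
        return self._backward_gemm(dout)

    # ---- 1x1x1 fast path -------------------------------------------------
    def _forward_1x1(self, x, training):
        B, C = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        xm = x.reshape(B, C, -1)
        Wm = self.W.data.reshape(self.out_channels, C)
        out = np.matmul(Wm, xm)
        if self.b is not None:
            out += self.b.data[None, :, None]
        if training:
            self._cache = ("1x1", xm, x.shape)
        return out.reshape(B, self.out_channels, *spatial)

    def _backward_1x1(self, dout):
        _, xm, xshape = self._cache
        B = xshape[0]
        dflat = dout.reshape(B, self.out_channels, -1)
        dW = np.matmul(dflat, xm.transpose(0, 2, 1)).sum(axis=0)
        self.W.grad += dW.reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        self._cache = None
        if not self.need_dx:
            return None
        Wm = self.W.data.reshape(self.out_channels, xshape[1])
        dx = np.matmul(Wm.T, dflat)
        return dx.reshape(xshape)

    # ---- GEMM (shift-and-matmul) path ------------------------------------
    def _forward_gemm(self, x, training, oshape):
        B, C = x.shape[0], x.shape[1]
        od, oh, ow = oshape
        M = od * oh * ow
        k3 = self.k ** 3
        s = self.stride
        cols6 = np.empty((B, C, k3, od, oh, ow), dtype=x.dtype)
        for idx, (a, b, c) in enumerate(self._offsets()):
            cols6[:, :, idx] = x[:, :, a:a + s * (od - 1) + 1:s,
                                    b:b + s * (oh - 1) + 1:s,
                                    c:c + s * (ow - 1) + 1:s]
        cols = cols6.reshape(B, C * k3, M)
        Wm = self.W.data.reshape(self.out_channels, C * k3).astype(x.dtype, copy=False)
        out = np.matmul(Wm, cols)
        if self.b is not None:
            out += self.b.data.astype(x.dtype, copy=False)[None, :, None]
        if training:
            self._cache = ("gemm", cols, x.shape, x.dtype, oshape)
        return out.reshape(B, self.out_channels, od, oh, ow)

    def _backward_gemm(self, dout):
        _, cols, xshape, xdtype, (od, oh, ow) = self._cache
        B, C = xshape[0], xshape[1]
        k3 = self.k ** 3
        M = od * oh * ow
        dflat = dout.reshape(B, self.out_channels, M)
        dW = np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0)
        self.W.grad += dW.reshape(self.W.data.shape)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        self._cache = None
        if not self.need_dx:
            return None
        Wm = self.W.data.reshape(self.out_channels, C * k3)
        dcols6 = np.matmul(Wm.T, dflat).reshape(B, C, k3, od, oh, ow)
        dx = np.zeros(xshape, dtype=xdtype)
        s = self.stride
        for idx, (a, b, c) in enumerate(self._offsets()):
            dx[:, :, a:a + s * (od - 1) + 1:s,
                  b:b + s * (oh - 1) + 1:s,
                  c:c + s * (ow - 1) + 1:s] += dcols6[:, :, idx]
        if self.pad:
            p = self.pad
            dx = dx[:, :, p:-p, p:-p, p:-p]
        return dx

    # ---- FFT path --------------------------------------------------------
    @staticmethod
    def _fft_len(spatial):
        return tuple(_sfft.next_fast_len(int(s)) for s in spatial)

    def _forward_fft(self, x, training, oshape):
        B, C = x.shape[0], x.shape[1]
        S = x.shape[2:]
        od, oh, ow = oshape
        L = self._fft_len(S)
        k = self.k
        s = self.stride
        Wd = self.W.data.astype(x.dtype, copy=False)
        Xf = _sfft.rfftn(x, s=L, axes=(2, 3, 4))
        Wf_flip = _sfft.rfftn(Wd[:, :, ::-1, ::-1, ::-1], s=L, axes=(2, 3, 4))
        Yf = _freq_contract(Xf, Wf_flip)  # (B, O, *Lf) -- contraction over channels
        y = _sfft.irfftn(Yf, s=L, axes=(2, 3, 4))
        out = y[:, :, k - 1:k - 1 + s * (od - 1) + 1:s,
                     k - 1:k - 1 + s * (oh - 1) + 1:s,
                     k - 1:k - 1 + s * (ow - 1) + 1:s]
        out = np.ascontiguousarray(out)
        if self.b is not None:
            out += self.b.data.astype(x.dtype, copy=False).reshape(1, -1, 1, 1, 1)
        if training:
            self._cache = ("fft", Xf, x.shape, x.dtype, oshape, L)
        return out

    def _backward_fft(self, dout):
        _, Xf, xshape, xdtype, (od, oh, ow), L = self._cache
        B, C = xshape[0], xshape[1]
        S = xshape[2:]
        k = self.k
        s = self.stride
        dflat = dout.reshape(B, self.out_channels, -1)
        if self.b is not None:
            self.b.grad += dflat.sum(axis=(0, 2))
        # zero-upsample dout onto the stride lattice (no offset):
        #   dW[kv] = sum_n dup[n] x[n + kv]  = conv(flip(x), dup)[S-1-kv]
        #   dx[i]  = sum_n dup[n] W[i - n]   = conv(dup, W)[i]
        # both valid slices are alias-free for FFT length >= input extent
        dup = np.zeros((B, self.out_channels) + tuple(S), dtype=dout.dtype)
        dup[:, :, :s * (od - 1) + 1:s,
               :s * (oh - 1) + 1:s,
               :s * (ow - 1) + 1:s] = dout
        Df = _sfft.rfftn(dup, s=L, axes=(2, 3, 4))
        P = _flip_phase(L, tuple(S), Xf.dtype)
        XfF = P * np.conj(Xf)
        Gf = _freq_contract(np.swapaxes(Df, 0, 1), np.swapaxes(XfF, 0, 1))  # (O, C, *Lf)
        G = _sfft.irfftn(Gf, s=L, axes=(2, 3, 4))
        sl = tuple(slice(Si - k, Si) for Si in S)
        dW = G[(slice(None), slice(None)) + sl][:, :, ::-1, ::-1, ::-1]
        self.W.grad += dW.astype(self.W.grad.dtype, copy=False)
        self._cache = None
        if not self.need_dx:
            return None
        Wd = self.W.data.astype(xdtype, copy=False)
        Wf = _sfft.rfftn(Wd, s=L, axes=(2, 3, 4))
        Hf = _freq_contract(Df, np.swapaxes(Wf, 0, 1))  # (B, C, *Lf), contracted over out-channels
        dxf = _sfft.irfftn(Hf, s=L, axes=(2, 3, 4))
        dx = np.ascontiguousarray(dxf[:, :, :S[0], :S[1], :S[2]]).astype(xdtype, copy=False)
        if self.pad:
            p = self.pad
            dx = dx[:, :, p:-p, p:-p, p:-p]
        return dx


class MaxPool3d(_Layer):
    def __init__(self, kernel, stride, pad=0):
        if pad != 0:
            raise NotImplementedError("padded pooling not needed")
        self.k = int(kernel)
        self.stride = int(stride)
        self._cache = None

    def out_shape(self, spatial):
        return tuple((d - self.k) // self.stride + 1 for d in spatial)

    def forward(self, x, training=False, rng=None):
        B, C, D, H, W = x.shape
        od, oh, ow = self.out_shape((D, H, W))
        if min(od, oh, ow) < 1:
            raise ValueError(f"MaxPool3d: input spatial {(D, H, W)} too small for kernel {self.k}")
        s = self.stride
        out = None
        arg = None
        idx = 0
        for a in range(self.k):
            for b in range(self.k):
                for c in range(self.k):
                    sl = x[:, :, a:a + s * (od - 1) + 1:s,
                             b:b + s * (oh - 1) + 1:s,
                             c:c + s * (ow - 1) + 1:s]
                    if out is None:
                        out = sl.copy()
                        arg = np.zeros(out.shape, dtype=np.int8)
                    else:
                        better = sl > out
                        np.copyto(out, sl, where=better)
                        arg[better] = idx
                    idx += 1
        self._cache = (arg, x.shape, x.dtype, (od, oh, ow))
        return out

    def backward(self, dout):
        arg, xshape, xdtype, (od, oh, ow) = self._cache
        dx = np.zeros(xshape, dtype=xdtype)
        s = self.stride
        idx = 0
        for a in range(self.k):
            for b in range(self.k):
                for c in range(self.k):
                    mask = arg == idx
                    dx[:, :, a:a + s * (od - 1) + 1:s,
                          b:b + s * (oh - 1) + 1:s,
                          c:c + s * (ow - 1) + 1:s] += np.where(mask, dout, 0)
                    idx += 1
        self._cache = None
        return dx


class _BatchNorm(_Layer):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1, dtype=DEFAULT_DTYPE):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(num_features, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(num_features, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _bshape(ndim):
        return (1, -1) + (1,) * (ndim - 2)

    def forward(self, x, training=False, rng=None):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)  # biased, used for normalization
            n = x.size // x.shape[1]
            unbiased = var * n / max(n - 1, 1)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(self.running_var.dtype)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        if training:
            self._cache = (xhat, inv_std, axes, shape)
        return out

    def backward(self, dout):
        xhat, inv_std, axes, shape = self._cache
        n = dout.size // dout.shape[1]
        self.gamma.grad += np.sum(dout * xhat, axis=axes)
        self.beta.grad += np.sum(dout, axis=axes)
        g = self.gamma.data.reshape(shape)
        dxhat = dout * g
        mean_d = dxhat.mean(axis=axes).reshape(shape)
        mean_dx = (dxhat * xhat).mean(axis=axes).reshape(shape)
        dx = (dxhat - mean_d - xhat * mean_dx) * inv_std.reshape(shape)
        self._cache = None
        return dx


class BatchNorm3d(_BatchNorm):
    pass


class BatchNorm1d(_BatchNorm):
    pass


class LeakyReLU(_Layer):
    def __init__(self, negative_slope=0.01):
        self.slope = negative_slope
        self._mask = None

    def forward(self, x, training=False, rng=None):
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout):
        dx = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return dx


class Dropout(_Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p=0.1):
        self.p = p
        self._mask = None

    def forward(self, x, training=False, rng=None):
        if not training or self.p <= 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        keep = 1.0 - self.p
        mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Flatten(_Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(_Layer):
    def __init__(self, in_features, out_features, bias=True, rng=None, dtype=DEFAULT_DTYPE):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Param(uniform_fan_in_init((out_features, in_features), in_features, rng, dtype), "linear.W")
        self.b = Param(uniform_fan_in_init((out_features,), in_features, rng, dtype), "linear.b") if bias else None
        self._x = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False, rng=None):
        if training:
            self._x = x
        out = x @ self.W.data.T
        if self.b is not None:
            out += self.b.data
        return out

    def backward(self, dout):
        self.W.grad += dout.T @ self._x
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        dx = dout @ self.W.data
        self._x = None
        return dx


class Sequential(_Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.params())
        return ps

    def forward(self, x, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self):
        """All stateful arrays (weights + normalization running statistics)."""
        arrays = []
        for layer in self.layers:
            arrays.extend(_layer_state(layer))
        return arrays

    def get_state(self):
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state):
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("checkpoint state length mismatch")
        for dst, src in zip(arrays, state):
            dst[...] = src


def _layer_state(layer):
    arrays = [p.data for p in layer.params()]
    if isinstance(layer, _BatchNorm):
        arrays += [layer.running_mean, layer.running_var]
    if isinstance(layer, Sequential):
        return layer.state_arrays()
    inner = getattr(layer, "inner_layers", None)
    if inner:
        for sub in inner:
            if not isinstance(sub, _Layer):
                continue
            arrays.extend(_layer_state(sub))
    return arrays


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
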