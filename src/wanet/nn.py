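"""Minimal CPU neural-network layers with explicit backpropagation.

All layers operate on channels-last NHWC float32 arrays — with one CPU
and BLAS doing the heavy lifting, channels-last keeps every unfold and
GEMM on contiguous memory with no layout transposes. Each layer caches
whatever its backward pass needs during ``forward`` and must therefore
be used at most once per forward pass of a model. Gradients are
*assigned* (not accumulated) into :class:`Param` objects, so a fresh
``backward`` fully replaces the previous step's gradients.

3x3 (and dilated) convolutions are evaluated by direct jit-compiled
kernels that vectorize over the contiguous channel axis — over input
channels when the layer contracts (cin >= cout) and over output
channels when it expands — which avoids the k^2-fold memory blowup of
im2col entirely; 1x1 convolutions are plain GEMMs. The input gradient
of a stride-1 "same" convolution is itself a "same" convolution with
the spatially flipped, channel-transposed kernel, so the backward pass
runs on the same kernels. Padded scratch canvases are reused across
calls of identical shape.
"""

from __future__ import annotations

import numba
import numpy as np

DTYPE = np.float32


@numba.njit(fastmath=True, cache=True)
def _fwd_bc(xp, wm, bias, out, k, d):  # pragma: no cover - jitted
    """Direct "same" conv, accumulation broadcast over out channels.

    xp: padded (N, Hp, Wp, Cin); wm: (k*k, Cin, Cout); out: (N, H, W, Cout).
    """
    n, hp, wp, cin = xp.shape
    _, h, w, cout = out.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                acc = out[ni, i, j]
                for o in range(cout):
                    acc[o] = bias[o]
                for a in range(k):
                    for b in range(k):
                        xv = xp[ni, i + a * d, j + b * d]
                        wt = wm[a * k + b]
                        for ci in range(cin):
                            v = xv[ci]
                            row = wt[ci]
                            for o in range(cout):
                                acc[o] += v * row[o]


@numba.njit(fastmath=True, cache=True)
def _fwd_red(xp, wm, bias, out, k, d):  # pragma: no cover - jitted
    """Direct "same" conv, per-output reduction over in channels.

    xp: padded (N, Hp, Wp, Cin); wm: (k*k, Cout, Cin); out: (N, H, W, Cout).
    """
    n, hp, wp, cin = xp.shape
    _, h, w, cout = out.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                acc = out[ni, i, j]
                for o in range(cout):
                    acc[o] = bias[o]
                for a in range(k):
                    for b in range(k):
                        xv = xp[ni, i + a * d, j + b * d]
                        wt = wm[a * k + b]
                        for o in range(cout):
                            s = np.float32(0.0)  # unified to float64 inputs
                            for ci in range(cin):
                                s += xv[ci] * wt[o, ci]
                            acc[o] += s


@numba.njit(fastmath=True, cache=True)
def _grad_w_red(xp, dy, dwm, k, d):  # pragma: no cover - jitted
    """Kernel gradient, accumulation vectorized over in channels:
    dwm (k*k, Cout, Cin)."""
    n, hp, wp, cin = xp.shape
    _, h, w, cout = dy.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                dyv = dy[ni, i, j]
                for a in range(k):
                    for b in range(k):
                        xv = xp[ni, i + a * d, j + b * d]
                        dwt = dwm[a * k + b]
                        for o in range(cout):
                            v = dyv[o]
                            row = dwt[o]
                            for ci in range(cin):
                                row[ci] += v * xv[ci]


@numba.njit(fastmath=True, cache=True)
def _grad_w(xp, dy, dwm, k, d):  # pragma: no cover - jitted
    """Kernel gradient: per-pixel outer products accumulated into
    dwm (k*k, Cin, Cout)."""
    n, hp, wp, cin = xp.shape
    _, h, w, cout = dy.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                dyv = dy[ni, i, j]
                for a in range(k):
                    for b in range(k):
                        xv = xp[ni, i + a * d, j + b * d]
                        dwt = dwm[a * k + b]
                        for ci in range(cin):
                            v = xv[ci]
                            row = dwt[ci]
                            for o in range(cout):
                                row[o] += v * dyv[o]


class Param:
    """A named trainable array with its gradient.

    ``kind`` tags what the array is: ``conv_weight`` entries are the ones
    counted by the parameter-complexity identities (conv kernels only,
    no biases, norm scales, or batch-norm affine terms).
    """

    __slots__ = ("name", "val", "grad", "kind")

    def __init__(self, name: str, val: np.ndarray, kind: str = "other"):
        self.name = name
        self.val = np.asarray(val, dtype=DTYPE)
        self.grad = np.zeros_like(self.val)
        self.kind = kind

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Param({self.name}, shape={self.val.shape}, kind={self.kind})"


class Layer:
    """Base class: forward/backward plus a flat parameter registry."""

    name: str = ""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Zero-mean normal with variance 2/fan_in for a conv kernel.

    ``shape`` is (out_channels, in_channels, k, k); fan_in = in_channels*k*k.
    """
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


def same_pad(k: int, dilation: int) -> int:
    """Padding that preserves spatial dims for a stride-1 dilated conv.

    The total pad d*(k-1) is even for odd k, so left == right.
    """
    return dilation * (k - 1) // 2


class _Padder:
    """Shape-cached zero-pad canvas: the margins never change after
    allocation, so re-use across same-shaped calls costs only the
    interior copy."""

    def __init__(self, pad: int):
        self.p = pad
        self._shape: tuple[int, ...] | None = None
        self._xp: np.ndarray | None = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.p
        if self._shape != x.shape or self._xp.dtype != x.dtype:
            self._shape = x.shape
            self._xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=x.dtype)
        self._xp[:, p:p + h, p:p + w, :] = x
        return self._xp


class Conv2d(Layer):
    """Stride-1 "same" 2-D convolution with optional dilation and
    weight normalization.

    With ``weight_norm=True`` the kernel is stored as a direction tensor
    ``V`` and a per-output-filter scale ``g``; the effective kernel is
    w_f = g_f * V_f / ||V_f||, so ||w_f|| == g_f regardless of the
    magnitude of V_f. Kernels are registered in (out, in, k, k) layout.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        dilation: int = 1,
        bias: bool = True,
        weight_norm: bool = False,
        name: str = "conv",
        rng: np.random.Generator | None = None,
    ):
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.cin, self.cout = in_channels, out_channels
        self.k, self.d = kernel, dilation
        self.wn = weight_norm
        self.name = name
        rng = rng or np.random.default_rng(0)
        w0 = he_normal(rng, (out_channels, in_channels, kernel, kernel))
        if weight_norm:
            self.V = Param(f"{name}.V", w0, kind="conv_weight")
            self.g = Param(f"{name}.g", self._filter_norms(w0), kind="wn_scale")
        else:
            self.W = Param(f"{name}.W", w0, kind="conv_weight")
        self.b = Param(f"{name}.b", np.zeros(out_channels), kind="bias") if bias else None
        p = same_pad(kernel, dilation)
        self._pad_x = _Padder(p)
        self._pad_dy = _Padder(p)
        self._xcache: np.ndarray | None = None  # padded input (or flat, k=1)

    @staticmethod
    def _filter_norms(w: np.ndarray) -> np.ndarray:
        return np.sqrt((w.reshape(w.shape[0], -1) ** 2).sum(axis=1))

    def effective_weight(self) -> np.ndarray:
        if not self.wn:
            return self.W.val
        norms = self._filter_norms(self.V.val)
        if np.any(norms == 0):
            raise FloatingPointError(
                f"{self.name}: zero-norm direction tensor; weight normalization undefined"
            )
        return (self.g.val / norms)[:, None, None, None] * self.V.val

    def set_weight(self, w: np.ndarray) -> None:
        """Assign an effective kernel (re-deriving V, g under WN)."""
        w = np.asarray(w, dtype=DTYPE)
        if self.wn:
            v = w.copy()
            norms = self._filter_norms(v)
            zero = norms == 0
            if np.any(zero):  # zero kernel: keep a valid direction, g = 0
                v[zero, 0, 0, 0] = 1.0
            self.V.val = v
            self.g.val = norms
        else:
            self.W.val = w.copy()

    @staticmethod
    def _run_conv(xp: np.ndarray, w: np.ndarray, bias: np.ndarray | None,
                  out_shape: tuple[int, ...], k: int, d: int) -> np.ndarray:
        """Dispatch to the direct kernel whose vectorized axis is widest."""
        cout, cin = w.shape[0], w.shape[1]
        out = np.empty(out_shape, dtype=xp.dtype)
        b = (bias if bias is not None else np.zeros(cout)).astype(xp.dtype)
        if cin >= cout:
            wm = np.ascontiguousarray(w.transpose(2, 3, 0, 1)).reshape(k * k, cout, cin)
            _fwd_red(xp, wm, b, out, k, d)
        else:
            wm = np.ascontiguousarray(w.transpose(2, 3, 1, 0)).reshape(k * k, cin, cout)
            _fwd_bc(xp, wm, b, out, k, d)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.cin:
            raise ValueError(
                f"{self.name}: expected {self.cin} input channels, got {x.shape[-1]}"
            )
        n, h, w, _ = x.shape
        weight = self.effective_weight().astype(x.dtype, copy=False)
        if self.k == 1 and self.d == 1:
            flat = np.ascontiguousarray(x).reshape(-1, self.cin)
            self._xcache = flat
            y = flat @ weight[:, :, 0, 0].T
            if self.b is not None:
                y += self.b.val
            return y.reshape(n, h, w, self.cout)
        xp = self._pad_x(x)
        self._xcache = xp
        y = self._run_conv(xp, weight, self.b.val if self.b is not None else None,
                           (n, h, w, self.cout), self.k, self.d)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        weight = self.effective_weight().astype(dy.dtype, copy=False)
        if self.k == 1 and self.d == 1:
            dy_flat = dy.reshape(-1, self.cout)
            dW = (dy_flat.T @ self._xcache)[:, :, None, None]
            if self.b is not None:
                self.b.grad = dy_flat.sum(axis=0)
            dx = (dy_flat @ weight[:, :, 0, 0]).reshape(n, h, w, self.cin)
            self._xcache = None
            self._set_weight_grad(dW)
            return dx
        if self.cin >= self.cout:
            dwm = np.zeros((self.k * self.k, self.cout, self.cin), dtype=dy.dtype)
            _grad_w_red(self._xcache, dy, dwm, self.k, self.d)
            dW = np.ascontiguousarray(
                dwm.reshape(self.k, self.k, self.cout, self.cin).transpose(2, 3, 0, 1))
        else:
            dwm = np.zeros((self.k * self.k, self.cin, self.cout), dtype=dy.dtype)
            _grad_w(self._xcache, dy, dwm, self.k, self.d)
            dW = np.ascontiguousarray(
                dwm.reshape(self.k, self.k, self.cin, self.cout).transpose(3, 2, 0, 1))
        self._xcache = None
        if self.b is not None:
            self.b.grad = dy.sum(axis=(0, 1, 2))
        # input gradient: "same" conv of dy with flipped, transposed kernel
        wt = np.ascontiguousarray(weight[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx = self._run_conv(self._pad_dy(dy), wt, None,
                            (n, h, w, self.cin), self.k, self.d)
        self._set_weight_grad(dW)
        return dx

    def _set_weight_grad(self, dW: np.ndarray) -> None:
        if self.wn:
            # chain rule through w = g * V/||V||, per output filter
            norms = self._filter_norms(self.V.val)
            vflat = self.V.val.reshape(self.cout, -1)
            dwflat = dW.reshape(self.cout, -1)
            dg = (dwflat * vflat).sum(axis=1) / norms
            self.g.grad = dg
            dV = (self.g.val / norms)[:, None] * (
                dwflat - (dg / norms)[:, None] * vflat
            )
            self.V.grad = dV.reshape(self.V.val.shape)
        else:
            self.W.grad = dW

    def params(self) -> list[Param]:
        ps = [self.V, self.g] if self.wn else [self.W]
        if self.b is not None:
            ps.append(self.b)
        return ps

    def conv_weight_count(self) -> int:
        return self.cout * self.cin * self.k * self.k


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-5,
                 name: str = "bn"):
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self.gamma = Param(f"{name}.gamma", np.ones(channels), kind="bn")
        self.beta = Param(f"{name}.beta", np.zeros(channels), kind="bn")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(DTYPE)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train)
        return self.gamma.val * xhat + self.beta.val

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.grad = (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad = dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.val
        if not train:
            return dxhat * inv
        return (
            dxhat
            - dxhat.mean(axis=(0, 1, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2), keepdims=True)
        ) * inv

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LeakyReLU(Layer):
    """f(x) = x for x > 0, a*x otherwise."""

    def __init__(self, alpha: float = 0.3):
        self.alpha = alpha

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 requires even spatial dims, got {h}x{w}")
        v = np.ascontiguousarray(
            x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(n, h // 2, w // 2, 4, c)
        self._arg = v.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(v, self._arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dv = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dv, self._arg[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dv = dv.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dv).reshape(n, h, w, c)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SoftmaxChannels(Layer):
    """Per-pixel softmax over the (last) channel axis."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._p = p
        return p

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dy - (dy * p).sum(axis=-1, keepdims=True))


class Sequential(Layer):
    def __init__(self, layers: list[Layer], name: str = "seq"):
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]
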