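"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small engine covering exactly the operations the package
needs: complex arithmetic and centered unitary FFTs for the coherent-imaging
forward model, plus convolutions, pooling and pointwise nonlinearities for
the reconstruction / staining networks.

Conventions
-----------
* Gradients of a real scalar loss with respect to a complex tensor ``z`` are
  stored as the steepest-ascent vector ``dL/d(Re z) + i * dL/d(Im z)``
  (twice the Wirtinger derivative with respect to ``conj(z)``).  For real
  tensors this reduces to the ordinary gradient.  Every rule below is
  checked against central finite differences in the test suite.
* Spectra are DC-centered and FFTs are orthonormal (``norm="ortho"``), so
  Parseval's identity holds exactly.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "no_grad",
    "concat",
    "stack",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}{flag})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd ------------------------------------------------------------
    def _accum(self, g: np.ndarray):
        g = np.asarray(g)
        if not np.iscomplexobj(self.data) and np.iscomplexobj(g):
            g = g.real
        g = _unbroadcast(g, self.data.shape)
        if g.dtype != self.data.dtype and not np.iscomplexobj(g):
            g = g.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients/graph references eagerly
                if node is not self:
                    node._backward = None
                    node._parents = ()

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        if isinstance(other, (int, float, complex)) and not isinstance(other, bool):
            return add(self, -other)
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- method sugar ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def abs(self):
        return tabs(self)

    def conj(self):
        return conj(self)

    def real(self):
        return real(self)

    def imag(self):
        return imag(self)


class Parameter(Tensor):
    """A trainable tensor (collected by :class:`ptystain.nn.Module`)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters stay trainable under no_grad()


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    # scalar fast path: keeps float32 graphs float32 (weak promotion)
    if isinstance(b, (int, float, complex)) and not isinstance(b, bool):
        a = astensor(a)
        data = a.data + b

        def backward(g):
            a._accum(g)

        return _make(data, (a,), backward)
    if isinstance(a, (int, float, complex)) and not isinstance(a, bool):
        return add(b, a)
    a, b = astensor(a), astensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float, complex)) and not isinstance(b, bool):
        a = astensor(a)
        data = a.data * b

        def backward(g):
            a._accum(g * np.conj(b))

        return _make(data, (a,), backward)
    if isinstance(a, (int, float, complex)) and not isinstance(a, bool):
        return mul(b, a)
    a, b = astensor(a), astensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g * np.conj(b.data))
        if b.requires_grad:
            b._accum(g * np.conj(a.data))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = astensor(a)
    data = a.data ** p

    def backward(g):
        a._accum(g * np.conj(p * a.data ** (p - 1)))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.conj(np.swapaxes(b.data, -1, -2))
            a._accum(ga)
        if b.requires_grad:
            gb = np.conj(np.swapaxes(a.data, -1, -2)) @ g
            b._accum(gb)

    return _make(data, (a, b), backward)


def texp(a) -> Tensor:
    a = astensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * np.conj(data))

    return _make(data, (a,), backward)


def tlog(a) -> Tensor:
    a = astensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accum(g / np.conj(a.data))

    return _make(data, (a,), backward)


def tsqrt(a) -> Tensor:
    return power(a, 0.5)


# ---------------------------------------------------------------------------
# complex-number plumbing
# ---------------------------------------------------------------------------

def conj(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        a._accum(np.conj(g))

    return _make(np.conj(a.data), (a,), backward)


def real(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        a._accum(g.real if np.iscomplexobj(g) else g)

    return _make(a.data.real.copy(), (a,), backward)


def imag(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        a._accum(1j * (g.real if np.iscomplexobj(g) else g))

    return _make(a.data.imag.copy(), (a,), backward)


def tabs(a, eps: float = 1e-30) -> Tensor:
    """|a| (real output for complex input)."""
    a = astensor(a)
    mag = np.abs(a.data)

    def backward(g):
        if np.iscomplexobj(a.data):
            a._accum(g * a.data / np.maximum(mag, eps))
        else:
            a._accum(g * np.sign(a.data))

    return _make(mag, (a,), backward)


def abs2(a) -> Tensor:
    """|a|^2, real output; gradient 2 g a under the steepest-ascent convention."""
    a = astensor(a)
    data = (a.data * np.conj(a.data)).real

    def backward(g):
        a._accum(2.0 * g * a.data)

    return _make(data, (a,), backward)


def polar(amp, phase) -> Tensor:
    """Complex field ``amp * exp(i * phase)`` from real amplitude and phase."""
    amp, phase = astensor(amp), astensor(phase)
    ph = np.exp(1j * phase.data)
    data = amp.data * ph

    def backward(g):
        if amp.requires_grad:
            amp._accum((g * np.conj(ph)).real)
        if phase.requires_grad:
            phase._accum((g * np.conj(1j * data)).real)

    return _make(data, (amp, phase), backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accum(g * mask)

    return _make(data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = astensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        a._accum(g * np.where(mask, 1.0, slope))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    x = np.clip(a.data, -60, 60)  # exp never overflows; sigmoid saturates anyway
    data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))

    def backward(g):
        a._accum(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def tanh(a) -> Tensor:
    a = astensor(a)
    data = np.tanh(a.data)

    def backward(g):
        a._accum(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + e^x), numerically stable; smooth positivity map."""
    a = astensor(a)
    x = a.data
    data = np.logaddexp(0.0, x)

    def backward(g):
        a._accum(g / (1.0 + np.exp(-x)))

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / max(data.size, 1)

    def backward(g):
        gg = np.asarray(g) / n
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accum(np.broadcast_to(gg, a.data.shape))

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = astensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(np.asarray(g).reshape(a.data.shape))

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = astensor(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros(a.data.shape, dtype=g.dtype if np.iscomplexobj(g) or not np.iscomplexobj(a.data) else a.data.dtype)
        np.add.at(full, idx, g)
        a._accum(full)

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad:
                t._accum(g[tuple(sl)])
            start += s

    return _make(data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return _make(data, tuple(tensors), backward)


def pad2d(a, pad: int, mode: str = "constant") -> Tensor:
    """Pad the trailing two axes symmetrically.

    The backward pass is the exact adjoint for ``constant`` (zero) padding.
    ``reflect`` padding is offered for shape plumbing only (its backward
    simply crops); no training path in the package differentiates through it.
    """
    a = astensor(a)
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    data = np.pad(a.data, width, mode=mode)

    def backward(g):
        sl = (Ellipsis, slice(pad, g.shape[-2] - pad), slice(pad, g.shape[-1] - pad))
        a._accum(np.array(g[sl]))

    return _make(data, (a,), backward)


def flip2d(a) -> Tensor:
    """Reverse both trailing axes (f -> -f up to the even-grid edge row/col)."""
    a = astensor(a)
    data = a.data[..., ::-1, ::-1].copy()

    def backward(g):
        a._accum(np.asarray(g)[..., ::-1, ::-1])

    return _make(data, (a,), backward)


def roll2d(a, shift_y: int, shift_x: int) -> Tensor:
    """Circular shift of the trailing two axes (used for spectrum shifts)."""
    a = astensor(a)
    data = np.roll(a.data, (shift_y, shift_x), axis=(-2, -1))

    def backward(g):
        a._accum(np.roll(g, (-shift_y, -shift_x), axis=(-2, -1)))

    return _make(data, (a,), backward)


def crop_center(a, out_h: int, out_w: int) -> Tensor:
    """Central crop of the trailing two axes."""
    a = astensor(a)
    h, w = a.shape[-2], a.shape[-1]
    y0, x0 = (h - out_h) // 2, (w - out_w) // 2
    idx = (Ellipsis, slice(y0, y0 + out_h), slice(x0, x0 + out_w))
    data = a.data[idx]

    def backward(g):
        full = np.zeros(a.data.shape, dtype=g.dtype)
        full[idx] = g
        a._accum(full)

    return _make(data, (a,), backward)


def pad_center(a, out_h: int, out_w: int) -> Tensor:
    """Zero-pad the trailing two axes up to (out_h, out_w), centered."""
    a = astensor(a)
    h, w = a.shape[-2], a.shape[-1]
    y0, x0 = (out_h - h) // 2, (out_w - w) // 2
    idx = (Ellipsis, slice(y0, y0 + h), slice(x0, x0 + w))
    shape = a.data.shape[:-2] + (out_h, out_w)
    data = np.zeros(shape, dtype=a.data.dtype)
    data[idx] = a.data

    def backward(g):
        a._accum(g[idx])

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# centered unitary FFTs
# ---------------------------------------------------------------------------

def _fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"), axes=(-2, -1))


def _ifft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"), axes=(-2, -1))


def fft2c(a) -> Tensor:
    """DC-centered orthonormal 2-D FFT of the trailing axes."""
    a = astensor(a)

    def backward(g):
        a._accum(_ifft2c(np.asarray(g, dtype=complex)))

    return _make(_fft2c(a.data), (a,), backward)


def ifft2c(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        a._accum(_fft2c(np.asarray(g, dtype=complex)))

    return _make(_ifft2c(a.data), (a,), backward)


# ---------------------------------------------------------------------------
# convolutions (NCHW)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    b, c, h, w = x.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # b, c, ho, wo, kh, kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho * wo, c * kh * kw)
    return cols, ho, wo


def _nhwc(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x.transpose(0, 2, 3, 1))


def _nchw(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _conv_fwd_nhwc(xp: np.ndarray, wk: np.ndarray, stride: int, ho: int, wo: int):
    """Shift-and-add convolution on a padded channels-last input.

    xp: (b, hp, wp, ci); wk: (kh, kw, ci, co).  Returns (b, ho, wo, co).
    """
    b = xp.shape[0]
    kh, kw, ci, co = wk.shape
    acc = np.zeros((b * ho * wo, co), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :]
            acc += np.ascontiguousarray(sl).reshape(b * ho * wo, ci) @ wk[i, j]
    return acc.reshape(b, ho, wo, co)


def _conv_bwd_input_nhwc(g: np.ndarray, wk: np.ndarray, stride: int,
                         hp: int, wp: int) -> np.ndarray:
    """Adjoint of :func:`_conv_fwd_nhwc` w.r.t. the *padded* input.

    g: (b, ho, wo, co) channels-last output gradient.  Returns the padded
    input gradient (b, hp, wp, ci); the caller strips the padding.
    """
    b, ho, wo, co = g.shape
    kh, kw, ci, _ = wk.shape
    g2 = g.reshape(b * ho * wo, co)
    dxp = np.zeros((b, hp, wp, ci), dtype=g.dtype)
    for i in range(kh):
        for j in range(kw):
            contrib = (g2 @ wk[i, j].T).reshape(b, ho, wo, ci)
            dxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :] += contrib
    return dxp


def _conv_bwd_weight_nhwc(xp: np.ndarray, g: np.ndarray, stride: int,
                          kh: int, kw: int) -> np.ndarray:
    """Weight gradient: (kh, kw, ci, co) from padded input and output grad."""
    b, ho, wo, co = g.shape
    ci = xp.shape[-1]
    g2 = g.reshape(b * ho * wo, co)
    dwk = np.empty((kh, kw, ci, co), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :]
            dwk[i, j] = np.ascontiguousarray(sl).reshape(b * ho * wo, ci).T @ g2
    return dwk


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; ``weight`` has shape (C_out, C_in, kh, kw).

    Internally runs channels-last with per-tap BLAS matmuls (fastest layout
    for NumPy); the public interface stays NCHW.
    """
    x, weight = astensor(x), astensor(weight)
    co, ci, kh, kw = weight.shape
    b, _, h, w = x.shape
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    xp = _nhwc(x.data)
    if padding:
        xp = np.pad(xp, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    wk = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0))  # kh,kw,ci,co
    out_n = _conv_fwd_nhwc(xp, wk, stride, ho, wo)
    if bias is not None:
        bias = astensor(bias)
        out_n = out_n + bias.data
    out = _nchw(out_n)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gn = _nhwc(g)
        if bias is not None and bias.requires_grad:
            bias._accum(gn.sum(axis=(0, 1, 2)))
        if weight.requires_grad:
            dwk = _conv_bwd_weight_nhwc(xp, gn, stride, kh, kw)
            weight._accum(np.ascontiguousarray(dwk.transpose(3, 2, 0, 1)))
        if x.requires_grad:
            dxp = _conv_bwd_input_nhwc(gn, wk, stride, hp, wp)
            if padding:
                dxp = dxp[:, padding:padding + h, padding:padding + w, :]
            x._accum(_nchw(dxp))

    return _make(out, parents, backward)


def conv2d_transpose(x, weight, bias=None, stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution (adjoint of :func:`conv2d` with same geometry).

    ``weight`` has shape (C_in, C_out, kh, kw); output spatial size is
    ``(in - 1) * stride - 2 * padding + k``.
    """
    x, weight = astensor(x), astensor(weight)
    ci, co, kh, kw = weight.shape
    b, _, h, w = x.shape
    oh = (h - 1) * stride - 2 * padding + kh
    ow = (w - 1) * stride - 2 * padding + kw
    ohp, owp = oh + 2 * padding, ow + 2 * padding
    # forward = adjoint of conv2d: the NHWC kernel reads (kh, kw, c_out, c_in)
    wk = np.ascontiguousarray(weight.data.transpose(2, 3, 1, 0))  # kh,kw,co,ci
    xn = _nhwc(x.data)
    outp = _conv_bwd_input_nhwc(xn, wk, stride, ohp, owp)
    out_n = outp[:, padding:padding + oh, padding:padding + ow, :] if padding else outp
    if bias is not None:
        bias = astensor(bias)
        out_n = out_n + bias.data
    out = _nchw(out_n)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gn = _nhwc(g)
        if padding:
            gn = np.pad(gn, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dwk = _conv_bwd_weight_nhwc(gn, xn, stride, kh, kw)  # kh,kw,co,ci
            weight._accum(np.ascontiguousarray(dwk.transpose(3, 2, 0, 1)))
        if x.requires_grad:
            gx = _conv_fwd_nhwc(gn, wk, stride, h, w)
            x._accum(_nchw(gx))

    return _make(out, parents, backward)


def depthwise_conv2d(x, weight, padding: int = 1) -> Tensor:
    """Per-channel (grouped, groups=C) convolution; ``weight``: (C, kh, kw)."""
    x, weight = astensor(x), astensor(weight)
    c, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    out = np.einsum("bchwij,cij->bchw", win, weight.data, optimize=True)

    def backward(g):
        if weight.requires_grad:
            dw = np.einsum("bchwij,bchw->cij", win, g, optimize=True)
            weight._accum(dw)
        if x.requires_grad:
            b, _, h, w = x.shape
            hp, wp = h + 2 * padding, w + 2 * padding
            dxp = np.zeros((b, c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + h, j:j + w] += g * weight.data[:, i, j][None, :, None, None]
            x._accum(dxp[:, :, padding:hp - padding, padding:wp - padding])

    return _make(out, (x, weight), backward)


def avg_pool2x(a) -> Tensor:
    """2x2 average pooling (trailing axes must be even)."""
    a = astensor(a)
    h, w = a.shape[-2], a.shape[-1]
    data = a.data.reshape(a.shape[:-2] + (h // 2, 2, w // 2, 2)).mean(axis=(-3, -1))

    def backward(g):
        gg = np.repeat(np.repeat(np.asarray(g), 2, axis=-1), 2, axis=-2) / 4.0
        a._accum(gg)

    return _make(data, (a,), backward)


def upsample2x(a) -> Tensor:
    """Nearest-neighbour 2x upsampling of the trailing axes."""
    a = astensor(a)
    data = np.repeat(np.repeat(a.data, 2, axis=-1), 2, axis=-2)

    def backward(g):
        h, w = a.shape[-2], a.shape[-1]
        gg = np.asarray(g).reshape(g.shape[:-2] + (h, 2, w, 2)).sum(axis=(-3, -1))
        a._accum(gg)

    return _make(data, (a,), backward)


# Haar DWT as graph operations -------------------------------------------------

def haar_dwt2(a):
    """Orthonormal single-level 2-D Haar DWT of the trailing axes.

    Returns (LL, LH, HL, HH); each has half the spatial size.  A constant
    image c maps to LL = 2c and zero detail bands under this normalization.
    """
    p00 = a[..., 0::2, 0::2]
    p01 = a[..., 0::2, 1::2]
    p10 = a[..., 1::2, 0::2]
    p11 = a[..., 1::2, 1::2]
    ll = (p00 + p01 + p10 + p11) * 0.5
    lh = (p00 + p01 - p10 - p11) * 0.5  # vertical detail (row difference)
    hl = (p00 - p01 + p10 - p11) * 0.5  # horizontal detail
    hh = (p00 - p01 - p10 + p11) * 0.5
    return ll, lh, hl, hh


def haar_idwt2(ll, lh, hl, hh):
    """Inverse of :func:`haar_dwt2` (exact perfect reconstruction)."""
    p00 = (ll + lh + hl + hh) * 0.5
    p01 = (ll + lh - hl - hh) * 0.5
    p10 = (ll - lh + hl - hh) * 0.5
    p11 = (ll - lh - hl + hh) * 0.5
    parts = [p00, p01, p10, p11]
    h2, w2 = ll.shape[-2], ll.shape[-1]
    out_shape = ll.shape[:-2] + (2 * h2, 2 * w2)
    # interleave via stack/reshape with graph ops
    rows_top = stack([p00, p01], axis=-1).reshape(out_shape[:-2] + (h2, 2 * w2))
    rows_bot = stack([p10, p11], axis=-1).reshape(out_shape[:-2] + (h2, 2 * w2))
    full = stack([rows_top, rows_bot], axis=-2).reshape(out_shape)
    del parts
    return full
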