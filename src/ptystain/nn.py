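"""Minimal neural-network layer library on top of :mod:`ptystain.autodiff`.

Layers follow NCHW layout.  Every layer takes an explicit
``numpy.random.Generator`` for weight initialization so that whole models
are bit-reproducible from a single seed; no global RNG state is touched.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self):
        params, seen = [], set()
        stack = [self]
        while stack:
            obj = stack.pop()
            if id(obj) in seen:
                continue
            seen.add(id(obj))
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        """Flat name -> array mapping (deterministic traversal order)."""
        out = {}

        def walk(obj, prefix):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, v in enumerate(value):
                        if isinstance(v, Module):
                            walk(v, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict):
        own = {}

        def walk(obj, prefix):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    own[key] = value
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, v in enumerate(value):
                        if isinstance(v, Module):
                            walk(v, f"{key}.{i}.")

        walk(self, "")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for key, param in own.items():
            arr = np.asarray(state[key], dtype=param.data.dtype)
            if arr.shape != param.data.shape:
                raise ValueError(f"shape mismatch for {key}: {arr.shape} vs {param.data.shape}")
            param.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return ad.leaky_relu(x, self.slope)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, (n_in, n_out)).astype(np.float32))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True, zero_init: bool = False):
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        fan_in = c_in * k * k
        if zero_init:
            w = np.zeros((c_out, c_in, k, k), dtype=np.float32)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Stride-2 upsampling convolution (k=4, p=1 doubles the spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, padding: int = 1, bias: bool = True):
        self.stride, self.padding = stride, padding
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_in, c_out, k, k)).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        return ad.conv2d_transpose(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution (used inside wavelet subband blocks)."""

    def __init__(self, channels: int, k: int = 3, rng: np.random.Generator | None = None,
                 identity_init: bool = False):
        self.padding = k // 2
        if identity_init:
            w = np.zeros((channels, k, k), dtype=np.float32)
            w[:, k // 2, k // 2] = 1.0
        else:
            w = rng.normal(0.0, np.sqrt(1.0 / (k * k)), (channels, k, k)).astype(np.float32)
        self.weight = Parameter(w)

    def forward(self, x):
        return ad.depthwise_conv2d(x, self.weight, self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learnable affine terms."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = ad.abs2(centered).mean(axis=(2, 3), keepdims=True)
        inv = ad.power(var + self.eps, -0.5)
        return centered * inv * self.gamma + self.beta


class ResidualBlock(Module):
    """conv-norm-relu-conv-norm with identity skip (image-translation style)."""

    def __init__(self, channels: int, rng: np.random.Generator, norm: bool = True):
        self.conv1 = Conv2d(channels, channels, 3, rng=rng, bias=not norm)
        self.conv2 = Conv2d(channels, channels, 3, rng=rng, bias=not norm)
        self.norm1 = InstanceNorm2d(channels) if norm else None
        self.norm2 = InstanceNorm2d(channels) if norm else None

    def forward(self, x):
        h = self.conv1(x)
        if self.norm1 is not None:
            h = self.norm1(h)
        h = ad.relu(h)
        h = self.conv2(h)
        if self.norm2 is not None:
            h = self.norm2(h)
        return h + x


class SEBlock(Module):
    """Squeeze-and-excitation channel gating; gates lie strictly in (0, 1)."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8):
        if channels % reduction != 0:
            raise ValueError(f"reduction {reduction} must divide channel count {channels}")
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def forward(self, x):
        b, c = x.shape[0], x.shape[1]
        squeeze = x.mean(axis=(2, 3))  # (b, c)
        gate = ad.sigmoid(self.fc2(ad.relu(self.fc1(squeeze))))
        return x * gate.reshape((b, c, 1, 1))


class WTConvBlock(Module):
    """Wavelet-transform convolution: Haar DWT -> per-subband depthwise conv -> IDWT.

    With identity-initialized subband convolutions the block is an exact
    identity map (perfect reconstruction of the orthonormal Haar pair).
    Odd spatial sizes are edge-padded to even and cropped back.
    """

    def __init__(self, channels: int, rng: np.random.Generator, identity_init: bool = False):
        self.subband = [DepthwiseConv2d(channels, 3, rng=rng, identity_init=identity_init)
                        for _ in range(4)]

    def forward(self, x):
        h, w = x.shape[-2], x.shape[-1]
        pad_h, pad_w = h % 2, w % 2
        if pad_h or pad_w:
            x = _odd_pad(x, pad_h, pad_w)
        bands = ad.haar_dwt2(x)
        bands = [conv(b) for conv, b in zip(self.subband, bands)]
        out = ad.haar_idwt2(*bands)
        if pad_h or pad_w:
            out = out[..., :h, :w]
        return out


def _odd_pad(x, pad_h, pad_w):
    # replicate last row/col by concatenation (differentiable reflect-ish pad)
    if pad_h:
        x = ad.concat([x, x[..., -1:, :]], axis=-2)
    if pad_w:
        x = ad.concat([x, x[..., :, -1:]], axis=-1)
    return x


class Adam:
    """Adam optimizer on a flat list of :class:`Parameter`."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64 if not np.iscomplexobj(p.data) else np.float64)
                  for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            dtype = p.data.dtype
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * np.abs(g) ** 2
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(dtype, copy=False)
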