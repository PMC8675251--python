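"""Neural-network layers for volumetric models, built on :mod:`meniscus3d.autodiff`.

Layout convention for feature volumes is ``(batch, channels, slices, rows,
cols)``.  The 3D convolution is evaluated as a shift-and-matmul loop over
kernel offsets: for every kernel offset the strided input slice is contracted
against the corresponding weight slab with a BLAS matmul.  The same scheme is
used for the input and weight gradients, so no im2col buffer larger than one
feature volume is ever materialised.

Weight initialisation follows the He scheme for ReLU networks (zero-mean
normal with sd sqrt(2/fan_in)); batch-norm scale starts at 1 and shift at 0.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, is_grad_enabled

__all__ = [
    "Module", "Parameter", "Sequential", "ModuleList", "Linear", "ReLU",
    "Dropout", "Conv3d", "BatchNorm3d", "MaxPool3d", "GlobalAvgPool3d",
]


class Parameter(Tensor):
    """A trainable tensor (always requires gradients)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ------------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    # -- train/eval -----------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.named_children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {("param." + k): v.data.copy() for k, v in self.named_parameters()}
        state.update({("buffer." + k): v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name!r}: "
                        f"{params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(np.float32).copy()
            elif kind == "buffer":
                self._assign_buffer(name, value)
            else:  # pragma: no cover
                raise KeyError(f"malformed state key {key!r}")

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj: Module = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise KeyError(f"unknown buffer {dotted!r}")
        setattr(obj, parts[-1], value.astype(np.float64).copy()
                if getattr(obj, parts[-1]).dtype == np.float64
                else value.astype(np.float32).copy())


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)
        self._n = len(layers)

    def __iter__(self):
        return (getattr(self, f"l{i}") for i in range(self._n))

    def forward(self, x):
        for layer in self:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._n = 0
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        setattr(self, f"m{self._n}", module)
        self._n += 1

    def __len__(self):
        return self._n

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, f"m{i % self._n if i >= 0 else self._n + i}")

    def forward(self, x):
        for m in self:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Needs an rng bound at model build."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * Tensor(mask)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        sd = float(np.sqrt(2.0 / in_features))
        self.weight = Parameter(rng.normal(0.0, sd, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


def _triple(v) -> tuple:
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v, v)


def _conv_out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - (k - 1) * d - 1) // s + 1


class Conv3d(Module):
    """3D convolution (cross-correlation) with stride, padding and dilation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 stride=1, padding=0, dilation=1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        self.dilation = _triple(dilation)
        fan_in = in_channels * int(np.prod(self.kernel_size))
        sd = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, sd, (out_channels, in_channels) + self.kernel_size))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        w = self.weight
        N, C = x.data.shape[:2]
        F = self.out_channels
        xp = _pad3d(x.data, self.padding)
        cols, oshape = _im2col(xp, self.kernel_size, self.stride, self.dilation)
        wm = w.data.reshape(F, -1)
        od, oh, ow = oshape
        out_data = np.ascontiguousarray(
            (cols @ wm.T).reshape(N, od, oh, ow, F).transpose(0, 4, 1, 2, 3))
        if self.bias is not None:
            out_data += self.bias.data[None, :, None, None, None]
        conv = self
        xp_shape = xp.shape

        def bwd(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, F)
            if w.requires_grad:
                w.accumulate((g2.T @ cols).reshape(w.data.shape))
            if conv.bias is not None and conv.bias.requires_grad:
                conv.bias.accumulate(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                dcols = g2 @ wm
                dxp = _col2im(dcols, xp_shape, conv.kernel_size, conv.stride,
                              conv.dilation, oshape)
                x.accumulate(_unpad3d(dxp, conv.padding))

        parents = (x, w) if self.bias is None else (x, w, self.bias)
        return Tensor.make(out_data, parents, bwd)


def _pad3d(x: np.ndarray, pad: tuple, value: float = 0.0) -> np.ndarray:
    if pad == (0, 0, 0):
        return x
    pd, ph, pw = pad
    return np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
                  constant_values=value)


def _unpad3d(x: np.ndarray, pad: tuple) -> np.ndarray:
    if pad == (0, 0, 0):
        return x
    pd, ph, pw = pad
    return x[:, :, pd:x.shape[2] - pd, ph:x.shape[3] - ph, pw:x.shape[4] - pw]


def _im2col(xp: np.ndarray, ksize, stride, dilation):
    """Gather conv patches into a (N*positions, C*k^3) matrix."""
    kd, kh, kw = ksize
    sd, sh, sw = stride
    dd, dh, dw = dilation
    N, C, D, H, W = xp.shape
    od = (D - (kd - 1) * dd - 1) // sd + 1
    oh = (H - (kh - 1) * dh - 1) // sh + 1
    ow = (W - (kw - 1) * dw - 1) // sw + 1
    if ksize == (1, 1, 1) and dilation == (1, 1, 1):
        xs = xp[:, :, ::sd, ::sh, ::sw]
        cols = np.ascontiguousarray(xs.transpose(0, 2, 3, 4, 1))
        return cols.reshape(N * od * oh * ow, C), (od, oh, ow)
    from ._kernels import gather3d
    cols = np.empty((N * od * oh * ow, C * kd * kh * kw), dtype=xp.dtype)
    gather3d(xp, cols, od, oh, ow, kd, kh, kw, sd, sh, sw, dd, dh, dw)
    return cols, (od, oh, ow)


def _col2im(dcols: np.ndarray, xp_shape, ksize, stride, dilation, oshape) -> np.ndarray:
    """Scatter-add patch gradients back onto the padded input grid."""
    kd, kh, kw = ksize
    sd, sh, sw = stride
    dd, dh, dw = dilation
    N, C, D, H, W = xp_shape
    od, oh, ow = oshape
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    if ksize == (1, 1, 1) and dilation == (1, 1, 1):
        dc = dcols.reshape(N, od, oh, ow, C).transpose(0, 4, 1, 2, 3)
        dxp[:, :, ::sd, ::sh, ::sw] += dc
        return dxp
    from ._kernels import scatter3d
    scatter3d(dxp, np.ascontiguousarray(dcols), od, oh, ow,
              kd, kh, kw, sd, sh, sw, dd, dh, dw)
    return dxp


class MaxPool3d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)

    def forward(self, x: Tensor) -> Tensor:
        kd, kh, kw = self.kernel_size
        sd, sh, sw = self.stride
        xp = _pad3d(x.data, self.padding, value=-np.inf)
        N, C, D, H, W = xp.shape
        od = (D - kd) // sd + 1
        oh = (H - kh) // sh + 1
        ow = (W - kw) // sw + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw][:, :, :od, :oh, :ow]
        flat = win.reshape(N, C, od, oh, ow, kd * kh * kw)
        idx = flat.argmax(axis=-1)
        out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        pool = self

        def bwd(g):
            dxp = np.zeros_like(xp)
            for k in range(kd * kh * kw):
                a, rem = divmod(k, kh * kw)
                b, c = divmod(rem, kw)
                mask = idx == k
                if not mask.any():
                    continue
                dxp[:, :, a:a + od * sd:sd, b:b + oh * sh:sh, c:c + ow * sw:sw] += g * mask
            x.accumulate(_unpad3d(dxp, pool.padding))

        return Tensor.make(out_data, (x,), bwd)


class GlobalAvgPool3d(Module):
    """Average each feature volume to a single value: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3, 4))


class BatchNorm3d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.weight, self.bias
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            if is_grad_enabled():
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mean).astype(np.float32)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        out_data = (xhat * gamma.data[None, :, None, None, None]
                    + beta.data[None, :, None, None, None])
        bn, training = self, self.training
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3] * x.data.shape[4]

        def bwd(g):
            if gamma.requires_grad:
                gamma.accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta.accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gb = gamma.data[None, :, None, None, None] * inv[None, :, None, None, None]
                if training:
                    gm = g.mean(axis=axes)[None, :, None, None, None]
                    gxm = (g * xhat).mean(axis=axes)[None, :, None, None, None]
                    x.accumulate(gb * (g - gm - xhat * gxm))
                else:
                    x.accumulate(gb * g)

        _ = m  # batch-element count folded into the means above
        return Tensor.make(out_data, (x, gamma, beta), bwd)
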