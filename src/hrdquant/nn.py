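"""Minimal reverse-mode autodiff engine and CNN layers on NumPy.

Just enough machinery for the segmentation network: 2D convolution with
dilation (shift-and-matmul), batch norm, 2x2 max-pooling, nearest
upsampling, channel concatenation, fully connected layers, softmax /
cross-entropy and soft-Dice losses, and SGD with momentum and weight
decay. Gradients are verified against finite differences in the test
suite.

All tensors are float32, NCHW layout for images.
"""

from __future__ import annotations

import numpy as np

#: Engine dtype. float32 for speed; tests switch to float64 for
#: finite-difference gradient checks.
DTYPE = np.float32

# ---------------------------------------------------------------- autograd


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() needs a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = np.asarray(g, dtype=DTYPE)
        self.grad = g if self.grad is None else self.grad + g


def _sum_to(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))
    out._backward = lambda g: (a._accum(_sum_to(g, a.shape)), b._accum(_sum_to(g, b.shape)))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))
    out._backward = lambda g: (a._accum(_sum_to(g * b.data, a.shape)),
                               b._accum(_sum_to(g * a.data, b.shape)))
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, (a,))
    out._backward = lambda g: a._accum(g * c)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: a._accum(g * mask)
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))
    out._backward = lambda g: a._accum(g * s * (1.0 - s))
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))
    out._backward = lambda g: (a._accum(g @ b.data.T), b._accum(a.data.T @ g))
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padding 2D convolution, square kernel, stride 1.

    x (N,C,H,W), w (O,C,k,k), b (O,). Padding = dilation*(k-1)//2, so odd
    kernels preserve the spatial shape at any dilation.
    """
    k = w.shape[-1]
    d = dilation
    pad = d * (k - 1) // 2
    N, C, H, W = x.shape
    O = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((N, H, W, O), dtype=x.data.dtype)
    for i in range(k):
        for j in range(k):
            shift = xp[:, :, i * d:i * d + H, j * d:j * d + W]
            out += np.tensordot(shift, w.data[:, :, i, j], axes=([1], [1]))
    out = out.transpose(0, 3, 1, 2) + b.data[None, :, None, None]
    res = Tensor(out, (x, w, b))

    def backward(g):
        b._accum(g.sum(axis=(0, 2, 3)))
        gt = g.transpose(0, 2, 3, 1)  # (N,H,W,O)
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for i in range(k):
                for j in range(k):
                    shift = xp[:, :, i * d:i * d + H, j * d:j * d + W]
                    dw[:, :, i, j] = np.tensordot(gt, shift, axes=([0, 1, 2], [0, 2, 3]))
            w._accum(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    contrib = np.tensordot(gt, w.data[:, :, i, j], axes=([3], [0]))
                    dxp[:, :, i * d:i * d + H, j * d:j * d + W] += contrib.transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp)

    res._backward = backward
    return res


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W)."""
    N, C, H, W = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
    out = Tensor(gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None],
                 (x, gamma, beta))

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gx = g * gamma.data[None, :, None, None]
        if not training:
            x._accum(gx / std[None, :, None, None])
            return
        m = N * H * W
        s = std[None, :, None, None]
        dvar = (gx * (x.data - mu[None, :, None, None])).sum(axis=(0, 2, 3)) * -0.5 * (var + eps) ** -1.5
        dmu = -(gx / s).sum(axis=(0, 2, 3)) + dvar * -2.0 * (x.data - mu[None, :, None, None]).mean(axis=(0, 2, 3))
        dx = (gx / s
              + dvar[None, :, None, None] * 2.0 * (x.data - mu[None, :, None, None]) / m
              + dmu[None, :, None, None] / m)
        x._accum(dx)

    out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H // 2, W // 2, 4)
    idx = xr.argmax(axis=-1)
    out = Tensor(np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0], (x,))

    def backward(g):
        gr = np.zeros_like(xr)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = gr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        x._accum(gx)

    out._backward = backward
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def backward(g):
        N, C, H2, W2 = g.shape
        x._accum(g.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)))

    out._backward = backward
    return out


def concat_channels(parts: list[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), tuple(parts))
    sizes = [p.shape[1] for p in parts]

    def backward(g):
        start = 0
        for p, c in zip(parts, sizes):
            p._accum(g[:, start:start + c])
            start += c

    out._backward = backward
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) spatial mean."""
    N, C, H, W = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), (x,))
    out._backward = lambda g: x._accum(
        np.broadcast_to(g[:, :, None, None], x.shape) / (H * W))
    return out


def channel_gate(x: Tensor, gate: Tensor) -> Tensor:
    """Multiply (N,C,H,W) by a per-channel gate (N,C)."""
    out = Tensor(x.data * gate.data[:, :, None, None], (x, gate))
    out._backward = lambda g: (x._accum(g * gate.data[:, :, None, None]),
                               gate._accum((g * x.data).sum(axis=(2, 3))))
    return out


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, (x,))

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accum(p * (g - dot))

    out._backward = backward
    return out


def cross_entropy_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixel-wise cross-entropy; logits (N,K,H,W), target (N,H,W) ints."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    N, K, H, W = logits.shape
    onehot = np.eye(K, dtype=logits.data.dtype)[target].transpose(0, 3, 1, 2)
    loss = float(-(onehot * np.log(p + 1e-12)).sum() / (N * H * W))
    out = Tensor(loss, (logits,))
    out._backward = lambda g: logits._accum(g * (p - onehot) / (N * H * W))
    return out


def sum_all(x: Tensor) -> Tensor:
    out = Tensor(x.data.sum(), (x,))
    out._backward = lambda g: x._accum(np.broadcast_to(g, x.shape).copy())
    return out


def soft_dice_loss(logits: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice of the foreground channel against a binary target."""
    p = softmax_channels(logits)
    fg = Tensor(np.asarray(target > 0, dtype=DTYPE))
    pf = Tensor(p.data[:, 1], (p,))
    pf._backward = lambda g: p._accum(
        np.stack([np.zeros_like(g), g], axis=1))
    inter = sum_all(mul(pf, fg))
    denom = sum_all(pf).data + fg.data.sum() + eps
    # loss = 1 - (2*inter + eps)/denom_sym where denom also depends on pf
    s = sum_all(pf)
    num = add(scale(inter, 2.0), Tensor(eps))
    den_val = s.data + fg.data.sum() + eps
    out = Tensor(1.0 - num.data / den_val, (num, s))

    def backward(g):
        num._accum(-g / den_val)
        s._accum(g * num.data / den_val ** 2)

    out._backward = backward
    del denom
    return out


# ---------------------------------------------------------------- modules


class Module:
    """Lightweight parameter container with recursive discovery."""

    training = True

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and BN running stats."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"bn_{j}_mean"] = m.running["mean"]
                out[f"bn_{j}_var"] = m.running["var"]
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=DTYPE)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running["mean"] = np.asarray(state[f"bn_{j}_mean"], dtype=DTYPE)
                m.running["var"] = np.asarray(state[f"bn_{j}_var"], dtype=DTYPE)


def _kaiming(rng, shape, fan_in):
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, dilation=1):
        self.dilation = dilation
        self.w = _kaiming(rng, (c_out, c_in, k, k), c_in * k * k)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return conv2d(x, self.w, self.b, self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running = {"mean": np.zeros(c, dtype=DTYPE),
                        "var": np.ones(c, dtype=DTYPE)}

    def __call__(self, x):
        return batchnorm2d(x, self.gamma, self.beta, self.running, self.training)


class ConvBNReLU(Module):
    def __init__(self, rng, c_in, c_out, k=3, dilation=1):
        self.conv = Conv2d(rng, c_in, c_out, k, dilation)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x):
        return relu(self.bn(self.conv(x)))


class Linear(Module):
    def __init__(self, rng, c_in, c_out):
        self.w = _kaiming(rng, (c_in, c_out), c_in)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return add(matmul(x, self.w), self.b)


class SGD:
    """SGD with classical momentum and decoupled-from-nothing weight decay
    (decay is added to the raw gradient, the conventional form)."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
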