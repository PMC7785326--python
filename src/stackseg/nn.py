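"""Minimal CPU neural-network layers with explicit backpropagation.

Everything the segmentation network needs — 2-D convolution, batch
normalization, ReLU, max pooling, pixel shuffle — implemented directly on
numpy arrays with hand-derived backward passes, plus SGD and Adam
optimizers.  Convolutions are evaluated as a sum of K*K strided
tensor contractions (one per kernel tap), which maps onto BLAS matmuls
and avoids materializing im2col buffers.

Layers cache what their backward pass needs during forward; each layer
instance therefore appears exactly once in a network graph.  Correctness
of every backward pass is pinned by finite-difference gradient checks in
the test suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with an accumulated gradient and a freeze flag."""

    __slots__ = ("data", "grad", "name", "trainable")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name
        self.trainable = True

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.data.shape})"


class Module:
    """Base class: owns parameters, children, and train/freeze state."""

    def __init__(self):
        self._params: list[Param] = []
        self._children: list[Module] = []
        self.training = True
        self.trainable = True

    def add_param(self, data: np.ndarray, name: str) -> Param:
        p = Param(data, name)
        self._params.append(p)
        return p

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Param]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for c in self._children:
            c.set_training(flag)

    def set_trainable(self, flag: bool) -> None:
        """Freeze/unfreeze this subtree (params and BN statistics)."""
        self.trainable = flag
        for p in self._params:
            p.trainable = flag
        for c in self._children:
            c.set_trainable(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    """2-D convolution (cross-correlation), optional bias, He init."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = self.add_param(
            rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32), "w")
        self.b = self.add_param(np.zeros(cout, dtype=np.float32), "b") if bias else None
        self._cache = None

    def out_shape(self, H: int, W: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        k, s, p = self.k, self.stride, self.pad
        Ho, Wo = self.out_shape(H, W)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        out = np.zeros((N, self.cout, Ho, Wo), dtype=np.result_type(x, self.w.data))
        for i in range(k):
            for j in range(k):
                view = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                out += np.tensordot(self.w.data[:, :, i, j], view,
                                    axes=([1], [1])).transpose(1, 0, 2, 3)
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        self._cache = (xp, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape = self._cache
        N, C, H, W = x_shape
        k, s, p = self.k, self.stride, self.pad
        Ho, Wo = dout.shape[2], dout.shape[3]
        dxp = np.zeros_like(xp, dtype=np.result_type(dout, self.w.data))
        for i in range(k):
            for j in range(k):
                view = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
                self.w.grad[:, :, i, j] += np.tensordot(
                    dout, view, axes=([0, 2, 3], [0, 2, 3]))
                dview = np.tensordot(self.w.data[:, :, i, j], dout,
                                     axes=([0], [1]))  # (cin, N, Ho, Wo)
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dview.transpose(1, 0, 2, 3)
        if self.b is not None:
            self.b.grad += dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:p + H, p:p + W]
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    When the module is frozen (``trainable == False``) or in eval mode it
    normalizes with running statistics and leaves them untouched, so a
    frozen encoder is genuinely inert.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.add_param(np.ones(c, dtype=np.float32), "gamma")
        self.beta = self.add_param(np.zeros(c, dtype=np.float32), "beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        use_batch = self.training and self.trainable
        if use_batch:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, use_batch)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, use_batch = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None] * ivar[None, :, None, None]
        if not use_batch:
            return dout * g
        N, C, H, W = dout.shape
        m = N * H * W
        s1 = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g / m * (m * dout - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2d(Module):
    """Max pooling (default 3x3 stride 2 pad 1, the ResNet stem pool)."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        Hp, Wp = xp.shape[2], xp.shape[3]
        Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        flat = win.reshape(N, C, Ho, Wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, (N, C, H, W), (Hp, Wp), (Ho, Wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (N, C, H, W), (Hp, Wp), (Ho, Wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros((N, C, Hp, Wp), dtype=dout.dtype)
        # flat index of each window's argmax inside the padded array
        oy, ox = np.meshgrid(np.arange(Ho), np.arange(Wo), indexing="ij")
        py = oy[None, None] * s + arg // k
        px = ox[None, None] * s + arg % k
        n_idx = np.arange(N)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        flat_idx = (((n_idx * C + c_idx) * Hp + py) * Wp + px)
        np.add.at(dxp.reshape(-1), flat_idx.ravel(), dout.ravel())
        return dxp[:, :, p:p + H, p:p + W]


def pixel_shuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Rearrange (N, C*r^2, H, W) -> (N, C, r*H, r*W).

    Pure index permutation: ``out[c, r*h+a, r*w+b] = in[c*r^2+a*r+b, h, w]``.
    Also accepts unbatched (C, H, W) input.
    """
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    N, C, H, W = x.shape
    if C % (r * r) != 0:
        raise ValueError(f"channel count {C} not divisible by r^2={r * r}")
    c = C // (r * r)
    out = (x.reshape(N, c, r, r, H, W)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, c, H * r, W * r))
    return out[0] if squeeze else out


def pixel_unshuffle(x: np.ndarray, r: int) -> np.ndarray:
    """Inverse of :func:`pixel_shuffle`."""
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    N, c, Hr, Wr = x.shape
    if Hr % r or Wr % r:
        raise ValueError(f"spatial dims {Hr}x{Wr} not divisible by r={r}")
    H, W = Hr // r, Wr // r
    out = (x.reshape(N, c, H, r, W, r)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(N, c * r * r, H, W))
    return out[0] if squeeze else out


class PixelShuffle(Module):
    def __init__(self, r: int):
        super().__init__()
        self.r = r

    def forward(self, x: np.ndarray) -> np.ndarray:
        return pixel_shuffle(x, self.r)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return pixel_unshuffle(dout, self.r)


class ConvBNReLU(Module):
    """conv -> batchnorm -> relu, the workhorse trio."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = self.add_child(Conv2d(cin, cout, k, stride, bias=False, rng=rng))
        self.bn = self.add_child(BatchNorm2d(cout))
        self.relu = self.add_child(ReLU())

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class BasicBlock(Module):
    """ResNet basic block: two 3x3 convs with an identity shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = self.add_child(Conv2d(cin, cout, 3, stride, bias=False, rng=rng))
        self.bn1 = self.add_child(BatchNorm2d(cout))
        self.relu1 = self.add_child(ReLU())
        self.conv2 = self.add_child(Conv2d(cout, cout, 3, 1, bias=False, rng=rng))
        self.bn2 = self.add_child(BatchNorm2d(cout))
        self.relu2 = self.add_child(ReLU())
        if stride != 1 or cin != cout:
            self.down_conv = self.add_child(
                Conv2d(cin, cout, 1, stride, pad=0, bias=False, rng=rng))
            self.down_bn = self.add_child(BatchNorm2d(cout))
        else:
            self.down_conv = self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.bn2.forward(self.conv2.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        idn = x if self.down_conv is None \
            else self.down_bn.forward(self.down_conv.forward(x))
        return self.relu2.forward(y + idn)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dx_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        if self.down_conv is None:
            return dx_main + d
        return dx_main + self.down_conv.backward(self.down_bn.backward(d))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = [self.add_child(l) for l in layers]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class SGD:
    """Plain (optionally momentum-free) stochastic gradient descent."""

    def __init__(self, groups: list[list[Param]], momentum: float = 0.0):
        self.groups = groups
        self.momentum = momentum
        self._vel = [[np.zeros_like(p.data) for p in g] for g in groups]

    def step(self, lrs) -> None:
        lrs = self._expand(lrs)
        for g, vels, lr in zip(self.groups, self._vel, lrs):
            for p, v in zip(g, vels):
                if not p.trainable:
                    continue
                if self.momentum:
                    v *= self.momentum
                    v += p.grad
                    upd = v
                else:
                    upd = p.grad
                p.data = (p.data - lr * upd).astype(p.data.dtype)

    def _expand(self, lrs):
        if np.isscalar(lrs):
            return [float(lrs)] * len(self.groups)
        if len(lrs) != len(self.groups):
            raise ValueError(f"{len(lrs)} lrs for {len(self.groups)} groups")
        return lrs


class Adam:
    """Adam with decoupled weight decay (wd = 0 by default)."""

    def __init__(self, groups: list[list[Param]], betas=(0.9, 0.99),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self._m = [[np.zeros_like(p.data) for p in g] for g in groups]
        self._v = [[np.zeros_like(p.data) for p in g] for g in groups]
        self._t = 0

    def step(self, lrs) -> None:
        if np.isscalar(lrs):
            lrs = [float(lrs)] * len(self.groups)
        elif len(lrs) != len(self.groups):
            raise ValueError(f"{len(lrs)} lrs for {len(self.groups)} groups")
        self._t += 1
        bc1 = 1.0 - self.b1 ** self._t
        bc2 = 1.0 - self.b2 ** self._t
        for g, ms, vs, lr in zip(self.groups, self._m, self._v, lrs):
            for p, m, v in zip(g, ms, vs):
                if not p.trainable:
                    continue
                grad = p.grad
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                mhat = m / bc1
                vhat = v / bc2
                upd = mhat / (np.sqrt(vhat) + self.eps)
                if self.wd:
                    upd = upd + self.wd * p.data
                p.data = (p.data - lr * upd).astype(p.data.dtype)
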