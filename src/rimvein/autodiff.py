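"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the patch network needs: 3-D convolution
(stride 1, padding 1, 3x3x3 kernels, evaluated as im2col GEMMs), batch
normalization, 2x2x2 max pooling, nearest-neighbour upsampling, linear layers,
ReLU/sigmoid, dropout, global average pooling and concatenation, plus the two
loss functions used in training.  Network activations are float32 throughout;
loss scalars are accumulated in float64 and their backward pass casts gradients
back to float32.

Gradients flow through a tape-free graph: each `Tensor` remembers its parents
and a closure mapping the upstream gradient to parent gradients; `backward`
runs a topological sweep and accumulates gradients on leaf tensors (the
parameters).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "Linear",
    "Adam",
    "relu",
    "sigmoid",
    "dropout",
    "max_pool3d",
    "upsample_nearest3d",
    "global_avg_pool3d",
    "concat",
    "weighted_mse_loss",
    "masked_bce_loss",
]


_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode): ops
    return plain Tensors, so intermediate activations free as soon as they
    go out of scope."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (),
                 backward: Callable | None = None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        if not _grad_enabled:
            parents, backward, requires_grad = (), None, False
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable leaf's ``.grad``.

        The graph is dismantled while it is swept (each node's parent links
        and closure are dropped once its gradient has been propagated), so
        activation memory is released progressively; a graph can therefore be
        backpropagated only once.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    k = id(parent)
                    grads[k] = pg if k not in grads else grads[k] + pg
            node._backward = None
            node._parents = ()


# ---------------------------------------------------------------------------
# modules

class Module:
    """Container with named parameters (leaf Tensors) and buffers (arrays)."""

    training: bool = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def _modules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def train(self, flag: bool = True):
        self.training = flag
        for m in self._modules():
            m.train(flag)
        return self

    def eval(self):
        return self.train(False)


_SCRATCH_BUFFERS: dict[str, np.ndarray] = {}


def _scratch(name: str, shape: tuple) -> np.ndarray:
    """A float32 scratch array reused across calls (grown as needed).  Valid
    only until the next request under the same name."""
    need = int(np.prod(shape))
    buf = _SCRATCH_BUFFERS.get(name)
    if buf is None or buf.size < need:
        buf = np.empty(need, np.float32)
        _SCRATCH_BUFFERS[name] = buf
    return buf[:need].reshape(shape)


class Conv3d(Module):
    """3x3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    # cap on the transient im2col buffer, in float32 elements (~128 MB)
    CHUNK_ELEMS = 32_000_000

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 27
        w = rng.standard_normal((out_channels, in_channels, 3, 3, 3)) * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32), requires_grad=True)

    @staticmethod
    def _to_cols(xp: np.ndarray, D: int, H: int, W: int) -> np.ndarray:
        # xp: (n, C, D+2, H+2, W+2) -> (n, C*27, D*H*W); columns ordered
        # (channel, offset) to match weight.reshape(O, C*27).  Filled by 27
        # strided block copies into a reused scratch buffer (repeatedly
        # allocating ~100 MB buffers costs more in page faults than the copy).
        n, C = xp.shape[0], xp.shape[1]
        cols = _scratch("cols", (n, C, 27, D, H, W))
        idx = 0
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    np.copyto(cols[:, :, idx], xp[:, :, i:i + D, j:j + H, k:k + W])
                    idx += 1
        return cols.reshape(n, C * 27, D * H * W)

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        N, C, D, H, W = xd.shape
        O = self.out_channels
        wm = self.weight.data.reshape(O, -1)  # (O, C*27)

        def _padded(src):
            xp = _scratch("xp", (N, C, D + 2, H + 2, W + 2))
            xp.fill(0.0)
            xp[:, :, 1:-1, 1:-1, 1:-1] = src
            return xp

        xp = _padded(xd)
        vox = D * H * W
        chunk = max(1, self.CHUNK_ELEMS // max(1, C * 27 * vox))
        out = np.empty((N, O, D, H, W), np.float32)
        for n0 in range(0, N, chunk):
            n1 = min(N, n0 + chunk)
            cols = self._to_cols(xp[n0:n1], D, H, W)
            np.matmul(wm, cols, out=out[n0:n1].reshape(n1 - n0, O, vox))
        out += self.bias.data.reshape(1, O, 1, 1, 1)

        def bwd(g):
            g_flat = g.reshape(N, O, vox)
            xpb = _padded(x.data)      # rebuilt rather than held since forward
            need_dx = x.requires_grad
            dxp = np.zeros_like(xpb) if need_dx else None
            dw = np.zeros((O, C * 27), np.float64)
            db = g.sum(axis=(0, 2, 3, 4), dtype=np.float64)
            for m0 in range(0, N, chunk):
                m1 = min(N, m0 + chunk)
                cols = self._to_cols(xpb[m0:m1], D, H, W)
                gc = g_flat[m0:m1]
                dw += np.matmul(gc, cols.transpose(0, 2, 1)).sum(axis=0)
                if not need_dx:
                    continue
                dcols = np.matmul(wm.T, gc,
                                  out=_scratch("dcols", (m1 - m0, C * 27, vox)))
                dcols = dcols.reshape(m1 - m0, C, 27, D, H, W)
                # scatter per sample so the target window stays cache-resident
                # (27 whole-batch passes would be memory-bandwidth bound)
                for m in range(m1 - m0):
                    dst = dxp[m0 + m]
                    idx = 0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                dst[:, i:i + D, j:j + H, k:k + W] += dcols[m, :, idx]
                                idx += 1
            dx = dxp[:, :, 1:-1, 1:-1, 1:-1] if need_dx else None
            return [dx, dw.astype(np.float32).reshape(self.weight.shape),
                    db.astype(np.float32)]

        return Tensor(out, parents=(x, self.weight, self.bias), backward=bwd)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        xd = x.data
        axes = (0, 2, 3, 4)
        sh = (1, -1, 1, 1, 1)
        count = xd.size // xd.shape[1]
        if self.training:
            mean = xd.mean(axis=axes)
            # one-pass variance (values are z-scored O(1), so the naive
            # sum-of-squares form is adequate)
            sq = np.einsum("ncdhw,ncdhw->c", xd, xd, optimize=False) / count
            var = np.maximum(sq - mean.astype(np.float64) ** 2, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        # single fused pass: out = x * scale + shift; xhat is recomputed
        # lazily in backward rather than stored
        scale = self.gamma.data * invstd
        shift = self.beta.data - mean * scale
        out = xd * scale.reshape(sh)
        out += shift.reshape(sh)
        training = self.training

        def bwd(g):
            xhat = xd - mean.reshape(sh)
            xhat *= invstd.reshape(sh)
            dgamma = np.einsum("ncdhw,ncdhw->c", g, xhat, optimize=False).astype(np.float32)
            dbeta = g.sum(axis=axes)
            gi = self.gamma.data * invstd
            if training:
                # dx = gi*g - gi*mean(g) - xhat*gi*mean(g*xhat), fused in-place
                dx = g * gi.reshape(sh)
                dx -= (gi * dbeta / count).reshape(sh)
                xhat *= (gi * dgamma / count).reshape(sh)
                dx -= xhat
            else:
                dx = g * gi.reshape(sh)
            return [dx, dgamma, dbeta]

        return Tensor(out, parents=(x, self.gamma, self.beta), backward=bwd)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.standard_normal((out_features, in_features)) * np.sqrt(2.0 / in_features)
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        out = x.data @ self.weight.data.T + self.bias.data

        def bwd(g):
            return [g @ self.weight.data,
                    g.T @ x.data,
                    g.sum(axis=0)]

        return Tensor(out, parents=(x, self.weight, self.bias), backward=bwd)


# ---------------------------------------------------------------------------
# stateless ops

def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0)
    return Tensor(out, parents=(x,), backward=lambda g: [g * (x.data > 0)])


def sigmoid(x: Tensor) -> Tensor:
    out = _stable_sigmoid(x.data)
    return Tensor(out, parents=(x,), backward=lambda g: [g * out * (1 - out)])


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape, dtype=np.float32) >= p).astype(x.data.dtype) / (1.0 - p)
    out = x.data * keep
    return Tensor(out, parents=(x,), backward=lambda g: [g * keep])


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; ties resolved to the first voxel."""
    N, C, D, H, W = x.shape
    pooled_shape = (N, C, D // 2, H // 2, W // 2, 8)
    xr = _scratch("pool", pooled_shape)
    np.copyto(xr.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2),
              x.data.reshape(N, C, D // 2, 2, H // 2, 2, W // 2, 2).transpose(
                  0, 1, 2, 4, 6, 3, 5, 7))
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxr = np.zeros(pooled_shape, np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(N, C, D // 2, H // 2, W // 2, 2, 2, 2)
        dx = dx.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(N, C, D, H, W)
        return [np.ascontiguousarray(dx)]

    return Tensor(out, parents=(x,), backward=bwd)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 along each spatial axis."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    N, C, D, H, W = x.shape

    def bwd(g):
        return [g.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))]

    return Tensor(out, parents=(x,), backward=bwd)


def global_avg_pool3d(x: Tensor) -> Tensor:
    N, C, D, H, W = x.shape
    out = x.data.mean(axis=(2, 3, 4))
    scale = 1.0 / (D * H * W)

    def bwd(g):
        return [np.broadcast_to(g[:, :, None, None, None] * scale, x.shape).astype(x.data.dtype)]

    return Tensor(out, parents=(x,), backward=bwd)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return np.split(g, splits, axis=axis)

    return Tensor(out, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# losses (float64 scalars, float32 gradients)

def weighted_mse_loss(recon: Tensor, target: np.ndarray, weights: np.ndarray) -> Tensor:
    """Sum(w * (r - t)^2) / Sum(w)."""
    diff = recon.data.astype(np.float64) - np.asarray(target, np.float64)
    w = np.asarray(weights, np.float64)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weight map sums to zero")
    val = (w * diff * diff).sum() / wsum

    def bwd(g):
        return [(g * 2.0 * w * diff / wsum).astype(np.float32)]

    return Tensor(np.float64(val), parents=(recon,), backward=bwd)


def masked_bce_loss(pred: Tensor, targets: np.ndarray, weights: np.ndarray) -> Tensor:
    """Mean over rows of the weight-masked binary cross-entropy.

    ``weights`` entries of exactly 0 contribute zero loss and exactly zero
    gradient, so components with missing or "unsure" labels cannot move any
    parameter.
    """
    p = pred.data.astype(np.float64)
    y = np.asarray(targets, np.float64)
    w = np.asarray(weights, np.float64)
    eps = 1e-12
    pc = np.clip(p, eps, 1.0 - eps)
    bce = -(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    n = max(1, p.shape[0]) if p.ndim > 0 else 1
    val = (w * bce).sum() / n

    def bwd(g):
        dp = w * (pc - y) / (pc * (1.0 - pc)) / n
        return [(g * dp).astype(np.float32)]

    return Tensor(np.float64(val), parents=(pred,), backward=bwd)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.data.dtype)
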