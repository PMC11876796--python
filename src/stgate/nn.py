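"""Neural-network building blocks on top of :mod:`stgate.autodiff`.

Modules hold named :class:`~stgate.autodiff.Tensor` parameters and expose
``parameters()`` returning a flat ``{name: Tensor}`` dict so the optimizer and
the checkpoint format stay trivial.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, concatenate


# --------------------------------------------------------------------- modules
class Module:
    """Parameter container with recursive discovery of sub-modules."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for key, val in self.__dict__.items():
            name = f"{prefix}{key}"
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                params.update(val.parameters(prefix=name + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        params.update(item.parameters(prefix=f"{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params[f"{name}.{i}"] = item
        return params

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")
        for name, tensor in params.items():
            arr = np.asarray(state[name])
            if arr.shape != tensor.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} "
                    f"vs model {tensor.data.shape}")
            tensor.data = arr.astype(tensor.data.dtype, copy=True)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def astype(self, dtype) -> "Module":
        """Convert every parameter in place (e.g. float32 for training)."""
        for p in self.parameters().values():
            p.data = p.data.astype(dtype)
        return self


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple | None = None) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 bias: bool = True):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class MLP(Module):
    """Perceptron with ReLU between layers; ``dims = [d_in, ..., d_out]``."""

    def __init__(self, rng: np.random.Generator, dims: list[int]):
        self.layers = [Linear(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class LayerNorm(Module):
    """Normalize over the last axis, then affine."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        norm = centered * ((var + self.eps) ** -0.5)
        return norm * self.gamma + self.beta


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax as one fused op; ``mask`` (False =
    excluded) zeroes the weight.  Only the output is retained for backward:
    d_scores = α ⊙ (g − Σ α·g).
    """
    data = x.data
    if mask is not None:
        data = data + np.where(mask, 0.0, -1e30).astype(data.dtype)
    e = np.exp(data - np.max(data, axis=axis, keepdims=True))
    alpha = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(alpha, parents=(x,))

    def bw(g):
        inner = (alpha * g).sum(axis=axis, keepdims=True)
        x._accum(alpha * (g - inner))
    out._backward = bw if out.requires_grad else None
    return out


def sinusoidal_positions(T: int, d: int) -> np.ndarray:
    """Standard sinusoidal positional encodings, shape (T, d)."""
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class TemporalSelfAttention(Module):
    """Multi-head self-attention along the time axis of (..., T, d) input."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int):
        if d % n_heads:
            raise ValueError(f"d={d} not divisible by n_heads={n_heads}")
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.wo = Linear(rng, d, d)
        self.n_heads = n_heads
        self.d = d

    def _split(self, x: Tensor) -> Tensor:
        # (..., T, d) -> (..., h, T, dh)
        *lead, T, d = x.shape
        h = self.n_heads
        return x.reshape(*lead, T, h, d // h).swapaxes(-2, -3)

    def __call__(self, x: Tensor, causal: bool = False) -> Tensor:
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        dh = self.d // self.n_heads
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        mask = None
        if causal:  # keys restricted to t' <= t
            T = x.shape[-2]
            mask = np.tril(np.ones((T, T), dtype=bool))
        attn = softmax(scores, axis=-1, mask=mask)
        out = attn @ v  # (..., h, T, dh)
        *lead, h, T, _ = out.shape
        out = out.swapaxes(-2, -3).reshape(*lead, T, self.d)
        return self.wo(out)


class TransformerLayer(Module):
    """Post-norm transformer encoder layer (attention + feedforward)."""

    def __init__(self, rng: np.random.Generator, d: int, n_heads: int,
                 d_ff: int | None = None):
        d_ff = d_ff or 4 * d
        self.attn = TemporalSelfAttention(rng, d, n_heads)
        self.ff = MLP(rng, [d, d_ff, d])
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)

    def __call__(self, x: Tensor, causal: bool = False) -> Tensor:
        x = self.ln1(x + self.attn(x, causal=causal))
        return self.ln2(x + self.ff(x))


# ------------------------------------------------------------------- optimizer
class Adam:
    """Adam, with an optional plain-SGD parameter group.

    Parameters named in ``sgd_group`` are updated by unscaled gradient
    descent at ``sgd_lr`` instead of Adam.  The causal-gate scorer uses this:
    its convergence analysis compares gradient *magnitudes* against the l1
    coefficient, a comparison Adam's per-coordinate normalization erases.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 8e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 sgd_group: set[str] | None = None, sgd_lr: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.sgd_group = sgd_group or set()
        self.sgd_lr = sgd_lr
        adam_keys = [k for k in params if k not in self.sgd_group]
        self.m = {k: np.zeros_like(params[k].data) for k in adam_keys}
        self.v = {k: np.zeros_like(params[k].data) for k in adam_keys}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self, lr: float | None = None, lr_scale: float = 1.0):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            if k in self.sgd_group:
                p.data = p.data - (self.sgd_lr * lr_scale) * p.grad
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, epoch: int, max_epochs: int) -> float:
    """Cosine-annealed learning rate over the epoch budget."""
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max(max_epochs, 1)))


def concat_last(a: Tensor, b: Tensor) -> Tensor:
    return concatenate([a, b], axis=-1)
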