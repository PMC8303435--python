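"""Layer abstractions over the autodiff engine: modules, convolutions,
weighted feature fusion and the bottleneck-transformer attention block."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Container with named parameters and submodules (torch-like, minimal)."""

    def _children(self) -> Iterator[Tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 padding: Optional[int] = None, bias: bool = True):
        self.padding = (k // 2) if padding is None else padding
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, padding=self.padding)


class ConvReLU(Module):
    def __init__(self, cin, cout, k, rng, bias=True):
        self.conv = Conv2d(cin, cout, k, rng, bias=bias)

    def forward(self, x):
        return T.relu(self.conv(x))


class WeightedFusion(Module):
    """Fast normalized fusion: out = sum_i relu(w_i) x_i / (eps + sum_i relu(w_i)).

    The raw weights are learned; relu enforces non-negativity and the epsilon
    guard keeps the division defined when every weight collapses to zero.
    """

    def __init__(self, n_inputs: int, eps: float = 1e-4):
        if n_inputs < 2:
            raise ValueError("fusion needs at least two inputs")
        self.n_inputs = n_inputs
        self.eps = float(eps)
        self.weights = Tensor(np.ones(n_inputs, np.float32), requires_grad=True)

    def normalized_weights(self) -> np.ndarray:
        w = np.maximum(self.weights.data, 0.0)
        return w / (self.eps + w.sum())

    def forward(self, inputs: Sequence[Tensor]) -> Tensor:
        if len(inputs) != self.n_inputs:
            raise ValueError(f"expected {self.n_inputs} inputs, got {len(inputs)}")
        shape = inputs[0].shape
        for t in inputs[1:]:
            if t.shape != shape:
                raise ValueError(f"fusion input shape mismatch: {t.shape} vs {shape}")
        w = T.relu(self.weights)
        denom = T.pow_scalar(T.tsum(w) + Tensor(self.eps), -1.0)
        out = None
        for i, x in enumerate(inputs):
            wi = T.reshape(w, (self.n_inputs,))  # keep graph shared
            coeff = T.mul(T.reshape(slice_index(wi, i), ()), denom)
            term = scale_by_scalar_tensor(x, coeff)
            out = term if out is None else T.add(out, term)
        return out


def slice_index(v: Tensor, i: int) -> Tensor:
    """Pick element i of a 1-D tensor, keeping the graph."""
    data = v.data[i : i + 1]

    def backward(g):
        gv = np.zeros_like(v.data)
        gv[i : i + 1] = g
        v._accumulate(gv)

    return T._make(data, (v,), backward)


def scale_by_scalar_tensor(x: Tensor, s: Tensor) -> Tensor:
    data = x.data * s.data

    def backward(g):
        x._accumulate(g * s.data)
        s._accumulate(np.asarray((g * x.data).sum(), np.float32).reshape(s.shape))

    return T._make(data, (x, s), backward)


def fuse_features(inputs: Sequence[Tensor], weights: Sequence[float], eps: float = 1e-4) -> Tensor:
    """Functional fast-normalized fusion with fixed (already non-negative
    transformed) weights — the arithmetic core used by :class:`WeightedFusion`."""
    w = np.maximum(np.asarray(weights, np.float32), 0.0)
    denom = eps + w.sum()
    out = None
    for wi, x in zip(w, inputs):
        term = T.mul_scalar(x, float(wi / denom))
        out = term if out is None else T.add(out, term)
    return out


class MultiHeadSelfAttention2d(Module):
    """Global multi-head self-attention over all spatial positions of a map,
    with learned relative height/width position encodings (content-position
    term added to the content-content logits)."""

    def __init__(self, channels: int, heads: int, h: int, w: int, rng: np.random.Generator):
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        if h * w > 4096:
            raise ValueError(
                f"attention over {h}x{w}={h*w} positions exceeds the 4096 cap; "
                "use a deeper pyramid so P5 is smaller"
            )
        self.heads = heads
        self.h, self.w = h, w
        d = channels // heads
        self.d = d
        self.wq = Conv2d(channels, channels, 1, rng, bias=False)
        self.wk = Conv2d(channels, channels, 1, rng, bias=False)
        self.wv = Conv2d(channels, channels, 1, rng, bias=False)
        self.rel_h = Tensor((rng.standard_normal((2 * h - 1, d)) * 0.02).astype(np.float32),
                            requires_grad=True)
        self.rel_w = Tensor((rng.standard_normal((2 * w - 1, d)) * 0.02).astype(np.float32),
                            requires_grad=True)

    def _split(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        # (N, heads, d, HW) -> (N*heads, HW, d)
        y = T.reshape(x, (n, self.heads, self.d, h * w))
        y = T.transpose(y, (0, 1, 3, 2))
        return T.reshape(y, (n * self.heads, h * w, self.d))

    def attention(self, x: Tensor) -> Tensor:
        """Row-stochastic attention matrix, shape (N*heads, HW, HW)."""
        q = self._split(self.wq(x))
        k = self._split(self.wk(x))
        logits = T.mul_scalar(T.matmul(q, T.transpose(k, (0, 2, 1))), 1.0 / np.sqrt(self.d))
        rel = T.relative_logits(q, self.rel_h, self.rel_w, self.h, self.w)
        return T.softmax(T.add(logits, rel), axis=-1)

    def forward(self, x: Tensor, attn_override: Optional[np.ndarray] = None) -> Tensor:
        n, c, h, w = x.shape
        v = self._split(self.wv(x))
        attn = Tensor(attn_override) if attn_override is not None else self.attention(x)
        out = T.matmul(attn, v)  # (N*heads, HW, d)
        out = T.reshape(out, (n, self.heads, h * w, self.d))
        out = T.transpose(out, (0, 1, 3, 2))
        return T.reshape(out, (n, c, h, w))


class BotBlock(Module):
    """Bottleneck-transformer block: 1x1 reduce -> global MHSA (replacing the
    middle 3x3 convolution) -> 1x1 expand, with a residual connection.  Applied
    at the coarsest pyramid level only, where (h*w)^2 attention is cheap."""

    def __init__(self, channels: int, heads: int, h: int, w: int, rng: np.random.Generator):
        mid = max(heads, channels // 2)
        mid -= mid % heads
        self.reduce = Conv2d(channels, mid, 1, rng)
        self.mhsa = MultiHeadSelfAttention2d(mid, heads, h, w, rng)
        self.expand = Conv2d(mid, channels, 1, rng)

    def forward(self, x: Tensor, attn_override: Optional[np.ndarray] = None) -> Tensor:
        y = T.relu(self.reduce(x))
        y = self.mhsa(y, attn_override=attn_override)
        y = self.expand(y)
        return T.add(x, y)
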