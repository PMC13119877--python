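"""Neural-network building blocks on top of the autodiff tape.

Parameter containers follow the familiar Module pattern: parameters are
``Tensor`` leaves with ``requires_grad=True``; ``parameters()`` walks nested
modules; ``state_dict``/``load_state_dict`` serialize plain arrays keyed by
attribute path, suitable for a single ``.npz`` checkpoint.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, erf, logsumexp, where

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "Sequential",
    "gelu", "softmax", "cross_entropy", "sinusoidal_positions",
    "MultiheadSelfAttention", "TransformerEncoderLayer", "BiLSTM",
]


class Module:
    """Base class: parameter discovery, train/eval mode, checkpointing."""

    def __init__(self):
        self.training = True

    def modules(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, mod in self.modules():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, m in self.modules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            from .tensor import get_default_dtype
            p.data = np.asarray(state[k], dtype=get_default_dtype()).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, scale: float | None = None) -> Tensor:
    if scale is None:  # truncated-normal a la standard transformer init
        scale = 0.02
    w = rng.standard_normal(shape) * scale
    np.clip(w, -2 * scale, 2 * scale, out=w)
    return Tensor(w, requires_grad=True)


class Linear(Module):
    def __init__(self, rng, d_in: int, d_out: int, bias: bool = True,
                 scale: float | None = None):
        super().__init__()
        if scale is None:
            scale = 1.0 / np.sqrt(d_in)
        self.W = Tensor(rng.uniform(-scale, scale, (d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class Dropout(Module):
    """Inverted dropout; a Generator must be attached for stochastic mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        if self.rng is None:
            raise RuntimeError("stochastic dropout needs an attached rng")
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def gelu(x: Tensor) -> Tensor:
    return x * (erf(x * (1.0 / np.sqrt(2.0))) + 1.0) * 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached shift
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logits [..., C], integer labels [...]."""
    logp = logits - logsumexp(logits, axis=-1, keepdims=True)
    labels = np.asarray(labels)
    flat = logp.reshape(-1, logits.shape[-1])
    picked = flat[np.arange(flat.shape[0]), labels.reshape(-1)]
    return -picked.mean()


def sinusoidal_positions(T: int, d: int) -> np.ndarray:
    """Absolute sinusoidal position table [T, d]."""
    pos = np.arange(T)[:, None]
    i = np.arange(d // 2)[None, :]
    ang = pos / np.power(10000.0, 2 * i / d)
    pe = np.zeros((T, d))
    pe[:, 0::2] = np.sin(ang)
    pe[:, 1::2] = np.cos(ang)
    return pe


class MultiheadSelfAttention(Module):
    """Standard scaled-dot multi-head self-attention with optional additive
    logit bias (shape broadcastable to [B, H, T, T]) and key padding mask."""

    def __init__(self, rng, d_model: int, heads: int, dropout: Dropout | None = None):
        super().__init__()
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.h = heads
        self.dh = d_model // heads
        self.q = Linear(rng, d_model, d_model)
        self.k = Linear(rng, d_model, d_model)
        self.v = Linear(rng, d_model, d_model)
        self.o = Linear(rng, d_model, d_model)
        self.drop = dropout

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, bias: Tensor | np.ndarray | None = None,
                key_mask: np.ndarray | None = None) -> Tensor:
        B, T, d = x.shape
        q = self._split(self.q(x), B, T)
        k = self._split(self.k(x), B, T)
        v = self._split(self.v(x), B, T)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        if bias is not None:
            logits = logits + bias
        if key_mask is not None:  # True = valid key
            neg = np.where(key_mask[:, None, None, :], 0.0, -1e30)
            logits = logits + neg
        p = softmax(logits, axis=-1)
        if self.drop is not None:
            p = self.drop(p)
        z = (p @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        self.last_attn = p.data  # diagnostics (entropy logging)
        return self.o(z)


class TransformerEncoderLayer(Module):
    """Pre-LN block: x + MHA(LN(x)); then u + FFN(LN(u)) with GELU."""

    def __init__(self, rng, d_model: int, heads: int, d_ffn: int,
                 dropout_p: float = 0.0, drop_rng: np.random.Generator | None = None):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiheadSelfAttention(
            rng, d_model, heads,
            Dropout(dropout_p, drop_rng) if dropout_p > 0 else None)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(rng, d_model, d_ffn)
        self.ff2 = Linear(rng, d_ffn, d_model)
        self.drop = Dropout(dropout_p, drop_rng) if dropout_p > 0 else None

    def forward(self, x: Tensor, bias=None, key_mask=None) -> Tensor:
        u = x + self.attn(self.ln1(x), bias=bias, key_mask=key_mask)
        h = gelu(self.ff1(self.ln2(u)))
        if self.drop is not None:
            h = self.drop(h)
        return u + self.ff2(h)


class _LSTMCellStack(Module):
    """One direction of a (possibly multi-layer) LSTM, loop over time.

    Input projections for the whole sequence are batched outside the time
    loop; only the recurrent matmul runs per step.
    """

    def __init__(self, rng, d_in: int, hidden: int, layers: int):
        super().__init__()
        self.hidden = hidden
        self.n_layers = layers
        self.Wx = [Linear(rng, d_in if l == 0 else hidden, 4 * hidden)
                   for l in range(layers)]
        self.Wh = [Linear(rng, hidden, 4 * hidden, bias=False)
                   for l in range(layers)]

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        out = x
        for l in range(self.n_layers):
            xz = self.Wx[l](out)  # [B, T, 4H], batched over time
            h = Tensor(np.zeros((B, H)))
            c = Tensor(np.zeros((B, H)))
            hs = []
            for t in range(T):
                z = xz[:, t, :] + self.Wh[l](h)
                i = z[:, 0 * H:1 * H].sigmoid()
                f = z[:, 1 * H:2 * H].sigmoid()
                g = z[:, 2 * H:3 * H].tanh()
                o = z[:, 3 * H:4 * H].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                hs.append(h)
            out = stack_time(hs)
        return out


def stack_time(tensors) -> Tensor:
    from .tensor import stack
    return stack(tensors, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM: forward and reversed stacks, concatenated."""

    def __init__(self, rng, d_in: int, hidden: int, layers: int):
        super().__init__()
        self.fwd = _LSTMCellStack(rng, d_in, hidden, layers)
        self.bwd = _LSTMCellStack(rng, d_in, hidden, layers)

    def forward(self, x: Tensor) -> Tensor:
        y_f = self.fwd(x)
        rev = x[:, ::-1, :]
        y_b = self.bwd(rev)[:, ::-1, :]
        return concatenate([y_f, y_b], axis=-1)
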