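"""Cross-modal temporal alignment attention.

Visual (skeleton) tokens act as the temporal anchor: for each anchor time
step *t* a query attends over sensor tokens in the local neighborhood
``Omega_t = [t-W, t+W]``.  A learnable per-modality scalar offset ``delta``
enters through a continuous-lag relative-position bias: the logit for
lag ``l = k - t`` is

    Q_t . K_k / sqrt(d_h)  +  R(-l - delta)

where ``R`` is a learnable per-head table over integer lags, evaluated at
the fractional position by linear interpolation so the whole operation stays
differentiable in ``delta``.  Attention rows are softmax-normalized over the
valid part of the neighborhood (edges truncate and renormalize), the output
is the convex combination of sensor values, and layers stack with residual
connections on the sensor stream.

The diagnostic :func:`expected_lag` computes ``E[k - t]`` under an attention
row; after training only ``delta`` and ``R`` on a reconstruction loss, its
mean converges to the true inter-stream lag — the property that makes the
learned offset interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, softmax
from .encoders import TokenSequence

__all__ = ["AlignmentConfig", "AlignedFeatures", "CrossModalAligner",
           "expected_lag", "mean_expected_lag"]


@dataclass
class AlignmentConfig:
    window_radius: int = 8            # W, tokens
    heads: int = 4
    layers: int = 2
    d_model: int = 256
    offset_init: float = 0.0          # tokens
    relpos_table_span: int | None = None   # >= W + max expected |delta|
    interp_values: bool = False       # gather values at fractional k+delta

    def __post_init__(self):
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")
        if self.d_model % self.heads:
            raise ValueError("heads must divide d_model")
        if self.relpos_table_span is None:
            self.relpos_table_span = self.window_radius + 8


@dataclass
class AlignedFeatures:
    f_hat: Tensor                     # [B, T, d]
    attn: np.ndarray                  # [layers, B, heads, T, 2W+1]
    lags: np.ndarray                  # [2W+1] integer lags k - t
    delta: float                      # current offset estimate (tokens)


class _AlignLayer(Module):
    def __init__(self, rng, cfg: AlignmentConfig):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.h = cfg.heads
        self.dh = d // cfg.heads
        self.wq = Linear(rng, d, d)
        self.wk = Linear(rng, d, d)
        self.wv = Linear(rng, d, d)
        self.wo = Linear(rng, d, d)

    def _heads(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, anchor: Tensor, sensor: Tensor, delta: Tensor,
                relpos: Tensor, sensor_valid: np.ndarray):
        B, T, d = anchor.shape
        W = self.cfg.window_radius
        lags = np.arange(-W, W + 1)
        k_idx = np.clip(np.arange(T)[:, None] + lags[None, :], 0, T - 1)  # [T, L]
        in_range = (np.arange(T)[:, None] + lags[None, :] >= 0) & \
                   (np.arange(T)[:, None] + lags[None, :] < T)

        q = self._heads(self.wq(anchor), B, T)                 # [B,H,T,dh]
        k = self._heads(self.wk(sensor), B, T)
        v = self._heads(self.wv(sensor), B, T)
        k_g = k[:, :, k_idx, :]                                # [B,H,T,L,dh]
        logits = (q.reshape(B, self.h, T, 1, self.dh) * k_g).sum(axis=-1) \
            * (1.0 / np.sqrt(self.dh))                         # [B,H,T,L]

        # continuous-lag relative position bias R(t - k - delta) = R(-l - delta)
        span = self.cfg.relpos_table_span
        pos = Tensor(-lags.astype(float)) - delta + float(span)  # [L]
        f0 = np.clip(np.floor(pos.data), 0, 2 * span - 1)
        frac = pos - Tensor(f0)
        lo = relpos[:, f0.astype(int)]                         # [H, L]
        hi = relpos[:, (f0 + 1).astype(int)]
        bias = lo * (1.0 - frac) + hi * frac                   # [H, L]
        logits = logits + bias.reshape(1, self.h, 1, 2 * W + 1)

        valid = in_range[None] & sensor_valid[:, k_idx]        # [B,T,L]
        neg = np.where(valid[:, None], 0.0, -1e30)             # [B,1,T,L]
        attn = softmax(logits + neg, axis=-1)

        if self.cfg.interp_values:
            d_int = int(np.floor(delta.data))
            frac_v = delta - float(d_int)
            k_lo = np.clip(k_idx + d_int, 0, T - 1)
            k_hi = np.clip(k_idx + d_int + 1, 0, T - 1)
            v_g = v[:, :, k_lo, :] * (1.0 - frac_v) + v[:, :, k_hi, :] * frac_v
        else:
            v_g = v[:, :, k_idx, :]                            # [B,H,T,L,dh]
        out = (attn.reshape(B, self.h, T, 2 * W + 1, 1) * v_g).sum(axis=3)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.wo(out), attn.data, lags


class CrossModalAligner(Module):
    """Stack of alignment layers for one sensor modality (I or E)."""

    def __init__(self, rng, cfg: AlignmentConfig):
        super().__init__()
        self.cfg = cfg
        self.delta = Tensor(np.array(float(cfg.offset_init)),
                            requires_grad=True)
        self.relpos = Tensor(
            np.zeros((cfg.heads, 2 * cfg.relpos_table_span + 1)),
            requires_grad=True)
        self.layers = [_AlignLayer(rng, cfg) for _ in range(cfg.layers)]

    def forward(self, anchor: TokenSequence,
                sensor: TokenSequence) -> AlignedFeatures:
        fa, fs = anchor.features, sensor.features
        if fa.shape[1] < 1:
            raise ValueError("empty token sequence")
        if fa.shape != fs.shape:
            raise ValueError(
                f"anchor/sensor shape mismatch: {fa.shape} vs {fs.shape}")
        x = fs
        maps = []
        lags = None
        for layer in self.layers:
            out, attn, lags = layer(fa, x, self.delta, self.relpos,
                                    sensor.validity)
            x = x + out                    # residual on the sensor stream
            maps.append(attn)
        return AlignedFeatures(f_hat=x, attn=np.stack(maps), lags=lags,
                               delta=float(self.delta.data))


def expected_lag(attn_row: np.ndarray, lags: np.ndarray) -> float:
    """E[k - t] under one attention row over the neighborhood lags."""
    attn_row = np.asarray(attn_row, dtype=float)
    if abs(attn_row.sum() - 1.0) > 1e-4:
        raise ValueError("attention row is not normalized")
    return float((attn_row * lags).sum())


def mean_expected_lag(attn: np.ndarray, lags: np.ndarray,
                      interior_only: bool = True) -> float:
    """Mean of E[k - t] over batch/heads/time of the last alignment layer.

    Edge rows are truncated (their neighborhood is clipped), which biases the
    expectation toward zero; ``interior_only`` drops them.
    """
    A = attn[-1]                       # last layer [B, H, T, L]
    T = A.shape[2]
    W = (A.shape[3] - 1) // 2
    if interior_only and T > 2 * W:
        A = A[:, :, W:T - W]
    return float((A * lags).sum(axis=-1).mean())
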