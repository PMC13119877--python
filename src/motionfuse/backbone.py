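"""Interleaved multimodal temporal Transformer backbone.

Per-modality token sequences (skeleton S, IMU I, EMG E — all ``[B, T, d]``)
are interleaved so the three tokens of one time step are adjacent, giving a
joint sequence of 3T tokens.  Pre-norm self-attention layers run over it
with two additive logit biases: a learnable relative-temporal table indexed
by ``time_i - time_j`` (clipped) and a learnable 3x3 ordered modality-pair
table.  Masked (invalid) tokens are excluded as attention keys.  The output
is de-interleaved back into three per-modality sequences for the fusion
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import LayerNorm, Module, Tensor, TransformerEncoderLayer
from .encoders import TokenSequence

__all__ = ["BackboneConfig", "InterleavedSequence", "interleave",
           "deinterleave_aggregate", "MultimodalBackbone"]

_MODS = ("S", "I", "E")


@dataclass
class BackboneConfig:
    layers: int = 4
    heads: int = 8
    d_model: int = 256
    ffn: int = 1024
    dropout: float = 0.1
    max_lag: int | None = None        # clip for the relative-time bias table

    def __post_init__(self):
        if min(self.layers, self.heads, self.d_model, self.ffn) < 1:
            raise ValueError("all backbone sizes must be positive")
        if self.d_model % self.heads:
            raise ValueError("heads must divide d_model")


@dataclass
class InterleavedSequence:
    tokens: Tensor                    # [B, 3T, d]
    modality_ids: np.ndarray          # [3T] in {0,1,2} = S,I,E
    time_ids: np.ndarray              # [3T]
    validity: np.ndarray              # [B, 3T]


def interleave(f_s: TokenSequence, f_i, f_e,
               modality_embed: Tensor | None = None) -> InterleavedSequence:
    """S,I,E tokens of each time step become adjacent: positions 3t, 3t+1,
    3t+2 carry time_id t."""
    seqs = (f_s, f_i, f_e)
    shapes = {s.features.shape for s in seqs}
    if len(shapes) != 1:
        raise ValueError(f"token sequences disagree in shape: {shapes}")
    B, T, d = f_s.features.shape
    from .nn import stack
    x = stack([s.features for s in seqs], axis=2)       # [B, T, 3, d]
    if modality_embed is not None:
        x = x + modality_embed.reshape(1, 1, 3, d)
    tokens = x.reshape(B, 3 * T, d)
    validity = np.stack([s.validity for s in seqs], axis=2).reshape(B, 3 * T)
    return InterleavedSequence(
        tokens=tokens,
        modality_ids=np.tile(np.arange(3), T),
        time_ids=np.repeat(np.arange(T), 3),
        validity=validity)


def deinterleave_aggregate(x: InterleavedSequence):
    """Split the 3T joint sequence back into (H_S, H_I, H_E), no mixing."""
    B, N, d = x.tokens.shape
    if N % 3 or not np.array_equal(x.modality_ids, np.tile(np.arange(3), N // 3)):
        raise ValueError("malformed interleaving pattern")
    T = N // 3
    y = x.tokens.reshape(B, T, 3, d)
    return y[:, :, 0, :], y[:, :, 1, :], y[:, :, 2, :]


class MultimodalBackbone(Module):
    def __init__(self, rng, cfg: BackboneConfig, drop_rng=None):
        super().__init__()
        self.cfg = cfg
        d = cfg.d_model
        self.mod_embed = Tensor(rng.standard_normal((3, d)) * 0.02,
                                requires_grad=True)
        # bias tables are per-head
        self.b_modal = Tensor(np.zeros((cfg.heads, 3, 3)), requires_grad=True)
        self._max_lag = cfg.max_lag   # resolved lazily from T
        self.b_time: Tensor | None = None
        self.layers = [TransformerEncoderLayer(rng, d, cfg.heads, cfg.ffn,
                                               cfg.dropout, drop_rng)
                       for _ in range(cfg.layers)]
        self.final_ln = LayerNorm(d)

    def _ensure_time_table(self, T: int):
        if self._max_lag is None:
            self._max_lag = T
        if self.b_time is None:
            self.b_time = Tensor(np.zeros((self.cfg.heads,
                                           2 * self._max_lag + 1)),
                                 requires_grad=True)

    def attention_bias(self, seq: InterleavedSequence) -> Tensor:
        """[heads, 3T, 3T] additive logit bias from the two tables."""
        mx = self._max_lag
        dt = np.clip(seq.time_ids[:, None] - seq.time_ids[None, :], -mx, mx) + mx
        bias_t = self.b_time[:, dt]                               # [H, N, N]
        bias_m = self.b_modal[:, seq.modality_ids[:, None],
                              seq.modality_ids[None, :]]          # [H, N, N]
        return bias_t + bias_m

    def forward(self, f_s: TokenSequence, f_i, f_e):
        seq = interleave(f_s, f_i, f_e, self.mod_embed)
        self._ensure_time_table(f_s.T)
        bias = self.attention_bias(seq).reshape(
            1, self.cfg.heads, seq.tokens.shape[1], seq.tokens.shape[1])
        x = seq.tokens
        for li, layer in enumerate(self.layers):
            x = layer(x, bias=bias, key_mask=seq.validity)
            if not np.isfinite(x.data).all():
                raise FloatingPointError(
                    f"non-finite activations in backbone layer {li}")
        x = self.final_ln(x)
        out = InterleavedSequence(x, seq.modality_ids, seq.time_ids,
                                  seq.validity)
        return deinterleave_aggregate(out)
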