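"""Modality-specific encoders projecting each stream into a shared latent
space at a common model token rate.

* skeleton: flattened joint coordinates + validity channels, linear embed,
  pre-norm temporal Transformer with sinusoidal absolute positions;
* IMU: 2-layer bidirectional LSTM, concatenated directions, linear
  projection;
* EMG: residual dilated temporal convolutions (kernel 3, dilations
  1,2,4,8, two convolutions per block, symmetric non-causal padding).

Each encoder ends with strided mean-pooling from the grid rate down to the
token rate, so all three emit ``[B, T, d]`` with the same ``T`` — the
precondition for interleaving in the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BiLSTM, Dropout, Linear, Module, Tensor,
                 TransformerEncoderLayer, gelu, sinusoidal_positions)

__all__ = ["EncoderConfig", "TokenSequence", "SkeletonEncoder", "IMUEncoder",
           "EMGEncoder", "tcn_receptive_field"]


@dataclass
class EncoderConfig:
    d_model: int = 256
    skeleton_layers: int = 4
    skeleton_heads: int = 8
    skeleton_ffn: int = 1024
    imu_layers: int = 2
    imu_hidden: int = 128
    emg_kernel: int = 3
    emg_dilations: tuple[int, ...] = (1, 2, 4, 8)
    token_rate: float = 25.0
    dropout: float = 0.1

    def __post_init__(self):
        if self.d_model % self.skeleton_heads:
            raise ValueError("d_model must be divisible by skeleton_heads")
        if any(b >= a for a, b in zip(self.emg_dilations[1:], self.emg_dilations)):
            raise ValueError("dilations must be strictly increasing")


@dataclass
class TokenSequence:
    """One modality's encoded feature sequence at the token rate."""

    features: Tensor            # [B, T, d]
    modality: str               # "S" | "I" | "E"
    token_rate: float
    validity: np.ndarray        # [B, T] bool

    @property
    def T(self) -> int:
        return self.features.shape[1]


def _check_finite(x: np.ndarray, name: str):
    if not np.isfinite(x).all():
        raise ValueError(f"non-finite values in {name} input")


def _pool_factor(grid_rate: float, token_rate: float) -> int:
    f = grid_rate / token_rate
    if abs(f - round(f)) > 1e-9 or f < 1:
        raise ValueError(
            f"grid_rate {grid_rate} must be an integer multiple of "
            f"token_rate {token_rate}")
    return int(round(f))


def strided_pool(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping mean pooling along the time axis."""
    B, T, d = x.shape
    T_out = T // factor
    return x[:, :T_out * factor, :].reshape(B, T_out, factor, d).mean(axis=2)


def pool_validity(valid: np.ndarray, factor: int) -> np.ndarray:
    B, T = valid.shape
    T_out = T // factor
    return valid[:, :T_out * factor].reshape(B, T_out, factor).any(axis=2)


class SkeletonEncoder(Module):
    def __init__(self, rng, cfg: EncoderConfig, n_joints: int,
                 drop_rng=None):
        super().__init__()
        self.cfg = cfg
        self.embed = Linear(rng, 3 * n_joints, cfg.d_model)  # coords + mask
        self.layers = [TransformerEncoderLayer(
            rng, cfg.d_model, cfg.skeleton_heads, cfg.skeleton_ffn,
            cfg.dropout, drop_rng) for _ in range(cfg.skeleton_layers)]
        self._pe_cache: dict[int, np.ndarray] = {}

    def forward(self, skeleton: np.ndarray, validity: np.ndarray,
                grid_rate: float) -> TokenSequence:
        _check_finite(skeleton, "skeleton")
        B, T_g, J, _ = skeleton.shape
        coords = np.where(validity[..., None], skeleton, 0.0)
        feats = np.concatenate(
            [coords.reshape(B, T_g, 2 * J), validity.astype(float)], axis=-1)
        x = self.embed(Tensor(feats))
        if T_g not in self._pe_cache:
            self._pe_cache[T_g] = sinusoidal_positions(T_g, self.cfg.d_model)
        x = x + Tensor(self._pe_cache[T_g][None])
        frame_valid = validity.any(axis=2)          # fully occluded frame
        for layer in self.layers:
            x = layer(x, key_mask=frame_valid)
        factor = _pool_factor(grid_rate, self.cfg.token_rate)
        return TokenSequence(strided_pool(x, factor), "S",
                             self.cfg.token_rate,
                             pool_validity(frame_valid, factor))


class IMUEncoder(Module):
    def __init__(self, rng, cfg: EncoderConfig, n_channels: int):
        super().__init__()
        self.cfg = cfg
        self.lstm = BiLSTM(rng, n_channels, cfg.imu_hidden, cfg.imu_layers)
        self.proj = Linear(rng, 2 * cfg.imu_hidden, cfg.d_model)

    def forward(self, imu: np.ndarray, validity: np.ndarray,
                grid_rate: float) -> TokenSequence:
        _check_finite(imu, "imu")
        x = self.proj(self.lstm(Tensor(imu)))
        factor = _pool_factor(grid_rate, self.cfg.token_rate)
        return TokenSequence(strided_pool(x, factor), "I",
                             self.cfg.token_rate,
                             pool_validity(validity, factor))


class _DilatedResBlock(Module):
    """Two dilated convolutions (kernel k, same dilation) with GELU and a
    residual connection; symmetric zero padding keeps length."""

    def __init__(self, rng, d: int, kernel: int, dilation: int):
        super().__init__()
        self.kernel, self.dilation = kernel, dilation
        self.conv1 = [Linear(rng, d, d, bias=(i == 0),
                             scale=1.0 / np.sqrt(d * kernel))
                      for i in range(kernel)]
        self.conv2 = [Linear(rng, d, d, bias=(i == 0),
                             scale=1.0 / np.sqrt(d * kernel))
                      for i in range(kernel)]

    def _conv(self, x: Tensor, taps: list[Linear]) -> Tensor:
        B, T, d = x.shape
        half = (self.kernel - 1) // 2 * self.dilation
        xp = x.pad(((0, 0), (half, half), (0, 0)))
        out = None
        for i, lin in enumerate(taps):
            piece = lin(xp[:, i * self.dilation:i * self.dilation + T, :])
            out = piece if out is None else out + piece
        return out

    def forward(self, x: Tensor) -> Tensor:
        h = gelu(self._conv(x, self.conv1))
        h = self._conv(h, self.conv2)
        return x + h


def tcn_receptive_field(kernel: int, dilations) -> int:
    """Receptive field of the stack: two convs per block."""
    return 1 + 2 * (kernel - 1) * sum(dilations)


class EMGEncoder(Module):
    def __init__(self, rng, cfg: EncoderConfig, n_channels: int):
        super().__init__()
        self.cfg = cfg
        self.embed = Linear(rng, n_channels, cfg.d_model)
        self.blocks = [_DilatedResBlock(rng, cfg.d_model, cfg.emg_kernel, dl)
                       for dl in cfg.emg_dilations]

    def forward(self, emg: np.ndarray, validity: np.ndarray,
                grid_rate: float) -> TokenSequence:
        _check_finite(emg, "emg")
        T_g = emg.shape[1]
        rf = tcn_receptive_field(self.cfg.emg_kernel, self.cfg.emg_dilations)
        if T_g < rf:
            raise ValueError(
                f"window of {T_g} samples shorter than TCN receptive "
                f"field ({rf})")
        x = self.embed(Tensor(emg))
        for blk in self.blocks:
            x = blk(x)
        factor = _pool_factor(grid_rate, self.cfg.token_rate)
        return TokenSequence(strided_pool(x, factor), "E",
                             self.cfg.token_rate,
                             pool_validity(validity, factor))
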