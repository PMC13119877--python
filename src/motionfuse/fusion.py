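"""Uncertainty-aware fusion.

Each modality's high-level stream is scored by a two-layer time-distributed
perceptron; the softplus of the score is the per-timestep uncertainty
``sigma >= 0``; weights are the softmax of ``-sigma`` (normalized inverse
confidence); the fused representation is the per-timestep convex combination
of the three streams.  A temporal smoothness penalty on the fused sequence
discourages prediction flicker.

For reference, the analytic minimizer of the expected squared fusion error
``sum_m omega_m^2 sigma_m`` over the simplex is ``omega_m ~ 1/sigma_m``
(:func:`optimal_weights_oracle`); the softmax weighting is the forward path,
the oracle quantifies the gap in tests and reports.

A modality whose validity mask is entirely false within a window has its
uncertainty forced to +inf (weight -> 0) before normalization, so total
modality loss is handled by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, softmax, softplus, stack

__all__ = ["UncertaintyHead", "FusionState", "UncertaintyFusion",
           "estimate_uncertainty", "fusion_weights", "fuse",
           "smoothness_penalty", "optimal_weights_oracle"]

_FORCED_SIGMA = 1e6    # stands in for +inf on fully invalid modalities


class UncertaintyHead(Module):
    """u_t = W2 phi(W1 h_t), scalar per time step; phi defaults to tanh."""

    def __init__(self, rng, d_model: int, bottleneck: int | None = None,
                 activation: str = "tanh"):
        super().__init__()
        bottleneck = bottleneck or max(d_model // 4, 4)
        self.w1 = Linear(rng, d_model, bottleneck)
        self.w2 = Linear(rng, bottleneck, 1)
        self.activation = activation

    def forward(self, h: Tensor) -> Tensor:
        z = self.w1(h)
        z = z.tanh() if self.activation == "tanh" else z.relu()
        u = self.w2(z)
        return u.reshape(u.shape[:-1])     # drop trailing singleton


def estimate_uncertainty(h: Tensor, head: UncertaintyHead):
    """Returns (u, sigma) with sigma = softplus(u), overflow-safe."""
    u = head(h)
    return u, softplus(u)


def fusion_weights(sigma: Tensor) -> Tensor:
    """omega = softmax(-sigma) across the modality axis (last)."""
    return softmax(-sigma, axis=-1)


def fuse(h_s: Tensor, h_i: Tensor, h_e: Tensor, omega: Tensor) -> Tensor:
    """z_t = sum_m omega_t^(m) h_t^(m); omega rows must lie on the simplex."""
    row_sum = omega.data.sum(axis=-1)
    if np.abs(row_sum - 1.0).max() > 1e-4 or omega.data.min() < -1e-9:
        raise ValueError("fusion weight rows are off the simplex")
    h = stack([h_s, h_i, h_e], axis=2)            # [B, T, 3, d]
    B, T, _, d = h.shape
    return (h * omega.reshape(B, T, 3, 1)).sum(axis=2)


def smoothness_penalty(z: Tensor) -> Tensor:
    """L_smooth = sum_t ||z_t - z_{t-1}||^2 along the time axis (axis 1 for
    batched input, axis 0 for a single sequence)."""
    t_axis = 1 if z.ndim == 3 else 0
    if z.shape[t_axis] < 2:
        warnings.warn("smoothness penalty undefined for T < 2; returning 0")
        return Tensor(np.zeros(()))
    if t_axis == 1:
        diff = z[:, 1:, :] - z[:, :-1, :]
    else:
        diff = z[1:] - z[:-1]
    return (diff * diff).sum()


def optimal_weights_oracle(sigma_row) -> np.ndarray:
    """Simplex minimizer of sum_m omega_m^2 sigma_m: omega ~ 1/sigma.

    Any zero-uncertainty entry receives all mass (split uniformly on ties).
    Treats sigma as a variance-like quantity (the reading under which the
    inverse weighting minimizes the error of uncorrelated unbiased
    estimators).
    """
    s = np.asarray(sigma_row, dtype=float)
    if (s < 0).any():
        raise ValueError("sigma must be non-negative")
    if (s == 0).any():
        w = (s == 0).astype(float)
        return w / w.sum()
    inv = 1.0 / s
    return inv / inv.sum()


@dataclass
class FusionState:
    """Diagnostics of one fusion pass (plain arrays)."""

    u: np.ndarray          # [B, T, 3]
    sigma: np.ndarray      # [B, T, 3]
    omega: np.ndarray      # [B, T, 3]
    z: np.ndarray          # [B, T, d]


class UncertaintyFusion(Module):
    """Three uncertainty heads + weighting + convex aggregation."""

    def __init__(self, rng, d_model: int, mode: str = "uncertainty"):
        super().__init__()
        if mode not in ("uncertainty", "uniform"):
            raise ValueError(f"unknown fusion mode {mode!r}")
        self.mode = mode
        self.heads = [UncertaintyHead(rng, d_model) for _ in range(3)]

    def forward(self, h_s: Tensor, h_i: Tensor, h_e: Tensor,
                invalid: np.ndarray | None = None):
        """``invalid``: [B, 3] bool — modality entirely lost in the window."""
        B, T, d = h_s.shape
        if self.mode == "uniform":
            omega = Tensor(np.full((B, T, 3), 1.0 / 3.0))
            u = sigma = Tensor(np.zeros((B, T, 3)))
        else:
            us, sigmas = [], []
            for head, h in zip(self.heads, (h_s, h_i, h_e)):
                u_m, s_m = estimate_uncertainty(h, head)
                us.append(u_m)
                sigmas.append(s_m)
            u = stack(us, axis=-1)            # [B, T, 3]
            sigma = stack(sigmas, axis=-1)
            if invalid is not None and invalid.any():
                sigma = sigma + Tensor(
                    np.where(invalid[:, None, :], _FORCED_SIGMA, 0.0))
            omega = fusion_weights(sigma)
        z = fuse(h_s, h_i, h_e, omega)
        state = FusionState(u=u.data.copy(), sigma=sigma.data.copy(),
                            omega=omega.data.copy(), z=z.data.copy())
        return z, omega, state
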