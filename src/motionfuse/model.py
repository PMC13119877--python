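"""Full network and the scikit-learn style estimator.

``FusionNetwork`` wires the pieces together:

    encoders -> cross-modal alignment (vision anchored) -> interleaved
    Transformer backbone -> uncertainty-aware fusion -> multi-task heads

``MotionStateClassifier`` wraps it with fit/predict/predict_proba semantics
on lists of :class:`~motionfuse.preprocess.UnifiedWindow`, AdamW with a
cosine learning-rate schedule, training-time modality dropout, optional
early stopping on a validation set, and per-epoch diagnostics (loss
components, mean expected alignment lag per sensor modality, mean fusion
weights).

Ablation variants are configuration switches:

* ``align_mode``:   "attention" (full) or "interp" (sensor features pass
  through on the anchor grid — plain interpolation alignment);
* ``arch_mode``:    "interleaved" (full) or "concat" (per-timestep channel
  concatenation, no token-level cross-modal attention, no offset
  compensation);
* ``backbone_mode``: "transformer" (full) or "pool" (identity — no joint
  temporal modeling);
* ``fusion_mode``:  "uncertainty" or "uniform" (fixed 1/3 weights);
* ``modality_dropout_p``: 0 disables modality dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import (AdamW, Linear, Module, Tensor, cosine_lr, cross_entropy,
                 logsumexp, softmax, concatenate)
from .encoders import (EMGEncoder, EncoderConfig, IMUEncoder, SkeletonEncoder,
                       TokenSequence, _pool_factor)
from .align import AlignmentConfig, CrossModalAligner, mean_expected_lag
from .backbone import BackboneConfig, MultimodalBackbone
from .fusion import UncertaintyFusion, smoothness_penalty
from .preprocess import UnifiedWindow

__all__ = ["PredictionBundle", "MultiTaskHeads", "forward_heads",
           "multitask_loss", "LossWeights", "FusionNetwork",
           "MotionStateClassifier", "collate", "apply_modality_dropout"]


@dataclass
class PredictionBundle:
    class_logits: Tensor       # [B, C]
    phase_logits: Tensor       # [B, T, P]
    stability: Tensor          # [B] in [0, 1]

    @property
    def class_probs(self) -> np.ndarray:
        return softmax(self.class_logits.detach(), axis=-1).data

    @property
    def phase_probs(self) -> np.ndarray:
        return softmax(self.phase_logits.detach(), axis=-1).data


class MultiTaskHeads(Module):
    """Class head (mean-pool + linear + softmax), per-token phase head,
    stability head (mean-pool + linear + sigmoid)."""

    def __init__(self, rng, d_model: int, n_classes: int, phase_count: int):
        super().__init__()
        self.cls = Linear(rng, d_model, n_classes)
        self.phase = Linear(rng, d_model, phase_count)
        self.stab = Linear(rng, d_model, 1)

    def forward(self, z: Tensor) -> PredictionBundle:
        pooled = z.mean(axis=1)                       # [B, d]
        stab = self.stab(pooled).sigmoid()
        return PredictionBundle(
            class_logits=self.cls(pooled),
            phase_logits=self.phase(z),
            stability=stab.reshape(stab.shape[0]))


def forward_heads(z: Tensor, heads: MultiTaskHeads) -> PredictionBundle:
    return heads(z)


@dataclass
class LossWeights:
    lam_cls: float = 1.0
    lam_phase: float = 1.0
    lam_stab: float = 0.5
    lam_smooth: float = 0.01


def multitask_loss(pred: PredictionBundle, labels: dict, z: Tensor,
                   weights: LossWeights = LossWeights()):
    """Joint objective; returns (total, per-component dict of floats).

    ``labels``: action [B] 0-based ints, phase [B, T] ints, stability [B].
    """
    action = np.asarray(labels["action"])
    C = pred.class_logits.shape[-1]
    if action.min() < 0 or action.max() >= C:
        raise ValueError("action label out of range")
    P = pred.phase_logits.shape[-1]
    phase = np.asarray(labels["phase"])
    if phase.min() < 0 or phase.max() >= P:
        raise ValueError("phase label out of range")

    l_cls = cross_entropy(pred.class_logits, action)
    l_phase = cross_entropy(pred.phase_logits, phase)   # mean over B*T
    err = pred.stability - Tensor(np.asarray(labels["stability"], dtype=float))
    l_stab = (err * err).mean()
    l_smooth = smoothness_penalty(z) * (1.0 / z.shape[0])   # per window
    total = (weights.lam_cls * l_cls + weights.lam_phase * l_phase
             + weights.lam_stab * l_stab + weights.lam_smooth * l_smooth)
    comps = {"cls": float(l_cls.data), "phase": float(l_phase.data),
             "stab": float(l_stab.data), "smooth": float(l_smooth.data),
             "total": float(total.data)}
    return total, comps


# ---------------------------------------------------------------------------
# batching + modality dropout
# ---------------------------------------------------------------------------

def collate(windows: list[UnifiedWindow]) -> dict:
    """Stack equally-shaped windows into one batch dict of arrays."""
    return {
        "skeleton": np.stack([w.skeleton_n for w in windows]),
        "imu": np.stack([w.imu_n for w in windows]),
        "emg": np.stack([w.emg_n for w in windows]),
        "valid_skeleton": np.stack([w.validity["skeleton"] for w in windows]),
        "valid_imu": np.stack([w.validity["imu"] for w in windows]),
        "valid_emg": np.stack([w.validity["emg"] for w in windows]),
        "grid_rate": windows[0].grid_rate,
        "action": np.array([w.action_class for w in windows]),
        "phase": np.stack([w.phase for w in windows]),
        "stability": np.array([w.stability for w in windows]),
    }


def apply_modality_dropout(window: UnifiedWindow, p: float,
                           rng: np.random.Generator,
                           include_skeleton: bool = False) -> UnifiedWindow:
    """Training-time modality dropout on one window.

    Each eligible modality is independently zeroed (stream and validity)
    with probability ``p``; at least one modality always survives (dropped
    sets leaving none are resampled).  The skeleton anchor is excluded by
    default because the alignment module is vision-anchored.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    mods = ["skeleton", "imu", "emg"] if include_skeleton else ["imu", "emg"]
    drop = [m for m in mods if rng.random() < p]
    if include_skeleton and len(drop) == 3:
        # at least one modality must survive: retain one uniformly
        drop.remove(drop[int(rng.integers(3))])
    if not drop:
        return window
    import copy
    out = copy.deepcopy(window)
    for m in drop:
        attr = {"skeleton": "skeleton_n", "imu": "imu_n", "emg": "emg_n"}[m]
        setattr(out, attr, np.zeros_like(getattr(out, attr)))
        out.validity[m] = np.zeros_like(out.validity[m])
    return out


def _batch_modality_dropout(batch: dict, p: float, rng: np.random.Generator,
                            include_skeleton: bool = False) -> dict:
    if p <= 0:
        return batch
    B = batch["action"].shape[0]
    mods = ("skeleton", "imu", "emg") if include_skeleton else ("imu", "emg")
    out = dict(batch)
    for key in ("skeleton", "imu", "emg", "valid_skeleton", "valid_imu",
                "valid_emg"):
        out[key] = batch[key].copy()
    for b in range(B):
        drop = [m for m in mods if rng.random() < p]
        if include_skeleton and len(drop) == 3:
            drop.remove(drop[int(rng.integers(3))])  # one survivor
        for m in drop:
            out[m][b] = 0.0
            out[f"valid_{m}"][b] = False
    return out


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class FusionNetwork(Module):
    def __init__(self, rng, *, n_joints: int, imu_channels: int,
                 emg_channels: int, n_classes: int, phase_count: int,
                 enc_cfg: EncoderConfig, align_cfg: AlignmentConfig,
                 bb_cfg: BackboneConfig, arch_mode: str = "interleaved",
                 align_mode: str = "attention",
                 fusion_mode: str = "uncertainty",
                 backbone_mode: str = "transformer", drop_rng=None):
        super().__init__()
        d = enc_cfg.d_model
        self.arch_mode = arch_mode
        self.align_mode = align_mode
        self.backbone_mode = backbone_mode
        self.enc_s = SkeletonEncoder(rng, enc_cfg, n_joints, drop_rng)
        self.enc_i = IMUEncoder(rng, enc_cfg, imu_channels)
        self.enc_e = EMGEncoder(rng, enc_cfg, emg_channels)
        if arch_mode == "interleaved":
            if align_mode == "attention":
                self.align_i = CrossModalAligner(rng, align_cfg)
                self.align_e = CrossModalAligner(rng, align_cfg)
            if backbone_mode == "transformer":
                self.backbone = MultimodalBackbone(rng, bb_cfg, drop_rng)
            self.fusion = UncertaintyFusion(rng, d, fusion_mode)
        elif arch_mode == "concat":
            self.concat_proj = Linear(rng, 3 * d, d)
            if backbone_mode == "transformer":
                self.backbone = MultimodalBackbone(rng, bb_cfg, drop_rng)
        else:
            raise ValueError(f"unknown arch_mode {arch_mode!r}")
        self.heads = MultiTaskHeads(rng, d, n_classes, phase_count)

    def forward(self, batch: dict):
        grid_rate = batch["grid_rate"]
        f_s = self.enc_s(batch["skeleton"], batch["valid_skeleton"], grid_rate)
        f_i = self.enc_i(batch["imu"], batch["valid_imu"], grid_rate)
        f_e = self.enc_e(batch["emg"], batch["valid_emg"], grid_rate)
        diag = {}

        if self.arch_mode == "concat":
            x = self.concat_proj(concatenate(
                [f_s.features, f_i.features, f_e.features], axis=-1))
            if self.backbone_mode == "transformer":
                seq = TokenSequence(x, "S", f_s.token_rate, f_s.validity)
                h_s, h_i, h_e = self.backbone(seq, seq, seq)
                z = (h_s + h_i + h_e) * (1.0 / 3.0)
            else:
                z = x
            diag["omega"] = None
        else:
            if self.align_mode == "attention":
                al_i = self.align_i(f_s, f_i)
                al_e = self.align_e(f_s, f_e)
                f_i = TokenSequence(al_i.f_hat, "I", f_i.token_rate,
                                    f_i.validity)
                f_e = TokenSequence(al_e.f_hat, "E", f_e.token_rate,
                                    f_e.validity)
                diag["lag_imu"] = mean_expected_lag(al_i.attn, al_i.lags)
                diag["lag_emg"] = mean_expected_lag(al_e.attn, al_e.lags)
                diag["delta_imu"] = al_i.delta
                diag["delta_emg"] = al_e.delta
            if self.backbone_mode == "transformer":
                h_s, h_i, h_e = self.backbone(f_s, f_i, f_e)
            else:
                h_s, h_i, h_e = f_s.features, f_i.features, f_e.features
            invalid = ~np.stack([f_s.validity.any(axis=1),
                                 f_i.validity.any(axis=1),
                                 f_e.validity.any(axis=1)], axis=1)
            z, omega, state = self.fusion(h_s, h_i, h_e, invalid)
            diag["omega"] = state.omega
            diag["sigma"] = state.sigma

        pred = self.heads(z)
        return pred, z, diag


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class MotionStateClassifier(BaseEstimator, ClassifierMixin):
    """Multimodal motion-state model with a scikit-learn surface.

    ``X`` is a list of :class:`UnifiedWindow`; ``y`` (optional) overrides the
    windows' action classes.  Defaults are the desk-scale preset (small
    latent width, short schedule); :meth:`paper_protocol` returns the
    full-scale setting (256-d latent, 4+4 layers, 8 heads, 150 epochs,
    cosine 1e-4 -> 1e-6).
    """

    def __init__(self, d_model=64, token_rate=5.0, skeleton_layers=2,
                 skeleton_heads=4, skeleton_ffn=128, imu_layers=2,
                 imu_hidden=48, emg_kernel=3, emg_dilations=(1, 2, 4, 8),
                 align_window=8, align_heads=4, align_layers=2,
                 backbone_layers=2, backbone_heads=4, backbone_ffn=128,
                 dropout=0.0, arch_mode="interleaved", align_mode="attention",
                 fusion_mode="uncertainty", backbone_mode="transformer",
                 modality_dropout_p=0.2, modality_dropout_skeleton=False,
                 epochs=30, batch_size=32,
                 lr_start=1e-3, lr_end=1e-5, weight_decay=1e-2,
                 lam_cls=1.0, lam_phase=1.0, lam_stab=0.5, lam_smooth=0.01,
                 grad_clip=1.0, patience=15, seed=0, verbose=0):
        self.d_model = d_model
        self.token_rate = token_rate
        self.skeleton_layers = skeleton_layers
        self.skeleton_heads = skeleton_heads
        self.skeleton_ffn = skeleton_ffn
        self.imu_layers = imu_layers
        self.imu_hidden = imu_hidden
        self.emg_kernel = emg_kernel
        self.emg_dilations = emg_dilations
        self.align_window = align_window
        self.align_heads = align_heads
        self.align_layers = align_layers
        self.backbone_layers = backbone_layers
        self.backbone_heads = backbone_heads
        self.backbone_ffn = backbone_ffn
        self.dropout = dropout
        self.arch_mode = arch_mode
        self.align_mode = align_mode
        self.fusion_mode = fusion_mode
        self.backbone_mode = backbone_mode
        self.modality_dropout_p = modality_dropout_p
        self.modality_dropout_skeleton = modality_dropout_skeleton
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.weight_decay = weight_decay
        self.lam_cls = lam_cls
        self.lam_phase = lam_phase
        self.lam_stab = lam_stab
        self.lam_smooth = lam_smooth
        self.grad_clip = grad_clip
        self.patience = patience
        self.seed = seed
        self.verbose = verbose

    @classmethod
    def paper_protocol(cls, **overrides):
        """Full-scale architecture and training protocol."""
        params = dict(d_model=256, token_rate=25.0, skeleton_layers=4,
                      skeleton_heads=8, skeleton_ffn=1024, imu_hidden=128,
                      backbone_layers=4, backbone_heads=8, backbone_ffn=1024,
                      dropout=0.1, epochs=150, lr_start=1e-4, lr_end=1e-6)
        params.update(overrides)
        return cls(**params)

    # -- internals ----------------------------------------------------------

    def _configs(self):
        enc = EncoderConfig(
            d_model=self.d_model, skeleton_layers=self.skeleton_layers,
            skeleton_heads=self.skeleton_heads, skeleton_ffn=self.skeleton_ffn,
            imu_layers=self.imu_layers, imu_hidden=self.imu_hidden,
            emg_kernel=self.emg_kernel, emg_dilations=tuple(self.emg_dilations),
            token_rate=self.token_rate, dropout=self.dropout)
        align = AlignmentConfig(
            window_radius=self.align_window, heads=self.align_heads,
            layers=self.align_layers, d_model=self.d_model)
        bb = BackboneConfig(
            layers=self.backbone_layers, heads=self.backbone_heads,
            d_model=self.d_model, ffn=self.backbone_ffn, dropout=self.dropout)
        return enc, align, bb

    def _labels(self, batch: dict, factor: int) -> dict:
        phase_tok = batch["phase"][:, factor // 2::factor]
        T = batch["skeleton"].shape[1] // factor
        return {"action": batch["action"] - self._class_offset,
                "phase": phase_tok[:, :T],
                "stability": batch["stability"]}

    def _clip_grads(self, params):
        if not self.grad_clip:
            return
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in params if p.grad is not None))
        if total > self.grad_clip:
            scale = self.grad_clip / (total + 1e-12)
            for p in params:
                if p.grad is not None:
                    p.grad *= scale

    # -- fit / predict ------------------------------------------------------

    def fit(self, X, y=None, eval_set=None):
        windows = list(X)
        if not windows:
            raise ValueError("no training windows")
        actions = np.array([w.action_class for w in windows]) if y is None \
            else np.asarray(y)
        self.classes_ = np.unique(actions)
        self._class_offset = int(self.classes_.min())
        n_classes = int(self.classes_.max() - self._class_offset) + 1
        phase_count = int(max(w.phase.max() for w in windows)) + 1
        w0 = windows[0]
        self._grid_rate = w0.grid_rate
        self._factor = _pool_factor(w0.grid_rate, self.token_rate)

        rng = np.random.default_rng([self.seed, 5])
        drop_rng = np.random.default_rng([self.seed, 11])
        enc, align, bb = self._configs()
        self.network_ = FusionNetwork(
            rng, n_joints=w0.skeleton_n.shape[1],
            imu_channels=w0.imu_n.shape[1], emg_channels=w0.emg_n.shape[1],
            n_classes=n_classes, phase_count=phase_count, enc_cfg=enc,
            align_cfg=align, bb_cfg=bb, arch_mode=self.arch_mode,
            align_mode=self.align_mode, fusion_mode=self.fusion_mode,
            backbone_mode=self.backbone_mode, drop_rng=drop_rng)

        # dry forward materializes lazily-sized tables before the optimizer
        self.network_.eval()
        self.network_(collate(windows[:1]))
        self.network_.train()

        params = self.network_.parameters()
        opt = AdamW(params, lr=self.lr_start, weight_decay=self.weight_decay)
        weights = LossWeights(self.lam_cls, self.lam_phase, self.lam_stab,
                              self.lam_smooth)
        order_rng = np.random.default_rng([self.seed, 17])
        md_rng = np.random.default_rng([self.seed, 23])

        history, best = [], (np.inf, None, -1)
        for epoch in range(self.epochs):
            opt.lr = cosine_lr(epoch, self.epochs, self.lr_start, self.lr_end)
            order = order_rng.permutation(len(windows))
            ep = {"loss": 0.0, "cls": 0.0, "phase": 0.0, "stab": 0.0,
                  "smooth": 0.0, "n": 0, "correct": 0}
            lag_i, lag_e, om = [], [], []
            for s in range(0, len(order), self.batch_size):
                idx = order[s:s + self.batch_size]
                batch = collate([windows[i] for i in idx])
                batch["action"] = actions[idx]
                batch = _batch_modality_dropout(
                    batch, self.modality_dropout_p, md_rng,
                    include_skeleton=self.modality_dropout_skeleton)
                pred, z, diag = self.network_(batch)
                labels = self._labels(batch, self._factor)
                loss, comps = multitask_loss(pred, labels, z, weights)
                opt.zero_grad()
                loss.backward()
                self._clip_grads(params)
                opt.step()
                nb = len(idx)
                ep["n"] += nb
                ep["loss"] += comps["total"] * nb
                for k in ("cls", "phase", "stab", "smooth"):
                    ep[k] += comps[k] * nb
                ep["correct"] += int(
                    (pred.class_probs.argmax(1) == labels["action"]).sum())
                if "lag_imu" in diag:
                    lag_i.append(diag["lag_imu"])
                    lag_e.append(diag["lag_emg"])
                if diag.get("omega") is not None:
                    om.append(diag["omega"].mean(axis=(0, 1)))
            row = {"epoch": epoch, "lr": opt.lr,
                   "loss": ep["loss"] / ep["n"],
                   "loss_cls": ep["cls"] / ep["n"],
                   "loss_phase": ep["phase"] / ep["n"],
                   "loss_stab": ep["stab"] / ep["n"],
                   "loss_smooth": ep["smooth"] / ep["n"],
                   "train_acc": ep["correct"] / ep["n"],
                   "lag_imu": float(np.mean(lag_i)) if lag_i else np.nan,
                   "lag_emg": float(np.mean(lag_e)) if lag_e else np.nan}
            if om:
                mo = np.mean(om, axis=0)
                row.update(omega_s=mo[0], omega_i=mo[1], omega_e=mo[2])
            if eval_set is not None:
                val_loss, val_acc = self._evaluate_loss(eval_set, weights)
                row.update(val_loss=val_loss, val_acc=val_acc)
                if val_loss < best[0] - 1e-6:
                    best = (val_loss, self.network_.state_dict(), epoch)
                elif epoch - best[2] >= self.patience:
                    history.append(row)
                    if self.verbose:
                        print(f"early stop at epoch {epoch}")
                    break
            history.append(row)
            if self.verbose:
                print({k: (round(v, 4) if isinstance(v, float) else v)
                       for k, v in row.items()})
        if eval_set is not None and best[1] is not None:
            self.network_.load_state_dict(best[1])
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = 3
        return self

    def _evaluate_loss(self, windows, weights):
        from .nn.tensor import no_grad
        self.network_.eval()
        tot, n, correct = 0.0, 0, 0
        with no_grad():
            for s in range(0, len(windows), self.batch_size):
                batch = collate(windows[s:s + self.batch_size])
                pred, z, _ = self.network_(batch)
                labels = self._labels(batch, self._factor)
                _, comps = multitask_loss(pred, labels, z, weights)
                nb = batch["action"].shape[0]
                tot += comps["total"] * nb
                n += nb
                correct += int(
                    (pred.class_probs.argmax(1) == labels["action"]).sum())
        self.network_.train()
        return tot / n, correct / n

    def _forward_eval(self, windows):
        from .nn.tensor import no_grad
        self.network_.eval()
        preds, diags = [], []
        with no_grad():
            for s in range(0, len(windows), self.batch_size):
                batch = collate(windows[s:s + self.batch_size])
                pred, _, diag = self.network_(batch)
                preds.append(pred)
                diags.append(diag)
        return preds, diags

    def predict_proba(self, X):
        preds, _ = self._forward_eval(list(X))
        probs = np.concatenate([p.class_probs for p in preds])
        # column order follows classes_
        cols = self.classes_ - self._class_offset
        return probs[:, cols]

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def predict_phase(self, X):
        """Per-token phase labels and probabilities for each window."""
        preds, _ = self._forward_eval(list(X))
        probs = np.concatenate([p.phase_probs for p in preds])
        return probs.argmax(axis=-1), probs

    def predict_stability(self, X):
        preds, _ = self._forward_eval(list(X))
        return np.concatenate([p.stability.data for p in preds])

    def diagnostics(self, X):
        """Mean fusion weights per modality and alignment lags on X."""
        _, diags = self._forward_eval(list(X))
        out = {}
        oms = [d["omega"] for d in diags if d.get("omega") is not None]
        if oms:
            om = np.concatenate(oms).mean(axis=(0, 1))
            out.update(omega_skeleton=om[0], omega_imu=om[1], omega_emg=om[2])
        if diags and "lag_imu" in diags[0]:
            out["lag_imu"] = float(np.mean([d["lag_imu"] for d in diags]))
            out["lag_emg"] = float(np.mean([d["lag_emg"] for d in diags]))
            out["delta_imu"] = diags[0].get("delta_imu")
            out["delta_emg"] = diags[0].get("delta_emg")
        return out

    def phase_token_labels(self, windows):
        """Ground-truth phase labels at the token rate (nearest frame)."""
        batch = collate(list(windows))
        return self._labels(batch, self._factor)["phase"]
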