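"""Multi-task heads, the joint loss, modality dropout, and the training
protocol (splits, leakage guard, capacity sanity check)."""

import copy

import numpy as np
import pandas as pd
import pytest

from motionfuse.nn import Tensor
from motionfuse.nn.tensor import autodiff_dtype
from motionfuse.model import (LossWeights, MotionStateClassifier,
                              MultiTaskHeads, PredictionBundle,
                              apply_modality_dropout, collate,
                              multitask_loss)
from motionfuse.preprocess import UnifiedWindow
from motionfuse.training import assert_no_leakage, fold_assignments, run_training


def _zero_heads(d=8, C=12, P=4):
    heads = MultiTaskHeads(np.random.default_rng(0), d, C, P)
    for _, p in heads.named_parameters():
        p.data[:] = 0.0
    return heads


def test_zero_everything_gives_uniform_and_half():
    heads = _zero_heads()
    z = Tensor(np.zeros((3, 5, 8)))
    pred = heads(z)
    assert np.allclose(pred.class_probs, 1 / 12, atol=1e-7)
    assert np.allclose(pred.stability.data, 0.5)
    assert np.abs(pred.phase_probs.sum(axis=-1) - 1.0).max() < 1e-6


def test_phase_rows_normalized_random_inputs(rng):
    heads = MultiTaskHeads(np.random.default_rng(1), 8, 12, 4)
    pred = heads(Tensor(rng.standard_normal((2, 6, 8))))
    assert np.abs(pred.phase_probs.sum(axis=-1) - 1.0).max() < 1e-6
    assert np.abs(pred.class_probs.sum(axis=-1) - 1.0).max() < 1e-6
    assert ((pred.stability.data >= 0) & (pred.stability.data <= 1)).all()


def _labels(B=2, T=5):
    return {"action": np.zeros(B, int), "phase": np.zeros((B, T), int),
            "stability": np.full(B, 0.5)}


def test_perfect_predictions_zero_loss():
    with autodiff_dtype(np.float64):
        B, T, C, P = 2, 5, 3, 2
        big = 200.0
        cls_logits = np.full((B, C), -big)
        cls_logits[:, 0] = big
        ph_logits = np.full((B, T, P), -big)
        ph_logits[..., 0] = big
        pred = PredictionBundle(Tensor(cls_logits), Tensor(ph_logits),
                                Tensor(np.full(B, 0.5)))
        z = Tensor(np.ones((B, T, 4)))
        total, comps = multitask_loss(pred, _labels(B, T), z)
        assert comps["total"] < 1e-9


def test_uniform_class_prediction_entropy():
    with autodiff_dtype(np.float64):
        B, T = 4, 3
        pred = PredictionBundle(Tensor(np.zeros((B, 12))),
                                Tensor(np.zeros((B, T, 4))),
                                Tensor(np.full(B, 0.5)))
        z = Tensor(np.zeros((B, T, 4)))
        _, comps = multitask_loss(pred, _labels(B, T), z)
        assert comps["cls"] == pytest.approx(np.log(12), abs=1e-9)


def test_loss_weight_linearity(rng):
    pred = PredictionBundle(Tensor(rng.standard_normal((2, 12))),
                            Tensor(rng.standard_normal((2, 5, 4))),
                            Tensor(np.full(2, 0.3)))
    z = Tensor(rng.standard_normal((2, 5, 4)))
    labels = _labels()
    _, c1 = multitask_loss(pred, labels, z, LossWeights(lam_phase=1.0))
    t2, c2 = multitask_loss(pred, labels, z, LossWeights(lam_phase=2.0))
    assert c2["phase"] == pytest.approx(c1["phase"])
    expected_total = c1["total"] + c1["phase"]
    assert c2["total"] == pytest.approx(expected_total, rel=1e-6)


def test_out_of_range_labels_raise(rng):
    pred = PredictionBundle(Tensor(rng.standard_normal((1, 12))),
                            Tensor(rng.standard_normal((1, 5, 4))),
                            Tensor(np.full(1, 0.3)))
    z = Tensor(rng.standard_normal((1, 5, 4)))
    labels = _labels(1, 5)
    labels["action"] = np.array([12])
    with pytest.raises(ValueError):
        multitask_loss(pred, labels, z)


def _window(rng, T_g=16):
    return UnifiedWindow(
        skeleton_n=rng.standard_normal((T_g, 4, 2)),
        imu_n=rng.standard_normal((T_g, 3)),
        emg_n=rng.standard_normal((T_g, 2)),
        validity={"skeleton": np.ones((T_g, 4), bool),
                  "imu": np.ones(T_g, bool), "emg": np.ones(T_g, bool)},
        grid_rate=4.0, action_class=1, phase=np.zeros(T_g, int),
        stability=0.8)


def test_modality_dropout_identity_at_zero(rng):
    w = _window(rng)
    out = apply_modality_dropout(w, 0.0, np.random.default_rng(0))
    assert np.array_equal(out.imu_n, w.imu_n)


def test_modality_dropout_survivor_rule(rng):
    w = _window(rng)
    # p=1 with skeleton eligible: exactly one modality survives
    for seed in range(10):
        out = apply_modality_dropout(w, 1.0, np.random.default_rng(seed),
                                     include_skeleton=True)
        alive = [m for m in ("skeleton", "imu", "emg")
                 if out.validity[m].any()]
        assert len(alive) == 1
    with pytest.raises(ValueError):
        apply_modality_dropout(w, 1.5, np.random.default_rng(0))


def test_modality_dropout_monte_carlo_frequency(rng):
    w = _window(rng)
    drop_rng = np.random.default_rng(123)
    n, hits = 10_000, {"imu": 0, "emg": 0}
    for _ in range(n):
        out = apply_modality_dropout(w, 0.2, drop_rng)
        for m in hits:
            hits[m] += not out.validity[m].any()
    for m in hits:
        assert abs(hits[m] / n - 0.2) < 0.02
    # skeleton anchor is never dropped by default
    out = apply_modality_dropout(w, 1.0, np.random.default_rng(7))
    assert out.validity["skeleton"].all()


def test_leakage_assertion():
    assert_no_leakage(["a", "b"], ["c"], ["d"])
    with pytest.raises(AssertionError):
        assert_no_leakage(["a", "b"], ["b"], ["d"])


def test_fold_assignments_rotate_and_stay_disjoint():
    man = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(10)],
        "split": ["train"] * 7 + ["val"] + ["test"] * 2})
    folds = list(fold_assignments(man, 4, seed=0))
    assert len(folds) == 4
    vals = [set(v) for _, v, _ in folds]
    assert set.union(*vals) == {f"S{i}" for i in range(8)}
    for tr, va, te in folds:
        assert not set(tr) & set(va)
        assert set(te) == {"S8", "S9"}


def test_zero_loss_weights_leave_parameters_unchanged(small_windows):
    est = MotionStateClassifier(epochs=1, lam_cls=0, lam_phase=0, lam_stab=0,
                                lam_smooth=0, modality_dropout_p=0.0,
                                token_rate=4.0, d_model=16, skeleton_layers=1,
                                align_layers=1, backbone_layers=1,
                                skeleton_heads=2, backbone_heads=2,
                                skeleton_ffn=32, backbone_ffn=32,
                                imu_hidden=8, weight_decay=0.0, seed=0)
    wins = small_windows[:8]
    est.fit(wins)
    before = copy.deepcopy(est.network_.state_dict())
    # second epoch via a fresh fit would reinit; instead check grads are
    # zero by re-fitting with 1 epoch and comparing to a 0-epoch clone
    est2 = MotionStateClassifier(**est.get_params())
    est2.fit(wins)
    after = est2.network_.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k]), k


def test_overfit_capacity_sanity(small_windows):
    """A small model driven by the classification objective alone memorizes
    a handful of windows (standard capacity sanity check)."""
    wins = small_windows[:16]
    est = MotionStateClassifier(       # 200 optimization steps
        epochs=200, batch_size=16, lam_phase=0.0, lam_stab=0.0,
        lam_smooth=0.0, modality_dropout_p=0.0, token_rate=4.0,
        d_model=32, skeleton_layers=1, align_layers=1, backbone_layers=1,
        skeleton_heads=2, backbone_heads=2, skeleton_ffn=64,
        backbone_ffn=64, imu_hidden=16, lr_start=3e-3, lr_end=3e-4,
        weight_decay=0.0, seed=0)
    est.fit(wins)
    y = np.array([w.action_class for w in wins])
    assert (est.predict(wins) == y).mean() == 1.0
    assert est.history_.loss.iloc[-1] < 0.01


def test_cross_fold_training_bookkeeping(small_dataset, desk_pre_cfg):
    sessions, manifest = small_dataset
    params = dict(epochs=2, d_model=16, skeleton_layers=1, align_layers=1,
                  backbone_layers=1, skeleton_heads=2, backbone_heads=2,
                  skeleton_ffn=32, backbone_ffn=32, imu_hidden=8,
                  token_rate=4.0)
    result = run_training(sessions, manifest, desk_pre_cfg, params,
                          n_folds=2, seed=0)
    assert len(result["models"]) == 2
    assert {"mean", "sd"} <= set(result["summary"].columns)
    assert len(result["folds"]) == 2
    hist = result["models"][0][0].history_
    assert {"loss", "val_loss", "lag_imu", "omega_s"} <= set(hist.columns)
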