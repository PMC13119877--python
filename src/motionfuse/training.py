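"""Training protocol: subject-independent partitions, k-fold rotation of
the validation subjects, leakage assertions, and cross-fold summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import MetricsReport, compute_metrics
from .model import MotionStateClassifier
from .preprocess import PreprocessConfig, SessionPreprocessor
from .synthgen import PerturbationSpec, perturb

__all__ = ["fold_assignments", "assert_no_leakage", "evaluate_model",
           "augment_sessions", "run_training"]


def augment_sessions(sessions, seed: int, p_perturb: float = 0.5):
    """Condition-diversity augmentation of a training partition.

    Each session is independently left clean (probability ``1 -
    p_perturb``) or given one corruption drawn uniformly from {joint
    occlusion at a fraction in 30-50%, viewpoint rotation +/-15 deg,
    20 dB additive sensor noise} — emulating acquisition campaigns that
    deliberately include occluded, rotated and noisy recordings.  Labels
    are untouched.  Total modality loss is excluded (training-time
    modality dropout already covers it).
    """
    rng = np.random.default_rng([seed, 977])
    out = []
    for i, sess in enumerate(sessions):
        if rng.random() >= p_perturb:
            out.append(sess)
            continue
        kind = rng.choice(["occlusion", "viewpoint", "sensor_noise"])
        if kind == "occlusion":
            spec = PerturbationSpec(kind="occlusion",
                                    occlusion_fraction=rng.uniform(0.3, 0.5))
        elif kind == "viewpoint":
            spec = PerturbationSpec(kind="viewpoint", rotation_deg=15.0)
        else:
            spec = PerturbationSpec(kind="sensor_noise", snr_db=20.0)
        out.append(perturb(sess, spec, rng_state=int(rng.integers(2 ** 31))))
    return out


def assert_no_leakage(*subject_groups):
    """Abort when any subject appears in more than one partition."""
    seen: dict[str, int] = {}
    for gi, group in enumerate(subject_groups):
        for s in group:
            if s in seen and seen[s] != gi:
                raise AssertionError(
                    f"subject {s} appears in two partitions ({seen[s]}, {gi})")
            seen[s] = gi


def fold_assignments(manifest: pd.DataFrame, n_folds: int, seed: int = 0):
    """Rotate validation subjects among the train+val pool; the test
    partition stays fixed.  Yields (train_subjects, val_subjects,
    test_subjects) per fold."""
    pool = sorted(set(manifest.loc[manifest.split != "test", "subject_id"]))
    test = sorted(set(manifest.loc[manifest.split == "test", "subject_id"]))
    order = np.random.default_rng([seed, 41]).permutation(len(pool))
    groups = [list(np.array(pool)[order[i::n_folds]]) for i in range(n_folds)]
    for i in range(n_folds):
        val = groups[i]
        train = [s for j, g in enumerate(groups) if j != i for s in g]
        assert_no_leakage(train, val, test)
        yield sorted(train), sorted(val), test


def evaluate_model(est: MotionStateClassifier, windows) -> tuple[MetricsReport, dict]:
    """Full metric suite + fusion/alignment diagnostics on a window set."""
    windows = list(windows)
    y_true = np.array([w.action_class for w in windows])
    probs = est.predict_proba(windows)
    y_pred = est.classes_[probs.argmax(axis=1)]
    phase_pred, phase_probs = est.predict_phase(windows)
    phase_true = est.phase_token_labels(windows)
    report = compute_metrics(
        y_true, y_pred, scores=probs,
        phase_true=list(phase_true), phase_pred=list(phase_pred),
        phase_probs=list(phase_probs), classes=est.classes_)
    return report, est.diagnostics(windows)


def run_training(sessions, manifest: pd.DataFrame,
                 pre_config: PreprocessConfig | None = None,
                 est_params: dict | None = None, n_folds: int = 1,
                 seed: int = 0, verbose: int = 0,
                 augment_p: float = 0.0):
    """Train under the subject-independent protocol.

    With ``n_folds > 1`` the validation subjects rotate through the
    train+val pool (test subjects never move); results are summarized as
    mean +/- sd across folds.  ``augment_p`` > 0 applies condition-
    diversity augmentation (:func:`augment_sessions`) to the training
    partition only.  Returns a dict with fitted estimators, per-fold test
    reports, diagnostics and the summary frame.
    """
    pre_config = pre_config or PreprocessConfig()
    est_params = dict(est_params or {})
    by_subject: dict[str, list] = {}
    for sess in sessions:
        by_subject.setdefault(sess.subject_id, []).append(sess)

    test_subjects = sorted(set(manifest.loc[manifest.split == "test",
                                            "subject_id"]))
    test_sessions = [s for sid in test_subjects for s in by_subject[sid]]

    folds = fold_assignments(manifest, n_folds, seed) if n_folds > 1 else \
        [(sorted(set(manifest.loc[manifest.split == "train", "subject_id"])),
          sorted(set(manifest.loc[manifest.split == "val", "subject_id"])),
          test_subjects)]

    models, reports, diags, rows = [], [], [], []
    for fold_i, (tr_subj, va_subj, te_subj) in enumerate(folds):
        assert_no_leakage(tr_subj, va_subj, te_subj)
        train_sessions = [s for sid in tr_subj for s in by_subject[sid]]
        if augment_p > 0:
            train_sessions = augment_sessions(train_sessions,
                                              seed + fold_i, augment_p)
        val_sessions = [s for sid in va_subj for s in by_subject[sid]]
        pre = SessionPreprocessor(pre_config).fit(train_sessions)
        w_tr = pre.transform(train_sessions)
        w_va = pre.transform(val_sessions)
        w_te = pre.transform(test_sessions)

        est = MotionStateClassifier(
            **{**est_params, "seed": est_params.get("seed", seed) + fold_i,
               "verbose": verbose})
        est.fit(w_tr, eval_set=w_va if w_va else None)
        report, diag = evaluate_model(est, w_te)
        models.append((est, pre))
        reports.append(report)
        diags.append(diag)
        rows.append({"fold": fold_i, "accuracy": report.accuracy,
                     "f1": report.f1, "map": report.map,
                     "f1_at_25": report.f1_at_25,
                     "stability": report.stability, **diag})
    frame = pd.DataFrame(rows)
    metric_cols = [c for c in frame.columns if c != "fold"]
    summary = pd.DataFrame({"mean": frame[metric_cols].mean(),
                            "sd": frame[metric_cols].std(ddof=0)})
    return {"models": models, "reports": reports, "diagnostics": diags,
            "folds": frame, "summary": summary}
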