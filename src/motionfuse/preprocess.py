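"""Preprocessing chain: keypoint normalization, band-pass + Z-score,
cubic-spline resampling to a unified temporal grid, and fixed windows.

Order of operations per session:

1. skeleton keypoints are normalized per frame (centroid removed, divided by
   a body-scale reference);
2. EMG is zero-phase Butterworth band-passed at its native rate, then
   Z-scored per channel; IMU is Z-scored (band-pass optional);
   Z-score statistics come from the training partition and are frozen;
3. every stream (and validity mask) is resampled to a common grid with a
   natural cubic spline sharing time zero;
4. the grid is cut into fixed-length sliding windows carrying the trial's
   action class, nearest-frame phase labels and stability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .synthgen import SyntheticSession

__all__ = [
    "PreprocessConfig", "UnifiedWindow", "normalize_keypoints",
    "filter_standardize", "resample_to_grid", "segment_windows",
    "windows_from_session", "SessionPreprocessor",
]

_EPS_SCALE = 1e-8

# COCO-17 indices used by the body-scale references
_SHOULDERS, _HIPS = (5, 6), (11, 12)


@dataclass
class PreprocessConfig:
    grid_rate: float = 1000.0          # Hz; desk-scale runs use 25
    window_seconds: float = 4.0
    window_stride_seconds: float = 2.0
    bandpass: tuple[float, float, int] = (20.0, 450.0, 4)  # low, high, order
    scale_reference: str = "torso_length"   # or shoulder_width / centroid_rms
    imu_bandpass: tuple[float, float, int] | None = None

    def __post_init__(self):
        low, high, order = self.bandpass
        if not (0 < low < high):
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.window_stride_seconds > self.window_seconds:
            raise ValueError("window_stride must be <= window length")
        if self.grid_rate <= 0:
            raise ValueError("grid_rate must be positive")


@dataclass
class UnifiedWindow:
    """All three modalities on one temporal grid, with label sidecar."""

    skeleton_n: np.ndarray            # [T_g, J, 2]
    imu_n: np.ndarray                 # [T_g, C_I]
    emg_n: np.ndarray                 # [T_g, C_E]
    validity: dict                    # skeleton [T_g, J]; imu/emg [T_g]
    grid_rate: float
    action_class: int                 # 1-based
    phase: np.ndarray                 # [T_g] ints
    stability: float
    subject_id: str = ""
    session_id: str = ""


def _frame_scale(frame: np.ndarray, valid: np.ndarray, reference: str) -> float:
    """Body-scale reference for one frame; NaN when undefinable."""
    if reference == "torso_length" and frame.shape[0] >= 13 and \
            valid[list(_SHOULDERS)].all() and valid[list(_HIPS)].all():
        mid_sh = frame[list(_SHOULDERS)].mean(axis=0)
        mid_hip = frame[list(_HIPS)].mean(axis=0)
        return float(np.linalg.norm(mid_sh - mid_hip))
    if reference == "shoulder_width" and frame.shape[0] >= 7 and \
            valid[list(_SHOULDERS)].all():
        return float(np.linalg.norm(frame[_SHOULDERS[0]] - frame[_SHOULDERS[1]]))
    # fallback / explicit centroid-RMS scale
    pts = frame[valid]
    if len(pts) < 2:
        return float("nan")
    mu = pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pts - mu) ** 2, axis=1))))


def normalize_keypoints(frames: np.ndarray, scale_reference: str = "torso_length",
                        mask: np.ndarray | None = None,
                        scale: float | np.ndarray | None = None):
    """Per-frame centroid removal and body-scale division.

    Parameters
    ----------
    frames : [T, J, 2] keypoints.
    scale_reference : which body length defines the per-frame scale.
    mask : [T, J] joint validity; invalid joints are excluded from the
        centroid/scale and stay masked in the output.
    scale : optional explicit per-frame scale overriding the reference.

    Returns ``(normalized, mask_out)``.  Frames with a degenerate scale
    (all joints coincident) are zeroed and fully masked rather than divided.
    """
    frames = np.asarray(frames, dtype=float)
    T, J, _ = frames.shape
    mask = np.ones((T, J), dtype=bool) if mask is None else mask.copy()
    out = np.zeros_like(frames)
    if scale is not None:
        scale = np.broadcast_to(np.asarray(scale, dtype=float), (T,))
    for t in range(T):
        valid = mask[t]
        if valid.sum() < 2:
            mask[t] = False
            continue
        mu = frames[t, valid].mean(axis=0)
        s = scale[t] if scale is not None else \
            _frame_scale(frames[t], valid, scale_reference)
        if not np.isfinite(s) or s < _EPS_SCALE:
            mask[t] = False          # degenerate pose: flag, do not divide
            continue
        out[t, valid] = (frames[t, valid] - mu) / s
    return out, mask


def filter_standardize(stream: np.ndarray, rate: float, cfg: PreprocessConfig,
                       modality: str, stats: tuple | None = None):
    """Butterworth band-pass (EMG; IMU optional) then per-channel Z-score.

    ``stats`` is an optional frozen ``(mean, sd)`` pair (training-partition
    statistics); when absent the stream standardizes itself.  Returns
    ``(standardized, (mean, sd))``.  Skeleton streams pass through untouched.
    """
    x = np.asarray(stream, dtype=float)
    if modality == "skeleton":
        return x, (np.zeros(1), np.ones(1))
    band = cfg.bandpass if modality == "emg" else cfg.imu_bandpass
    if band is not None:
        low, high, order = band
        if high >= rate / 2:
            raise ValueError(
                f"band edge {high} Hz at/above Nyquist ({rate / 2} Hz)")
        if x.shape[0] <= 3 * order:
            raise ValueError("stream too short for the filter order")
        sos = butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    if stats is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
    else:
        mean, sd = stats
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x - mean) / sd, (mean, sd)


def resample_to_grid(stream: np.ndarray, src_rate: float, grid_rate: float,
                     n_out: int | None = None):
    """Cubic-spline resampling onto a uniform grid sharing time zero.

    Not-a-knot end conditions (so cubic signals are reproduced exactly,
    including near the edges).  Source sample times are reproduced exactly;
    grid points beyond the last source sample are never extrapolated (held
    at the last value and flagged invalid).  Returns ``(grid_stream,
    valid)``.
    """
    if grid_rate <= 0:
        raise ValueError("grid_rate must be positive")
    x = np.asarray(stream, dtype=float)
    T = x.shape[0]
    if T < 4:
        raise ValueError("cubic spline needs at least 4 samples")
    t_src = np.arange(T) / src_rate
    t_end = t_src[-1]
    if n_out is None:
        n_out = int(np.floor(t_end * grid_rate + 1e-9)) + 1
    t_grid = np.arange(n_out) / grid_rate
    valid = t_grid <= t_end + 1e-12
    cs = CubicSpline(t_src, x, axis=0, bc_type="not-a-knot")
    out = np.empty((n_out,) + x.shape[1:], dtype=float)
    out[valid] = cs(t_grid[valid])
    if (~valid).any():
        out[~valid] = x[-1]
    return out, valid


def _nearest_frame(t_grid: np.ndarray, src_rate: float, n_src: int) -> np.ndarray:
    return np.clip(np.round(t_grid * src_rate).astype(int), 0, n_src - 1)


def segment_windows(grid: dict, cfg: PreprocessConfig) -> list[UnifiedWindow]:
    """Cut a preprocessed session (dict of grid-rate arrays) into sliding
    fixed-length windows."""
    T_g = grid["skeleton_n"].shape[0]
    win = int(round(cfg.window_seconds * cfg.grid_rate))
    hop = int(round(cfg.window_stride_seconds * cfg.grid_rate))
    if T_g < win:
        warnings.warn("session shorter than one window; returning none")
        return []
    starts = range(0, T_g - win + 1, hop)
    out = []
    for s in starts:
        sl = slice(s, s + win)
        out.append(UnifiedWindow(
            skeleton_n=grid["skeleton_n"][sl],
            imu_n=grid["imu_n"][sl],
            emg_n=grid["emg_n"][sl],
            validity={k: v[sl] for k, v in grid["validity"].items()},
            grid_rate=cfg.grid_rate,
            action_class=grid["action_class"],
            phase=grid["phase"][sl],
            stability=grid["stability"],
            subject_id=grid.get("subject_id", ""),
            session_id=grid.get("session_id", ""),
        ))
    return out


def windows_from_session(session: SyntheticSession, cfg: PreprocessConfig,
                         stats: dict | None = None) -> list[UnifiedWindow]:
    """Full chain for one session: normalize, filter+standardize, resample,
    window.  ``stats`` holds frozen per-modality Z-score statistics."""
    r_s, r_i, r_e = session.rates
    stats = stats or {}

    skel_n, skel_mask = normalize_keypoints(
        session.skeleton, cfg.scale_reference, mask=session.masks["skeleton"])
    imu_z, _ = filter_standardize(session.imu, r_i, cfg, "imu",
                                  stats.get("imu"))
    emg_z, _ = filter_standardize(session.emg, r_e, cfg, "emg",
                                  stats.get("emg"))
    if not session.masks["imu"].any():      # lost modality stays lost
        imu_z = np.zeros_like(imu_z)
    if not session.masks["emg"].any():
        emg_z = np.zeros_like(emg_z)

    T_s = skel_n.shape[0]
    n_out = int(np.floor((T_s - 1) / r_s * cfg.grid_rate + 1e-9)) + 1
    skel_g, v_s = resample_to_grid(
        skel_n.reshape(T_s, -1), r_s, cfg.grid_rate, n_out)
    skel_g = skel_g.reshape(-1, *skel_n.shape[1:])
    imu_g, v_i = resample_to_grid(imu_z, r_i, cfg.grid_rate, n_out)
    emg_g, v_e = resample_to_grid(emg_z, r_e, cfg.grid_rate, n_out)

    t_grid = np.arange(n_out) / cfg.grid_rate
    f_near = _nearest_frame(t_grid, r_s, T_s)
    skel_valid = skel_mask[f_near] & v_s[:, None]
    imu_valid = session.masks["imu"][_nearest_frame(t_grid, r_i, len(session.imu))] & v_i
    emg_valid = session.masks["emg"][_nearest_frame(t_grid, r_e, len(session.emg))] & v_e
    phase_g = session.phase_labels[f_near]

    grid = {
        "skeleton_n": skel_g, "imu_n": imu_g, "emg_n": emg_g,
        "validity": {"skeleton": skel_valid, "imu": imu_valid, "emg": emg_valid},
        "phase": phase_g, "action_class": session.action_class,
        "stability": session.stability_true,
        "subject_id": session.subject_id, "session_id": session.session_id,
    }
    return segment_windows(grid, cfg)


class SessionPreprocessor:
    """scikit-learn style transformer: sessions -> UnifiedWindow lists.

    ``fit`` computes per-channel Z-score statistics of the band-passed
    IMU/EMG streams over the supplied (training) sessions and freezes them;
    ``transform`` applies the full chain with the frozen statistics, so
    validation/test data never contribute to normalization (no leakage
    under the subject-independent protocol).
    """

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()

    def get_params(self, deep=True):
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, sessions, y=None):
        cfg = self.config
        sums, sqs, counts = {}, {}, {}
        for sess in sessions:
            for name, rate in (("imu", sess.rates[1]), ("emg", sess.rates[2])):
                x = getattr(sess, name)
                band = cfg.bandpass if name == "emg" else cfg.imu_bandpass
                if band is not None:
                    low, high, order = band
                    sos = butter(order, [low, high], btype="bandpass",
                                 fs=rate, output="sos")
                    x = sosfiltfilt(sos, x, axis=0)
                sums[name] = sums.get(name, 0) + x.sum(axis=0)
                sqs[name] = sqs.get(name, 0) + (x ** 2).sum(axis=0)
                counts[name] = counts.get(name, 0) + x.shape[0]
        self.stats_ = {}
        for name in sums:
            mean = sums[name] / counts[name]
            var = sqs[name] / counts[name] - mean ** 2
            self.stats_[name] = (mean, np.sqrt(np.maximum(var, 0.0)))
        return self

    def transform(self, sessions) -> list[UnifiedWindow]:
        if not hasattr(self, "stats_"):
            raise RuntimeError("SessionPreprocessor must be fit first")
        out = []
        for sess in sessions:
            out.extend(windows_from_session(sess, self.config, self.stats_))
        return out

    def fit_transform(self, sessions, y=None):
        return self.fit(sessions).transform(sessions)
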