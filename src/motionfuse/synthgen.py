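"""Synthetic multimodal motion sessions: skeleton / IMU / EMG with known lags.

Each trial is built from an analytic, differentiable joint-trajectory model so
that the three streams are kinematically consistent by construction:

* **Skeleton** (30 Hz): per-class banks of joint sinusoids (class-specific
  fundamental frequency in 0.5-2.5 Hz plus a second harmonic) on top of a
  rest pose, with subject-specific scale and measurement noise.  A smooth
  "jitter" perturbation with trial-specific amplitude drives the ground-truth
  stability score.
* **IMU** (100 Hz): the *analytic* second time-derivative of designated limb
  joints, sampled at the sensor clock (shifted by the injected clock offset),
  plus a constant gravity bias on one axis per sensor and white noise.
* **EMG** (1000 Hz): band-limited (20-450 Hz) noise carrier amplitude
  modulated by a rectified joint-speed envelope that *leads* the kinematics
  by the neuromuscular latency, recorded with its own clock offset.

Because IMU/EMG are evaluated from the same continuous-time model, the
injected offsets are recoverable by cross-correlation — the property the
alignment module is later trained to absorb.

Quantified corruptions (joint occlusion, viewpoint rotation, additive noise
at a target SNR, total modality loss) are applied by :func:`perturb`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "GeneratorConfig", "SyntheticSession", "PerturbationSpec",
    "synthesize_trial", "generate_dataset", "perturb",
    "save_session", "load_session", "save_dataset", "load_dataset",
]

# Approximate COCO-17 rest pose (x, y), y up, units ~ body heights.
_COCO17_POSE = np.array([
    [0.00, 0.95],   # nose
    [-0.03, 0.97], [0.03, 0.97],     # eyes
    [-0.07, 0.95], [0.07, 0.95],     # ears
    [-0.18, 0.78], [0.18, 0.78],     # shoulders
    [-0.25, 0.55], [0.25, 0.55],     # elbows
    [-0.28, 0.32], [0.28, 0.32],     # wrists
    [-0.12, 0.40], [0.12, 0.40],     # hips
    [-0.14, 0.20], [0.14, 0.20],     # knees
    [-0.15, 0.00], [0.15, 0.00],     # ankles
])

# Limb joints used as IMU / EMG sources (wrists, ankles, elbows, knees).
_LIMB_JOINTS_17 = [9, 10, 15, 16, 7, 8, 13, 14]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic acquisition campaign."""

    n_subjects: int = 20
    trials_per_subject: int = 12
    n_classes: int = 12
    n_joints: int = 17
    imu_channels: int = 9
    emg_channels: int = 8
    rates: tuple[float, float, float] = (30.0, 100.0, 1000.0)  # skel, imu, emg
    trial_duration: float = 4.0
    offset_range: float = 0.05       # s, +/- bound of per-modality clock offset
    emg_latency: float = 0.04        # s, EMG envelope lead over kinematics
    noise_floor: dict = field(default_factory=lambda: {
        "skeleton": 0.01, "imu": 0.05, "emg": 0.02})
    jitter_max: float = 0.06         # max smooth-jitter amplitude (stability 0)
    offset_fixed: dict | None = None  # e.g. {"imu": 0.75, "emg": 0.75} seconds
    phase_count: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be strictly positive")
        if self.offset_range < 0:
            raise ValueError("offset_range must be >= 0")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        for k in ("n_subjects", "trials_per_subject", "n_joints",
                  "imu_channels", "emg_channels", "phase_count"):
            if getattr(self, k) < 1:
                raise ValueError(f"{k} must be a positive integer")


@dataclass
class SyntheticSession:
    subject_id: str
    session_id: str
    skeleton: np.ndarray          # [T_s, J, 2] at rates[0]
    imu: np.ndarray               # [T_i, C_I] at rates[1]
    emg: np.ndarray               # [T_e, C_E] at rates[2]
    action_class: int             # 1-based
    phase_labels: np.ndarray      # [T_s] ints in [0, phase_count)
    stability_true: float
    offsets_true: dict            # {"imu": s, "emg": s}
    rates: tuple[float, float, float]
    masks: dict = field(default_factory=dict)  # validity per modality

    def __post_init__(self):
        if not self.masks:
            self.masks = {
                "skeleton": np.ones(self.skeleton.shape[:2], dtype=bool),
                "imu": np.ones(len(self.imu), dtype=bool),
                "emg": np.ones(len(self.emg), dtype=bool),
            }

    def copy(self) -> "SyntheticSession":
        return SyntheticSession(
            subject_id=self.subject_id, session_id=self.session_id,
            skeleton=self.skeleton.copy(), imu=self.imu.copy(),
            emg=self.emg.copy(), action_class=self.action_class,
            phase_labels=self.phase_labels.copy(),
            stability_true=self.stability_true,
            offsets_true=dict(self.offsets_true), rates=self.rates,
            masks={k: v.copy() for k, v in self.masks.items()})


@dataclass
class PerturbationSpec:
    kind: str = "none"            # occlusion | viewpoint | sensor_noise | modality_loss | none
    occlusion_fraction: float = 0.4
    rotation_deg: float = 15.0
    snr_db: float = 20.0
    lost_modality: str = "emg"    # skeleton | imu | emg

    _KINDS = ("occlusion", "viewpoint", "sensor_noise", "modality_loss", "none")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "occlusion" and not (0.0 <= self.occlusion_fraction <= 1.0):
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.kind == "modality_loss" and self.lost_modality not in (
                "skeleton", "imu", "emg"):
            raise ValueError(f"unknown modality {self.lost_modality!r}")


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------

class _SinusoidBank:
    """Analytic joint trajectories: base + sum_k A sin(w_k t + phi).

    Amplitudes/phases have shape [J, 2, K]; angular frequencies [K] are
    shared across joints.  Position, velocity and acceleration are exact.
    """

    def __init__(self, base: np.ndarray, amp: np.ndarray,
                 omega: np.ndarray, phase: np.ndarray):
        self.base, self.amp, self.omega, self.phase = base, amp, omega, phase

    def _terms(self, t: np.ndarray, deriv: int) -> np.ndarray:
        # t: [T] -> [T, J, 2]
        arg = self.omega[None, :] * t[:, None] + np.pi / 2 * deriv  # sin -> cos -> -sin
        ang = arg[:, None, None, :] + self.phase[None, :, :, :]
        w = self.omega ** deriv
        return np.einsum("tjck,jck,k->tjc", np.sin(ang), self.amp, w)

    def pos(self, t):
        return self.base[None] + self._terms(t, 0)

    def vel(self, t):
        return self._terms(t, 1)

    def acc(self, t):
        return self._terms(t, 2)


def _rest_pose(J: int, rng_layout: np.random.Generator) -> np.ndarray:
    if J == 17:
        return _COCO17_POSE.copy()
    pose = rng_layout.uniform(-0.3, 0.3, (J, 2))
    pose[:, 1] += np.linspace(0.0, 1.0, J)  # roughly vertical chain
    return pose


def _limb_joints(J: int) -> list[int]:
    if J == 17:
        return list(_LIMB_JOINTS_17)
    return list(np.linspace(0, J - 1, min(8, J)).round().astype(int))


def class_fundamental(action_class: int, n_classes: int) -> float:
    """Per-class fundamental frequency, evenly spread over 0.5-2.5 Hz."""
    if n_classes == 1:
        return 1.0
    return 0.5 + 2.0 * (action_class - 1) / (n_classes - 1)


def _class_motif(cfg: GeneratorConfig, action_class: int):
    """Deterministic motif parameters for a class (independent of cfg.seed,
    so every subject performs the same action vocabulary)."""
    rng = np.random.default_rng([97, cfg.n_classes, cfg.n_joints, action_class])
    J = cfg.n_joints
    f0 = class_fundamental(action_class, cfg.n_classes)
    amp = np.empty((J, 2, 2))
    amp[:, :, 0] = rng.uniform(0.06, 0.22, (J, 2))        # fundamental
    amp[:, :, 1] = rng.uniform(0.02, 0.07, (J, 2))        # 2nd harmonic
    phase = rng.uniform(0, 2 * np.pi, (J, 2, 2))
    omega = 2 * np.pi * np.array([f0, 2 * f0])
    return amp, omega, phase, f0


def _emg_carrier(rng: np.random.Generator, n: int, rate: float,
                 delay_s: float = 0.0) -> np.ndarray:
    """Band-limited (20-450 Hz) unit-variance noise carrier, optionally
    delayed by a fractional number of samples (exact FFT phase shift — the
    clock offset displaces the whole recorded waveform)."""
    pad = 512
    white = rng.standard_normal(n + 2 * pad)
    high = min(450.0, 0.45 * rate)
    sos = butter(4, [20.0, high], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, white)
    if delay_s:
        freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
        x = np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * delay_s),
                         n=len(x))
    x = x[pad:pad + n]
    return x / (x.std() + 1e-12)


def synthesize_trial(cfg: GeneratorConfig, subject_id: str, action_class: int,
                     rng_state: int) -> SyntheticSession:
    """Generate one trial; fully determined by (cfg, subject_id, action_class,
    rng_state)."""
    if not 1 <= action_class <= cfg.n_classes:
        raise ValueError(f"action_class {action_class} outside "
                         f"[1, {cfg.n_classes}]")
    sid = str(subject_id)
    subj_idx = (int(sid.lstrip("S")) if sid.startswith("S") and
                sid.lstrip("S").isdigit() else zlib.crc32(sid.encode()) % 2 ** 31)
    rng = np.random.default_rng([cfg.seed, subj_idx, action_class, rng_state])
    subj_rng = np.random.default_rng([cfg.seed, subj_idx, 7919])

    J = cfg.n_joints
    r_s, r_i, r_e = cfg.rates
    T_s = int(round(cfg.trial_duration * r_s))
    T_i = int(round(cfg.trial_duration * r_i))
    T_e = int(round(cfg.trial_duration * r_e))

    amp, omega, phase, f0 = _class_motif(cfg, action_class)
    subj_scale = subj_rng.uniform(0.85, 1.15)
    base = _rest_pose(J, np.random.default_rng([11, J])) * subj_scale

    # smooth jitter: 3 extra sinusoid terms, amplitude sets stability
    jitter_amp = rng.uniform(0.0, cfg.jitter_max)
    stability_true = float(1.0 - jitter_amp / cfg.jitter_max) if cfg.jitter_max > 0 else 1.0
    j_omega = 2 * np.pi * rng.uniform(3.0, 6.0, 3)
    j_amp = jitter_amp * rng.uniform(0.3, 1.0, (J, 2, 3))
    j_phase = rng.uniform(0, 2 * np.pi, (J, 2, 3))

    bank = _SinusoidBank(
        base,
        np.concatenate([amp * subj_scale, j_amp], axis=2),
        np.concatenate([omega, j_omega]),
        np.concatenate([phase, j_phase], axis=2),
    )

    offsets = {
        "imu": float(rng.uniform(-cfg.offset_range, cfg.offset_range)),
        "emg": float(rng.uniform(-cfg.offset_range, cfg.offset_range)),
    }
    if cfg.offset_fixed is not None:   # draws above keep the rng stream
        offsets.update({k: float(v) for k, v in cfg.offset_fixed.items()})

    # ---- skeleton (anchor clock) ----
    t_s = np.arange(T_s) / r_s
    skeleton = bank.pos(t_s)
    skeleton += cfg.noise_floor["skeleton"] * rng.standard_normal(skeleton.shape)

    # ---- IMU: analytic acceleration at sensor clock (content delayed by o_I)
    limbs = _limb_joints(J)
    t_i = np.arange(T_i) / r_i
    acc = bank.acc(t_i - offsets["imu"])           # [T_i, J, 2]
    imu = np.empty((T_i, cfg.imu_channels))
    imu_sources: list[tuple[int, str]] = []
    for c in range(cfg.imu_channels):
        sensor, axis = divmod(c, 3)
        joint = limbs[sensor % len(limbs)]
        if axis == 2:       # gravity axis of this sensor
            imu[:, c] = 9.81 + 0.1 * acc[:, joint, 0]
            imu_sources.append((joint, "g"))
        else:
            imu[:, c] = acc[:, joint, axis]
            imu_sources.append((joint, "xy"[axis]))
    imu += cfg.noise_floor["imu"] * rng.standard_normal(imu.shape)

    # ---- EMG: carrier x rectified speed envelope (leads kinematics)
    t_e = np.arange(T_e) / r_e
    speed = np.linalg.norm(bank.vel(t_e - offsets["emg"] + cfg.emg_latency),
                           axis=2)                 # [T_e, J]
    emg = np.empty((T_e, cfg.emg_channels))
    emg_sources: list[int] = []
    for c in range(cfg.emg_channels):
        joint = limbs[c % len(limbs)]
        env = speed[:, joint]
        env = env / (env.mean() + 1e-12) + 0.15
        carrier = _emg_carrier(rng, T_e, r_e, delay_s=offsets["emg"])
        emg[:, c] = carrier * env
        emg_sources.append(joint)
    emg += cfg.noise_floor["emg"] * rng.standard_normal(emg.shape)

    # ---- phase labels: phase_count contiguous phases per motif cycle
    phase_labels = np.floor((f0 * t_s % 1.0) * cfg.phase_count).astype(np.int64)
    phase_labels = np.clip(phase_labels, 0, cfg.phase_count - 1)

    sess = SyntheticSession(
        subject_id=f"S{subj_idx:03d}" if isinstance(subject_id, int) else str(subject_id),
        session_id=f"{subject_id}_c{action_class:02d}_t{rng_state:03d}",
        skeleton=skeleton, imu=imu, emg=emg, action_class=int(action_class),
        phase_labels=phase_labels, stability_true=stability_true,
        offsets_true=offsets, rates=cfg.rates)
    sess.imu_sources = imu_sources      # channel -> (joint, axis) metadata
    sess.emg_sources = emg_sources
    return sess


# ---------------------------------------------------------------------------
# dataset generation + subject-independent split
# ---------------------------------------------------------------------------

def subject_split(subject_ids: list[str], seed: int,
                  fractions=(0.7, 0.1, 0.2)) -> dict[str, str]:
    """Disjoint subject-level train/val/test assignment (70/10/20)."""
    n = len(subject_ids)
    n_train = int(round(fractions[0] * n))
    n_val = max(1, int(round(fractions[1] * n)))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"{n} subjects cannot fill a {fractions} subject-level split; "
            "need at least 10")
    order = np.random.default_rng([seed, 131]).permutation(n)
    split = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split[subject_ids[idx]] = "train"
        elif rank < n_train + n_val:
            split[subject_ids[idx]] = "val"
        else:
            split[subject_ids[idx]] = "test"
    return split


def generate_dataset(cfg: GeneratorConfig):
    """All subjects x trials, classes balanced per subject.

    Returns ``(sessions, manifest)`` where the manifest is a DataFrame with
    one row per session (session_id, subject_id, action_class, split,
    stability_true) recording the subject-independent 70/10/20 partition.
    """
    subjects = [f"S{i:03d}" for i in range(cfg.n_subjects)]
    split = subject_split(subjects, cfg.seed)
    sessions, rows = [], []
    for s_i, subj in enumerate(subjects):
        for trial in range(cfg.trials_per_subject):
            action = 1 + (trial % cfg.n_classes)   # balanced by construction
            sess = synthesize_trial(cfg, subj, action, rng_state=trial)
            sessions.append(sess)
            rows.append({
                "session_id": sess.session_id, "subject_id": subj,
                "action_class": action, "split": split[subj],
                "stability_true": sess.stability_true,
            })
    manifest = pd.DataFrame(rows)
    return sessions, manifest


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def perturb(session: SyntheticSession, spec: PerturbationSpec,
            rng_state: int = 0) -> SyntheticSession:
    """Apply one quantified corruption; labels are never changed."""
    out = session.copy()
    if spec.kind == "none":
        return out
    rng = np.random.default_rng(
        [rng_state, 223, zlib.crc32(session.session_id.encode()) % 2 ** 31])

    if spec.kind == "occlusion":
        T, J, _ = out.skeleton.shape
        k = int(round(spec.occlusion_fraction * J))
        for t in range(T):
            hit = rng.choice(J, size=k, replace=False)
            out.skeleton[t, hit] = 0.0
            out.masks["skeleton"][t, hit] = False

    elif spec.kind == "viewpoint":
        theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        cent = out.skeleton.mean(axis=1, keepdims=True)   # per-frame centroid
        out.skeleton = (out.skeleton - cent) @ R.T + cent

    elif spec.kind == "sensor_noise":
        factor = 10.0 ** (spec.snr_db / 10.0)
        for name in ("imu", "emg"):
            x = getattr(out, name)
            p_sig = np.mean(x ** 2, axis=0)               # per-channel power
            sd = np.sqrt(p_sig / factor)
            setattr(out, name, x + sd * rng.standard_normal(x.shape))

    elif spec.kind == "modality_loss":
        x = getattr(out, spec.lost_modality)
        setattr(out, spec.lost_modality, np.zeros_like(x))
        out.masks[spec.lost_modality][:] = False

    return out


# ---------------------------------------------------------------------------
# on-disk layout: one HDF5 per session + CSV manifest
# ---------------------------------------------------------------------------

def save_session(session: SyntheticSession, path: str | Path):
    with h5py.File(path, "w", track_order=True) as f:
        for name in ("skeleton", "imu", "emg", "phase_labels"):
            f.create_dataset(name, data=getattr(session, name), track_times=False)
        g = f.create_group("masks")
        for k, v in session.masks.items():
            g.create_dataset(k, data=v, track_times=False)
        f.attrs["subject_id"] = session.subject_id
        f.attrs["session_id"] = session.session_id
        f.attrs["action_class"] = session.action_class
        f.attrs["stability_true"] = session.stability_true
        f.attrs["rates"] = np.asarray(session.rates)
        f.attrs["offset_imu"] = session.offsets_true["imu"]
        f.attrs["offset_emg"] = session.offsets_true["emg"]


def load_session(path: str | Path) -> SyntheticSession:
    with h5py.File(path, "r") as f:
        return SyntheticSession(
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
            skeleton=f["skeleton"][:], imu=f["imu"][:], emg=f["emg"][:],
            action_class=int(f.attrs["action_class"]),
            phase_labels=f["phase_labels"][:],
            stability_true=float(f.attrs["stability_true"]),
            offsets_true={"imu": float(f.attrs["offset_imu"]),
                          "emg": float(f.attrs["offset_emg"])},
            rates=tuple(f.attrs["rates"]),
            masks={k: f["masks"][k][:].astype(bool) for k in f["masks"]})


def save_dataset(sessions, manifest: pd.DataFrame, out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sess in sessions:
        save_session(sess, out / f"{sess.session_id}.h5")
    manifest.to_csv(out / "manifest.csv", index=False)


def load_dataset(data_dir: str | Path):
    data = Path(data_dir)
    manifest = pd.read_csv(data / "manifest.csv")
    sessions = [load_session(data / f"{sid}.h5")
                for sid in manifest["session_id"]]
    return sessions, manifest
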