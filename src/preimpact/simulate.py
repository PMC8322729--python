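"""Seeded synthetic generator of labeled low-back IMU motion trials.

The generator emits 100 Hz 9-channel recordings in the same dialect the I/O
layer reads, covering a catalogue of 21 ADL types (D01-D21, from 30 s static
postures through gait, transitions, a jump and a stumble) and 15 fall types
(F01-F15, crossed over preceding activity and fall plane), with ground-truth
onset/impact labels for falls.

It is an idealized kinematic sketch, not a biomechanical model: each trial
is assembled from a world-frame vertical-acceleration profile, horizontal
sway, and orientation tracks, which are then rotated into the body frame so
that acceleration, angular velocity and Euler channels are mutually
consistent by construction (an upright stationary sensor reads
``(0, -1, 0)`` g).  Falls follow the canonical pre-impact envelope: the
acceleration magnitude dips below ~0.6 g during descent, the vertical
velocity ramps monotonically past 0.5 m/s, the fall-plane angle sweeps
beyond 60 degrees, and a 3-6 g spike marks the impact; fall duration is
drawn from a truncated Normal(746 ms, 150 ms).  A short jerk transient on
the category's sensitive axis marks the onset, as real falls show at the
moment balance is lost.

All randomness flows from one integer seed through counter-derived
sub-sequences, so any single trial — and the whole dataset — is reproducible
piecewise.  Per-subject random effects (gait frequency/amplitude, posture
offset) make subject-wise splitting meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import UsageError
from .io import FallLabel, IMURecording, write_labels, write_recording
from .kinematics import G, rotation_matrices

# ---------------------------------------------------------------------------
# Task catalogues

#: ADL catalogue: task -> (kind, duration_s, trials, params)
ADL_TASKS: dict[str, dict] = {
    "D01": dict(kind="static", duration=30.0, trials=1, pitch=0.0, roll=0.0),
    "D02": dict(kind="bend", duration=8.0, trials=5, angle=65.0, descent=0.25),
    "D03": dict(kind="bend", duration=6.0, trials=5, angle=75.0, descent=0.35),
    "D04": dict(kind="jump", duration=6.0, trials=5, flight=0.25),
    "D05": dict(kind="transition", duration=10.0, trials=5, angle=10.0, descent=0.50,
                move_s=3.0),
    "D06": dict(kind="gait", duration=8.0, trials=5, freq=1.9, amp=0.15, turn=True),
    "D07": dict(kind="gait", duration=8.0, trials=5, freq=2.2, amp=0.20, turn=True),
    "D08": dict(kind="gait", duration=8.0, trials=5, freq=2.5, amp=0.30, turn=True),
    "D09": dict(kind="gait", duration=8.0, trials=5, freq=2.7, amp=0.35, turn=True),
    "D10": dict(kind="stumble", duration=8.0, trials=5, freq=1.9, amp=0.15),
    "D11": dict(kind="static", duration=30.0, trials=1, pitch=5.0, roll=0.0),
    "D12": dict(kind="static", duration=30.0, trials=1, pitch=30.0, roll=0.0),
    "D13": dict(kind="transition", duration=8.0, trials=5, angle=8.0, descent=0.35,
                move_s=2.0),
    "D14": dict(kind="transition", duration=8.0, trials=5, angle=8.0, descent=0.35,
                move_s=1.4),
    "D15": dict(kind="collapse", duration=8.0, trials=5, angle=8.0, descent=0.28,
                move_s=1.5),
    "D16": dict(kind="transition", duration=10.0, trials=5, angle=30.0, descent=0.40,
                move_s=2.5),
    "D17": dict(kind="static", duration=30.0, trials=1, pitch=85.0, roll=0.0),
    "D18": dict(kind="lie", duration=12.0, trials=5, angle=85.0, descent=0.40,
                move_s=3.0),
    "D19": dict(kind="lie", duration=10.0, trials=5, angle=85.0, descent=0.35,
                move_s=2.0),
    "D20": dict(kind="gait", duration=8.0, trials=5, freq=1.6, amp=0.20, turn=False),
    "D21": dict(kind="gait", duration=8.0, trials=5, freq=1.9, amp=0.25, turn=False),
}

#: Fall catalogue: task -> (preceding activity, fall plane, direction sign)
FALL_TASKS: dict[str, dict] = {
    "F01": dict(preceding="sitdown", plane="sagittal", sign=+1,
                description="Forward fall when trying to sit down"),
    "F02": dict(preceding="sitdown", plane="sagittal", sign=-1,
                description="Backward fall when trying to sit down"),
    "F03": dict(preceding="sitdown", plane="frontal", sign=+1,
                description="Lateral fall when trying to sit down"),
    "F04": dict(preceding="getup", plane="sagittal", sign=+1,
                description="Forward fall when trying to get up"),
    "F05": dict(preceding="getup", plane="frontal", sign=+1,
                description="Lateral fall when trying to get up"),
    "F06": dict(preceding="sitting", plane="sagittal", sign=+1,
                description="Forward fall while sitting, caused by fainting"),
    "F07": dict(preceding="sitting", plane="frontal", sign=+1,
                description="Lateral fall while sitting, caused by fainting"),
    "F08": dict(preceding="sitting", plane="sagittal", sign=-1,
                description="Backward fall while sitting, caused by fainting"),
    "F09": dict(preceding="walk", plane="sagittal", sign=+1,
                description="Vertical (forward) fall while walking caused by fainting"),
    "F10": dict(preceding="walk", plane="sagittal", sign=+1,
                description="Fall while walking, use of hands to dampen fall"),
    "F11": dict(preceding="walk", plane="sagittal", sign=+1,
                description="Forward fall while walking caused by a trip"),
    "F12": dict(preceding="jog", plane="sagittal", sign=+1,
                description="Forward fall while jogging caused by a trip"),
    "F13": dict(preceding="walk", plane="sagittal", sign=+1,
                description="Forward fall while walking caused by a slip"),
    "F14": dict(preceding="walk", plane="frontal", sign=+1,
                description="Lateral fall while walking caused by a slip"),
    "F15": dict(preceding="walk", plane="sagittal", sign=-1,
                description="Backward fall while walking caused by a slip"),
}

ALL_TASKS = list(ADL_TASKS) + list(FALL_TASKS)


def fall_category(task_id: str) -> tuple[str, str]:
    """(preceding_activity, fall_plane) labels for the onset-labeling rule."""
    info = FALL_TASKS[task_id]
    preceding = "sitting_faint" if info["preceding"] == "sitting" else "dynamic"
    return preceding, info["plane"]


# ---------------------------------------------------------------------------
# Specification dataclasses

@dataclass
class NoiseSpec:
    """Per-channel sensor noise standard deviations (typical MEMS at 100 Hz)."""

    acc_g: float = 0.005
    gyro_dps: float = 0.5
    euler_deg: float = 0.2

    def __post_init__(self) -> None:
        if min(self.acc_g, self.gyro_dps, self.euler_deg) < 0:
            raise UsageError("noise standard deviations must be non-negative")


@dataclass
class FallParams:
    """Kinematic envelope of a simulated fall."""

    duration_mean_ms: float = 746.0
    duration_sd_ms: float = 150.0
    duration_min_ms: float = 300.0
    accel_peak_ms2: tuple[float, float] = (6.0, 8.0)   # half-sine descent peak
    impact_peak_g: tuple[float, float] = (3.0, 6.0)
    angle_excursion_deg: tuple[float, float] = (70.0, 85.0)
    onset_pulse_acc_g: float = 0.7
    onset_pulse_gyro_dps: float = 300.0

    def __post_init__(self) -> None:
        if self.duration_min_ms <= 0:
            raise UsageError("fall durations must be positive")


@dataclass
class SubjectEffects:
    """Per-subject random effects applied across all of a subject's trials."""

    gait_freq_factor: float = 1.0
    gait_amp_factor: float = 1.0
    posture_offset_deg: float = 0.0


@dataclass
class SimulationSpec:
    n_subjects: int = 32
    tasks: list[str] | None = None          # None = full catalogue
    trials_per_task: int | None = None      # None = catalogue trial counts
    sample_rate_hz: float = 100.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fall: FallParams = field(default_factory=FallParams)
    seed: int = 0


# ---------------------------------------------------------------------------
# Profile assembly

def _smoothstep(n: int) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)
    return 3 * u ** 2 - 2 * u ** 3


def _smoothstep_accel(n: int, fs: float) -> np.ndarray:
    """Second derivative of the unit smoothstep over n frames (per s²)."""
    u = np.linspace(0.0, 1.0, n)
    T = n / fs
    return (6 - 12 * u) / T ** 2


@dataclass
class _Profile:
    """World-frame motion profile before rotation into the body frame."""

    av: np.ndarray          # vertical acceleration, m/s², downward positive
    pitch: np.ndarray       # deg, stored as EulerX
    roll: np.ndarray        # deg, stored as EulerZ
    yaw: np.ndarray         # deg, stored as EulerY
    hx: np.ndarray          # horizontal world acc, g
    hz: np.ndarray
    acc_extra: np.ndarray   # body-frame additive acceleration, g, (n, 3)
    gyro_extra: np.ndarray  # additive angular rate, deg/s, (n, 3)

    @classmethod
    def zeros(cls, n: int) -> "_Profile":
        z = np.zeros(n)
        return cls(av=z.copy(), pitch=z.copy(), roll=z.copy(), yaw=z.copy(),
                   hx=z.copy(), hz=z.copy(), acc_extra=np.zeros((n, 3)),
                   gyro_extra=np.zeros((n, 3)))

    def concat(self, other: "_Profile") -> "_Profile":
        return _Profile(*[np.concatenate([getattr(self, f.name), getattr(other, f.name)])
                          for f in self.__dataclass_fields__.values()])


def _assemble(profile: _Profile, spec: SimulationSpec, rng: np.random.Generator,
              subject_id: str, task_id: str, trial_id: int) -> IMURecording:
    """Rotate the world-frame profile into body-frame channels and add noise."""
    n = len(profile.av)
    fs = spec.sample_rate_hz
    euler = np.column_stack([profile.pitch, profile.yaw, profile.roll])
    measured_down = 1.0 - profile.av / G                       # g units
    world = np.column_stack([profile.hx, -measured_down, profile.hz])
    R = rotation_matrices(euler)
    body = np.einsum("nji,nj->ni", R, world)                   # R.T @ world
    acc = body + profile.acc_extra + rng.normal(0, spec.noise.acc_g, (n, 3))
    gyro = (np.gradient(euler, axis=0) * fs + profile.gyro_extra
            + rng.normal(0, spec.noise.gyro_dps, (n, 3)))
    euler_meas = euler + rng.normal(0, spec.noise.euler_deg, (n, 3))
    return IMURecording(
        subject_id=subject_id, task_id=task_id, trial_id=trial_id,
        sample_rate_hz=fs, time_s=np.arange(n) / fs,
        frame=np.arange(1, n + 1), acc_g=acc, gyro_dps=gyro,
        euler_deg=euler_meas)


def _gait_profile(n: int, fs: float, freq: float, amp_g: float,
                  turn: bool, effects: SubjectEffects) -> _Profile:
    p = _Profile.zeros(n)
    f = freq * effects.gait_freq_factor
    a = amp_g * effects.gait_amp_factor
    t = np.arange(n) / fs
    p.av = a * G * np.sin(2 * np.pi * f * t)
    p.hx = 0.5 * a * np.sin(2 * np.pi * f * t + 1.1)
    p.hz = 0.3 * a * np.sin(2 * np.pi * 2 * f * t + 0.4)
    p.pitch = effects.posture_offset_deg + 3.0 * np.sin(2 * np.pi * f * t + 0.7)
    p.roll = 2.0 * np.sin(2 * np.pi * f * t + 2.1)
    if turn and n > 40:
        lo, hi = n // 3, 2 * n // 3
        p.yaw[lo:hi] = 180.0 * _smoothstep(hi - lo)
        p.yaw[hi:] = 180.0
    return p


def _static_profile(n: int, pitch: float, roll: float,
                    effects: SubjectEffects) -> _Profile:
    p = _Profile.zeros(n)
    p.pitch += pitch + effects.posture_offset_deg
    p.roll += roll
    return p


def _transition_profile(n: int, fs: float, angle: float, descent_m: float,
                        move_frames: int, effects: SubjectEffects,
                        reverse: bool = False, plane: str = "sagittal") -> _Profile:
    """Smooth descent (or rise) with an orientation ramp; sub-threshold velocity."""
    p = _Profile.zeros(n)
    m = min(move_frames, n)
    sign = -1.0 if reverse else 1.0
    ramp = _smoothstep(m)
    accel = sign * descent_m * _smoothstep_accel(m, fs)
    p.av[:m] = accel
    angle_track = np.concatenate([angle * ramp, np.full(n - m, angle)])
    if reverse:
        angle_track = angle - angle_track
    if plane == "frontal":
        p.roll += angle_track
    else:
        p.pitch += angle_track
    p.pitch += effects.posture_offset_deg
    return p


def _jump_profile(n: int, fs: float, flight_s: float,
                  effects: SubjectEffects) -> _Profile:
    p = _Profile.zeros(n)
    v0 = G * flight_s / 2.0
    n_f = int(round(flight_s * fs))
    n_p = max(int(round(0.12 * fs)), 1)
    start = n // 3
    a_pulse = v0 / (n_p / fs)
    seg = np.concatenate([np.full(n_p, -a_pulse), np.full(n_f, G),
                          np.full(n_p, -a_pulse)])
    end = min(start + len(seg), n)
    p.av[start:end] = seg[:end - start]
    p.pitch += effects.posture_offset_deg
    return p


def simulate_adl(task_id: str, spec: SimulationSpec | None = None,
                 seed: int | np.random.SeedSequence = 0,
                 subject_id: str = "S01", trial_id: int = 1,
                 effects: SubjectEffects | None = None) -> IMURecording:
    """One synthetic ADL trial.  Same seed -> identical recording."""
    spec = spec or SimulationSpec()
    if task_id not in ADL_TASKS:
        raise UsageError(f"unknown ADL task {task_id!r}")
    info = ADL_TASKS[task_id]
    effects = effects or SubjectEffects()
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    n = int(round(info["duration"] * fs))
    kind = info["kind"]
    if kind == "static":
        p = _static_profile(n, info["pitch"], info["roll"], effects)
    elif kind == "gait":
        p = _gait_profile(n, fs, info["freq"], info["amp"], info["turn"], effects)
    elif kind in ("transition", "lie", "bend", "collapse"):
        move = int(round(info.get("move_s", 2.0) * fs))
        half = n // 2
        down = _transition_profile(half, fs, info["angle"], info["descent"],
                                   move, effects)
        up = _transition_profile(n - half, fs, info["angle"], info["descent"],
                                 move, effects, reverse=True)
        p = down.concat(up)
        if kind == "collapse":  # abrupt stop at seat contact: brief body-frame jolt
            j = min(half - 1, move)
            p.acc_extra[j:j + 3, 1] -= 1.0
    elif kind == "jump":
        p = _jump_profile(n, fs, info["flight"], effects)
    elif kind == "stumble":
        p = _gait_profile(n, fs, info["freq"], info["amp"], False, effects)
        j = n // 2  # brief catch-step transient, no sustained free fall
        p.acc_extra[j:j + 3, 0] += 1.5
        p.acc_extra[j:j + 3, 1] -= 1.0
    else:  # pragma: no cover - catalogue is closed
        raise UsageError(f"unhandled task kind {kind!r}")
    return _assemble(p, spec, rng, subject_id, task_id, trial_id)


def _preceding_profile(preceding: str, n: int, fs: float,
                       effects: SubjectEffects) -> tuple[_Profile, float]:
    """Pre-fall segment and the posture angle it ends at."""
    if preceding == "walk":
        return _gait_profile(n, fs, 1.9, 0.15, False, effects), 0.0
    if preceding == "jog":
        return _gait_profile(n, fs, 2.5, 0.30, False, effects), 0.0
    if preceding == "sitting":
        return _static_profile(n, 5.0, 0.0, effects), 5.0
    if preceding == "sitdown":
        move = int(round(1.5 * fs))
        return _transition_profile(n, fs, 8.0, 0.35, move, effects), 8.0
    if preceding == "getup":
        move = int(round(1.5 * fs))
        return _transition_profile(n, fs, 8.0, 0.35, move, effects,
                                   reverse=True), 0.0
    raise UsageError(f"unknown preceding activity {preceding!r}")


def simulate_fall(task_id: str, spec: SimulationSpec | None = None,
                  seed: int | np.random.SeedSequence = 0,
                  subject_id: str = "S01", trial_id: int = 1,
                  effects: SubjectEffects | None = None
                  ) -> tuple[IMURecording, FallLabel]:
    """One synthetic fall trial with its ground-truth onset/impact label."""
    spec = spec or SimulationSpec()
    if task_id not in FALL_TASKS:
        raise UsageError(f"unknown fall task {task_id!r}")
    info = FALL_TASKS[task_id]
    effects = effects or SubjectEffects()
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate_hz
    fp = spec.fall

    n_pre = int(round(3.0 * fs))
    pre, base_angle = _preceding_profile(info["preceding"], n_pre, fs, effects)

    dur_ms = max(rng.normal(fp.duration_mean_ms, fp.duration_sd_ms),
                 fp.duration_min_ms)
    n_fall = max(int(round(dur_ms / 1000.0 * fs)), 10)
    n_spike = 3
    n_post = int(round(2.0 * fs))

    fall = _Profile.zeros(n_fall + n_spike + n_post)
    t_fall = np.arange(n_fall) / n_fall
    peak = rng.uniform(*fp.accel_peak_ms2)
    fall.av[:n_fall] = peak * np.sin(np.pi * t_fall)
    impact_g = rng.uniform(*fp.impact_peak_g)
    fall.av[n_fall:n_fall + n_spike] = (1.0 - impact_g) * G

    excursion = info["sign"] * rng.uniform(*fp.angle_excursion_deg)
    ramp = np.concatenate([_smoothstep(n_fall),
                           np.ones(n_spike + n_post)]) * excursion
    if info["plane"] == "frontal":
        fall.roll += ramp
        fall.pitch += base_angle
    else:
        fall.pitch += ramp + base_angle

    # onset jerk transient on the category's sensitive axis
    if info["preceding"] == "sitting":
        axis = 0 if info["plane"] == "sagittal" else 2   # GyrX / GyrZ
        fall.gyro_extra[:3, axis] += info["sign"] * fp.onset_pulse_gyro_dps
    else:
        fall.acc_extra[:3, 1] -= fp.onset_pulse_acc_g     # AccY

    profile = pre.concat(fall)
    rec = _assemble(profile, spec, rng, subject_id, task_id, trial_id)
    label = FallLabel(task_id=task_id, description=info["description"],
                      trial_id=trial_id, onset_frame=n_pre + 1,
                      impact_frame=n_pre + n_fall + 1)
    return rec, label


def _subject_effects(spec: SimulationSpec, subject_index: int) -> SubjectEffects:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919, subject_index]))
    return SubjectEffects(
        gait_freq_factor=float(np.clip(rng.normal(1.0, 0.06), 0.8, 1.2)),
        gait_amp_factor=float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.4)),
        posture_offset_deg=float(rng.normal(0.0, 1.5)))


def generate_dataset(spec: SimulationSpec | None = None
                     ) -> list[tuple[IMURecording, FallLabel | None]]:
    """Full dataset over subjects × tasks × trials, fully determined by ``spec.seed``."""
    spec = spec or SimulationSpec()
    tasks = spec.tasks if spec.tasks is not None else ALL_TASKS
    unknown = [t for t in tasks if t not in ADL_TASKS and t not in FALL_TASKS]
    if unknown:
        raise UsageError(f"unknown tasks: {unknown}")
    out: list[tuple[IMURecording, FallLabel | None]] = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s + 1:02d}"
        effects = _subject_effects(spec, s)
        for ti, task in enumerate(tasks):
            is_fall = task in FALL_TASKS
            n_trials = (spec.trials_per_task if spec.trials_per_task is not None
                        else (FALL_TASKS[task].get("trials", 5) if is_fall
                              else ADL_TASKS[task]["trials"]))
            for trial in range(1, n_trials + 1):
                seed = np.random.SeedSequence([spec.seed, s, ti, trial])
                if is_fall:
                    rec, lab = simulate_fall(task, spec, seed, subject_id, trial,
                                             effects)
                    out.append((rec, lab))
                else:
                    out.append((simulate_adl(task, spec, seed, subject_id, trial,
                                             effects), None))
    return out


def write_dataset(dataset: list[tuple[IMURecording, FallLabel | None]],
                  outdir: str | Path, label_format: str = "csv") -> None:
    """Write recordings and per-subject label tables in the on-disk dialect."""
    outdir = Path(outdir)
    labels_by_subject: dict[str, list[FallLabel]] = {}
    for rec, lab in dataset:
        d = outdir / rec.subject_id
        d.mkdir(parents=True, exist_ok=True)
        write_recording(rec, d / f"{rec.subject_id}{rec.task_id}R{rec.trial_id:02d}.csv")
        if lab is not None:
            labels_by_subject.setdefault(rec.subject_id, []).append(lab)
    label_dir = outdir / "labels"
    label_dir.mkdir(parents=True, exist_ok=True)
    for subject, labels in labels_by_subject.items():
        write_labels(labels, label_dir / f"{subject}_label.{label_format}")


def fixture_spec(seed: int = 0) -> SimulationSpec:
    """A tiny 8-recording profile (2 subjects × {D01, D06, F09, F07} × 1 trial)."""
    return SimulationSpec(n_subjects=2, tasks=["D01", "D06", "F09", "F07"],
                          trials_per_task=1, seed=seed)
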