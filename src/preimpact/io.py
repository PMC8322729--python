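"""Reading and writing the 11-column low-back IMU motion dialect.

One trial is a CSV with columns ``TimeStamp`` (seconds), ``FrameCounter``
(1-based, strictly increasing), three acceleration axes in g, three angular
velocity axes in deg/s and three Euler angles in degrees, sampled at 100 Hz.
Fall trials carry a label row (task code, description, trial ID, fall-onset
frame, fall-impact frame) in a per-subject label table (CSV or xlsx).

Frame numbers in all public APIs are the on-disk frame-counter values
(1-based); conversion to 0-based array indices happens internally via
:meth:`IMURecording.index_of_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, RangeError

#: Canonical column order of the on-disk dialect.
COLUMNS = [
    "TimeStamp",
    "FrameCounter",
    "AccX",
    "AccY",
    "AccZ",
    "GyrX",
    "GyrY",
    "GyrZ",
    "EulerX",
    "EulerY",
    "EulerZ",
]

LABEL_COLUMNS = [
    "Task Code (Task ID)",
    "Description",
    "Trial ID",
    "Fall_onset_frame",
    "Fall_impact_frame",
]


@dataclass
class IMURecording:
    """One trial's 9-channel inertial time series plus metadata.

    ``acc_g``, ``gyro_dps`` and ``euler_deg`` are ``(n, 3)`` float arrays;
    ``frame`` holds the 1-based frame-counter values as stored on disk.
    """

    subject_id: str
    task_id: str
    trial_id: int
    time_s: np.ndarray
    frame: np.ndarray
    acc_g: np.ndarray
    gyro_dps: np.ndarray
    euler_deg: np.ndarray
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.frame = np.asarray(self.frame, dtype=int)
        self.acc_g = np.atleast_2d(np.asarray(self.acc_g, dtype=float))
        self.gyro_dps = np.atleast_2d(np.asarray(self.gyro_dps, dtype=float))
        self.euler_deg = np.atleast_2d(np.asarray(self.euler_deg, dtype=float))
        n = len(self.time_s)
        if n < 1:
            raise IntegrityError("recording must contain at least one sample")
        for name, arr in (("acc_g", self.acc_g), ("gyro_dps", self.gyro_dps),
                          ("euler_deg", self.euler_deg)):
            if arr.shape != (n, 3):
                raise IntegrityError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        if len(self.frame) != n:
            raise IntegrityError("frame counter length does not match channels")
        if n > 1 and not np.all(np.diff(self.frame) > 0):
            raise IntegrityError("frame counter must be strictly increasing")
        if n > 1 and not np.all(np.diff(self.time_s) >= 0):
            raise IntegrityError("timestamps must be non-decreasing")
        if self.sample_rate_hz <= 0:
            raise IntegrityError("sample_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    def index_of_frame(self, frame: int) -> int:
        """0-based array index of a 1-based frame-counter value."""
        i = int(np.searchsorted(self.frame, frame))
        if i >= self.n_frames or self.frame[i] != frame:
            raise RangeError(f"frame {frame} not present in recording "
                             f"({self.frame[0]}..{self.frame[-1]})")
        return i

    def slice_frames(self, start_frame: int | None = None,
                     end_frame: int | None = None) -> "IMURecording":
        """Sub-recording covering frame-counter values [start_frame, end_frame], inclusive."""
        i0 = 0 if start_frame is None else self.index_of_frame(start_frame)
        i1 = self.n_frames - 1 if end_frame is None else self.index_of_frame(end_frame)
        sl = slice(i0, i1 + 1)
        return replace(self, time_s=self.time_s[sl], frame=self.frame[sl],
                       acc_g=self.acc_g[sl], gyro_dps=self.gyro_dps[sl],
                       euler_deg=self.euler_deg[sl])

    def to_frame(self) -> pd.DataFrame:
        """The recording as a DataFrame in canonical column order."""
        data = np.column_stack([self.time_s, self.frame, self.acc_g,
                                self.gyro_dps, self.euler_deg])
        df = pd.DataFrame(data, columns=COLUMNS)
        df["FrameCounter"] = df["FrameCounter"].astype(int)
        return df


@dataclass
class FallLabel:
    """Temporal label of one fall trial: 1-based onset and impact frame counters."""

    task_id: str
    description: str
    trial_id: int
    onset_frame: int
    impact_frame: int

    def __post_init__(self) -> None:
        if self.onset_frame >= self.impact_frame:
            raise IntegrityError(
                f"onset frame {self.onset_frame} must precede impact frame "
                f"{self.impact_frame} ({self.task_id} trial {self.trial_id})")


@dataclass
class PhaseSegmentation:
    """The three phases of a fall trial, as inclusive frame-counter intervals.

    ``pre_fall`` covers [start, onset), ``falling`` covers [onset, impact],
    ``post_fall`` covers (impact, end].  An empty interval is ``None``.
    Downstream training and evaluation use only ``pre_fall`` and ``falling``;
    the post-impact phase is excluded by the pre-impact problem definition.
    """

    pre_fall: tuple[int, int] | None
    falling: tuple[int, int]
    post_fall: tuple[int, int] | None


def read_recording(path: str | Path, subject_id: str = "", task_id: str = "",
                   trial_id: int = 1, sample_rate_hz: float = 100.0) -> IMURecording:
    """Parse one 11-column trial CSV.

    Files with or without a header row are accepted; columns are mapped by
    position in the canonical order (timestamp, frame counter, acc ×3,
    gyro ×3, Euler ×3).
    """
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = any(isinstance(v, str) for v in first.iloc[0])
    try:
        df = pd.read_csv(path, header=0 if has_header else None)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] != len(COLUMNS):
        raise FormatError(f"{path}: expected {len(COLUMNS)} columns, found {df.shape[1]}")
    if df.shape[0] < 1:
        raise FormatError(f"{path}: no data rows")
    df.columns = COLUMNS
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise FormatError(f"{path}: malformed value on data line {int(bad[0]) + 1}")
    try:
        return IMURecording(
            subject_id=subject_id, task_id=task_id, trial_id=trial_id,
            sample_rate_hz=sample_rate_hz,
            time_s=df["TimeStamp"].to_numpy(float),
            frame=df["FrameCounter"].to_numpy(int),
            acc_g=df[["AccX", "AccY", "AccZ"]].to_numpy(float),
            gyro_dps=df[["GyrX", "GyrY", "GyrZ"]].to_numpy(float),
            euler_deg=df[["EulerX", "EulerY", "EulerZ"]].to_numpy(float),
        )
    except IntegrityError as exc:
        raise IntegrityError(f"{path}: {exc}") from exc


def write_recording(rec: IMURecording, path: str | Path, header: bool = True) -> None:
    """Emit the 11-column dialect readable by :func:`read_recording`."""
    rec.to_frame().to_csv(Path(path), index=False, header=header,
                          float_format="%.9g")


def read_labels(path: str | Path) -> list[FallLabel]:
    """Read a per-subject label table (CSV or xlsx; 5 or 6 columns).

    A sixth column, when present, is treated as auxiliary notes and ignored.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.shape[1] not in (5, 6):
        raise FormatError(f"{path}: expected 5 or 6 label columns, found {df.shape[1]}")
    labels = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            labels.append(FallLabel(task_id=str(row[0]), description=str(row[1]),
                                    trial_id=int(row[2]), onset_frame=int(row[3]),
                                    impact_frame=int(row[4])))
        except IntegrityError as exc:
            raise IntegrityError(f"{path} row {i + 1}: {exc}") from exc
    return labels


def write_labels(labels: Sequence[FallLabel], path: str | Path) -> None:
    """Write a label table; format chosen from the file extension (CSV or xlsx)."""
    df = pd.DataFrame(
        [(l.task_id, l.description, l.trial_id, l.onset_frame, l.impact_frame)
         for l in labels],
        columns=LABEL_COLUMNS)
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def segment_phases(rec: IMURecording, label: FallLabel) -> PhaseSegmentation:
    """Partition a labeled fall trial into pre-fall / falling / post-fall phases."""
    i_on = rec.index_of_frame(label.onset_frame)
    i_im = rec.index_of_frame(label.impact_frame)
    start, end = int(rec.frame[0]), int(rec.frame[-1])
    pre = (start, int(rec.frame[i_on - 1])) if i_on > 0 else None
    post = (int(rec.frame[i_im + 1]), end) if i_im < rec.n_frames - 1 else None
    return PhaseSegmentation(pre_fall=pre,
                             falling=(label.onset_frame, label.impact_frame),
                             post_fall=post)
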