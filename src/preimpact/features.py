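"""Sliding-window extraction of the 40 hand-crafted motion features.

From each 50-frame (0.5 s) window five scalar source signals are derived:
acceleration magnitude, angular-velocity magnitude, and the pitch, roll and
yaw angles.  The magnitude signals each contribute 11 features (mean,
variance, RMS, ZCR, ABSDIFF, the first five FFT coefficient magnitudes, and
spectral energy); each angle contributes 6 (mean, standard deviation, RMS,
ZCR, ABSDIFF, spectral energy) — 40 in total.

Definitions follow the source conventions of this detection protocol rather
than textbook usage: *ZCR* is the count of samples strictly above the window
mean (despite the conventional name), *ABSDIFF* is the mean absolute
deviation from the window mean, and *spectral energy* is the sum of squared
unnormalized DFT coefficient magnitudes divided by the window length.
Variance and standard deviation are population statistics (divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler

from .errors import UsageError
from .io import IMURecording
from .kinematics import DEFAULT_ANGLE_MAPPING, _EULER_INDEX

DEFAULT_WIDTH = 50
DEFAULT_STRIDE = 10

#: Channel order inside Window.samples.
WINDOW_CHANNELS = ["AccX", "AccY", "AccZ", "GyrX", "GyrY", "GyrZ",
                   "EulerX", "EulerY", "EulerZ"]

_MAG_STATS = ["mean", "var", "rms", "zcr", "absdiff",
              "fft1", "fft2", "fft3", "fft4", "fft5", "se"]
_ANGLE_STATS = ["mean", "sd", "rms", "zcr", "absdiff", "se"]

#: Frozen 40-name feature order; saved models depend on it.
FEATURE_NAMES = ([f"acc_m_{s}" for s in _MAG_STATS]
                 + [f"gyro_m_{s}" for s in _MAG_STATS]
                 + [f"pitch_{s}" for s in _ANGLE_STATS]
                 + [f"roll_{s}" for s in _ANGLE_STATS]
                 + [f"yaw_{s}" for s in _ANGLE_STATS])


@dataclass
class Window:
    """A 9-channel segment of ``width`` frames starting at ``start_frame`` (1-based)."""

    samples: np.ndarray  # (width, 9) in WINDOW_CHANNELS order
    start_frame: int
    width: int = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (self.width, len(WINDOW_CHANNELS)):
            raise UsageError(f"window samples must have shape ({self.width}, 9), "
                             f"got {self.samples.shape}")

    @property
    def end_frame(self) -> int:
        """1-based frame counter of the last sample in the window."""
        return self.start_frame + self.width - 1


@dataclass
class FeatureVector:
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise UsageError("feature values/names length mismatch")


def sliding_windows(rec: IMURecording, width: int = DEFAULT_WIDTH,
                    stride: int = DEFAULT_STRIDE) -> list[Window]:
    """Windows at offsets 0, stride, 2·stride, …; a final partial window is dropped."""
    if width < 1 or stride < 1:
        raise UsageError("width and stride must be positive")
    data = np.column_stack([rec.acc_g, rec.gyro_dps, rec.euler_deg])
    out = []
    for start in range(0, rec.n_frames - width + 1, stride):
        out.append(Window(samples=data[start:start + width],
                          start_frame=int(rec.frame[start]), width=width))
    return out


def zcr(values: np.ndarray) -> int:
    """Count of samples strictly greater than the window mean."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UsageError("zcr requires a non-empty window")
    return int(np.sum(x > x.mean()))


def absdiff(values: np.ndarray) -> float:
    """Mean absolute deviation of the samples from the window mean."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UsageError("absdiff requires a non-empty window")
    return float(np.abs(x - x.mean()).mean())


def fft5(values: np.ndarray) -> np.ndarray:
    """Magnitudes of the first five unnormalized DFT coefficients (DC included)."""
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise UsageError("fft5 requires at least 5 samples")
    return np.abs(np.fft.fft(x)[:5])


def spectral_energy(values: np.ndarray) -> float:
    """Sum of squared DFT coefficient magnitudes divided by the window length."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UsageError("spectral_energy requires a non-empty window")
    return float(np.sum(np.abs(np.fft.fft(x)) ** 2) / x.size)


def _mag_features(x: np.ndarray) -> list[float]:
    return ([float(x.mean()), float(x.var()), float(np.sqrt(np.mean(x ** 2))),
             float(zcr(x)), absdiff(x)]
            + list(fft5(x)) + [spectral_energy(x)])


def _angle_features(x: np.ndarray) -> list[float]:
    return [float(x.mean()), float(x.std()), float(np.sqrt(np.mean(x ** 2))),
            float(zcr(x)), absdiff(x), spectral_energy(x)]


def extract_features(window: Window,
                     angle_mapping: dict[str, str] | None = None) -> FeatureVector:
    """The 40-dimensional descriptor of one window, in :data:`FEATURE_NAMES` order."""
    m = angle_mapping or DEFAULT_ANGLE_MAPPING
    acc = window.samples[:, 0:3]
    gyro = window.samples[:, 3:6]
    euler = window.samples[:, 6:9]
    acc_m = np.linalg.norm(acc, axis=1)
    gyro_m = np.linalg.norm(gyro, axis=1)
    values = _mag_features(acc_m) + _mag_features(gyro_m)
    for role in ("pitch", "roll", "yaw"):
        values += _angle_features(euler[:, _EULER_INDEX[m[role]]])
    return FeatureVector(values=np.array(values), names=list(FEATURE_NAMES))


def feature_matrix(windows: list[Window],
                   angle_mapping: dict[str, str] | None = None) -> np.ndarray:
    """(n_windows, 40) stacked feature matrix."""
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.stack([extract_features(w, angle_mapping).values for w in windows])


class Normalizer:
    """Per-feature z-scoring from training statistics.

    Zero-variance features are centered but not scaled.  ``transform`` before
    ``fit`` is a usage error.
    """

    def __init__(self) -> None:
        self._scaler: StandardScaler | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise UsageError("fit requires at least 2 training vectors")
        self._scaler = StandardScaler().fit(X)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._scaler is None:
            raise UsageError("Normalizer.transform called before fit")
        return self._scaler.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_normalizer(train_vectors: np.ndarray) -> Normalizer:
    return Normalizer().fit(train_vectors)


def apply_normalizer(normalizer: Normalizer, vectors: np.ndarray) -> np.ndarray:
    return normalizer.transform(vectors)
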