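"""Window classifiers: feature-based SVM and the raw-signal Conv+LSTM.

Both consume 50-frame windows.  The SVM takes the normalized 40-feature
descriptor (:mod:`preimpact.features`); the Conv+LSTM takes the raw
9-channel window directly (:mod:`preimpact.convlstm`).

Window labeling rule: a window is labeled *fall* iff its last frame lies in
the falling phase [onset, impact]; windows ending before onset are *adl*;
windows extending past the impact frame are discarded from training, since a
pre-impact detector must never learn from post-impact signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .convlstm import ConvLSTMNet, ConvLSTMSpec, build_convlstm, train_convlstm  # noqa: F401
from .errors import UsageError
from .features import (FEATURE_NAMES, Normalizer, Window, feature_matrix,
                       sliding_windows)
from .io import FallLabel, IMURecording

FALL, ADL = 1, 0


def label_windows(windows: list[Window], label: FallLabel | None) -> tuple[list[Window], np.ndarray]:
    """Apply the window labeling rule; returns (kept windows, labels 1=fall/0=adl)."""
    if label is None:
        return list(windows), np.zeros(len(windows), dtype=int)
    kept, ys = [], []
    for w in windows:
        if w.end_frame > label.impact_frame:
            continue  # post-impact content: excluded from training
        kept.append(w)
        ys.append(FALL if w.end_frame >= label.onset_frame else ADL)
    return kept, np.array(ys, dtype=int)


def windows_and_labels(dataset: list[tuple[IMURecording, FallLabel | None]],
                       width: int = 50, stride: int = 10
                       ) -> tuple[list[Window], np.ndarray]:
    """Pooled labeled windows from a mixed fall/ADL dataset."""
    all_w: list[Window] = []
    all_y: list[np.ndarray] = []
    for rec, lab in dataset:
        w, y = label_windows(sliding_windows(rec, width, stride), lab)
        all_w += w
        all_y.append(y)
    return all_w, (np.concatenate(all_y) if all_y else np.zeros(0, dtype=int))


@dataclass
class SVMModel:
    """A trained margin classifier plus the feature order it expects."""

    estimator: SVC
    feature_names: list[str]


def train_svm(features: np.ndarray, labels: np.ndarray, C: float = 1.0,
              kernel: str = "rbf", gamma: str | float = "scale",
              class_weight: str | dict | None = "balanced",
              seed: int = 0) -> SVMModel:
    """Fit the window-level SVM on normalized feature vectors."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or X.shape[0] == 0:
        raise UsageError("feature matrix must be non-empty and 2-D")
    if len(np.unique(y)) < 2:
        raise UsageError("training requires both fall and ADL windows")
    est = SVC(C=C, kernel=kernel, gamma=gamma, class_weight=class_weight,
              random_state=seed)
    est.fit(X, y)
    names = (list(FEATURE_NAMES) if X.shape[1] == len(FEATURE_NAMES)
             else [f"f{i}" for i in range(X.shape[1])])
    return SVMModel(estimator=est, feature_names=names)


def predict_windows(model: SVMModel | ConvLSTMNet, windows: np.ndarray) -> np.ndarray:
    """Order-preserving per-window predictions (1 = fall, 0 = adl).

    For :class:`SVMModel`, ``windows`` is a (n, 40) normalized feature matrix;
    for the Conv+LSTM it is (n, width, channels) raw windows.
    """
    X = np.asarray(windows, dtype=float)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int)
    if isinstance(model, SVMModel):
        if X.ndim != 2 or X.shape[1] != len(model.feature_names):
            raise UsageError(f"SVM expects (n, {len(model.feature_names)}) features, "
                             f"got {X.shape}")
        return model.estimator.predict(X).astype(int)
    if isinstance(model, ConvLSTMNet):
        probs = model.forward(X, train=False)  # shape-checks internally
        return probs.argmax(axis=1).astype(int)
    raise UsageError(f"unsupported model type {type(model).__name__}")


def window_detector(model: SVMModel | ConvLSTMNet,
                    normalizer: Normalizer | None = None,
                    width: int = 50, stride: int = 10):
    """Adapter for :func:`preimpact.evaluation.evaluate`.

    Returns a callable mapping a recording to the (sorted) end frames of
    windows the model classifies as falls.  Detection time is the window's
    end frame, matching a causal streaming detector.
    """

    def _detector(rec: IMURecording) -> list[int]:
        ws = sliding_windows(rec, width, stride)
        if not ws:
            return []
        if isinstance(model, SVMModel):
            X = feature_matrix(ws)
            if normalizer is not None:
                X = normalizer.transform(X)
        else:
            X = np.stack([w.samples for w in ws])
        pred = predict_windows(model, X)
        return [ws[i].end_frame for i in np.flatnonzero(pred == FALL)]

    return _detector


def save_model(path: str | Path, model: SVMModel | ConvLSTMNet,
               normalizer: Normalizer | None = None) -> None:
    """Persist a trained model (plus normalizer and feature order) to one archive."""
    payload = {"kind": "svm" if isinstance(model, SVMModel) else "convlstm",
               "model": model, "normalizer": normalizer,
               "feature_names": list(FEATURE_NAMES)}
    joblib.dump(payload, Path(path))


def load_model(path: str | Path) -> tuple[SVMModel | ConvLSTMNet, Normalizer | None]:
    payload = joblib.load(Path(path))
    return payload["model"], payload.get("normalizer")
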