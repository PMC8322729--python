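"""Shared fixtures: small synthetic recordings and one session-scoped study.

The "study" is a seeded synthetic dataset (8 subjects, a mixed task subset,
2 trials per task) with a subject-wise train/test split, reused by the
classifier and evaluation tests so the simulator runs once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import preimpact as pi

STUDY_TASKS = ["D01", "D04", "D06", "D08", "D10", "D13", "D18",
               "F01", "F03", "F07", "F09", "F13", "F15"]


def make_recording(acc=None, gyro=None, euler=None, n=None, fs=100.0, **meta):
    """A minimal valid recording from explicit channel arrays (defaults: zeros)."""
    for arr in (acc, gyro, euler):
        if arr is not None:
            n = len(arr)
            break
    if n is None:
        n = 10
    zeros = np.zeros((n, 3))
    return pi.IMURecording(
        subject_id=meta.get("subject_id", "S01"),
        task_id=meta.get("task_id", "D01"),
        trial_id=meta.get("trial_id", 1),
        sample_rate_hz=fs,
        time_s=np.arange(n) / fs,
        frame=np.arange(1, n + 1),
        acc_g=zeros if acc is None else np.asarray(acc, float),
        gyro_dps=zeros if gyro is None else np.asarray(gyro, float),
        euler_deg=zeros if euler is None else np.asarray(euler, float),
    )


@pytest.fixture()
def standing_recording():
    """Stationary upright sensor: acc = (0, -1, 0) g everywhere."""
    n = 200
    acc = np.tile([0.0, -1.0, 0.0], (n, 1))
    return make_recording(acc=acc)


@pytest.fixture()
def fall_trial():
    """One seeded forward fall while walking, with its ground-truth label."""
    return pi.simulate_fall("F09", seed=42)


@pytest.fixture(scope="session")
def study_dataset():
    spec = pi.SimulationSpec(n_subjects=8, tasks=STUDY_TASKS,
                             trials_per_task=2, seed=11)
    return pi.generate_dataset(spec)


@pytest.fixture(scope="session")
def study_split(study_dataset):
    subjects = sorted({rec.subject_id for rec, _ in study_dataset})
    train_ids, test_ids = pi.subject_split(subjects, test_fraction=0.25, seed=3)
    train = [(r, l) for r, l in study_dataset if r.subject_id in train_ids]
    test = [(r, l) for r, l in study_dataset if r.subject_id in test_ids]
    return train, test


@pytest.fixture(scope="session")
def study_windows(study_split):
    train, test = study_split
    w_tr, y_tr = pi.windows_and_labels(train)
    w_te, y_te = pi.windows_and_labels(test)
    return (w_tr, y_tr), (w_te, y_te)


@pytest.fixture(scope="session")
def study_features(study_windows):
    (w_tr, y_tr), (w_te, y_te) = study_windows
    X_tr = pi.feature_matrix(w_tr)
    X_te = pi.feature_matrix(w_te)
    norm = pi.fit_normalizer(X_tr)
    return (norm.transform(X_tr), y_tr), (norm.transform(X_te), y_te)


def subsample_balanced(y: np.ndarray, n_max: int, seed: int = 0) -> np.ndarray:
    """Indices of at most n_max windows keeping every fall window."""
    if len(y) <= n_max:
        return np.arange(len(y))
    rng = np.random.default_rng(seed)
    fall_idx = np.flatnonzero(y == 1)
    adl_idx = np.flatnonzero(y == 0)
    n_adl = max(n_max - len(fall_idx), len(fall_idx))
    keep = np.concatenate([fall_idx, rng.choice(adl_idx, size=min(n_adl, len(adl_idx)),
                                                replace=False)])
    return np.sort(keep)
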