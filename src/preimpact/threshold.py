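"""Threshold-based pre-impact fall detector and its grid-search calibration.

Four scalar criteria are monitored per frame: acceleration magnitude dipping
below a free-fall threshold, integrated vertical velocity exceeding a descent
threshold, and pitch/roll excursions beyond a posture threshold.  The default
combination fires at the first frame where

    ACC_M(t) <= acc_m_g  AND  VV(t) >= vv_ms
    AND  (|pitch(t)| >= pitch_deg  OR  |roll(t)| >= roll_deg)

with the published operating point 0.8 g / 25° / 25° / 0.3 m/s.  The boolean
combination is configurable as an expression over the named criteria
(``accm``, ``vv``, ``pitch``, ``roll`` with ``&``, ``|``, ``~`` and
parentheses) so alternative gating structures can be expressed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError
from .io import FallLabel, IMURecording
from .kinematics import ResetPolicy, magnitude, posture_angles, vertical_velocity

DEFAULT_COMBINATION = "accm & vv & (pitch | roll)"


@dataclass
class ThresholdConfig:
    """Detector operating point (published defaults) and criterion combination."""

    acc_m_g: float = 0.8
    pitch_deg: float = 25.0
    roll_deg: float = 25.0
    vv_ms: float = 0.3
    combination: str = DEFAULT_COMBINATION

    def __post_init__(self) -> None:
        for name in ("acc_m_g", "pitch_deg", "roll_deg", "vv_ms"):
            if getattr(self, name) <= 0:
                raise UsageError(f"threshold {name} must be positive")


@dataclass
class DetectionResult:
    """Per-trial decision; ``detection_frame`` is the 1-based frame counter."""

    is_fall: bool
    detection_frame: int | None
    triggered_criteria: frozenset[str] = frozenset()


@dataclass
class DetectorSignals:
    """Precomputed scalar signals for one recording (reused by the grid search)."""

    frame: np.ndarray
    acc_m: np.ndarray
    vv: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray


def compute_signals(rec: IMURecording,
                    reset_policy: ResetPolicy | None = None,
                    angle_mapping: dict[str, str] | None = None) -> DetectorSignals:
    pitch, roll = posture_angles(rec, angle_mapping)
    return DetectorSignals(
        frame=rec.frame,
        acc_m=magnitude(rec, "acc").values,
        vv=vertical_velocity(rec, reset_policy).values,
        pitch=pitch.values,
        roll=roll.values,
    )


def _criterion_arrays(sig: DetectorSignals, cfg: ThresholdConfig) -> dict[str, np.ndarray]:
    return {
        "accm": sig.acc_m <= cfg.acc_m_g,
        "vv": sig.vv >= cfg.vv_ms,
        "pitch": np.abs(sig.pitch) >= cfg.pitch_deg,
        "roll": np.abs(sig.roll) >= cfg.roll_deg,
    }


def _combine(crit: dict[str, np.ndarray], expression: str) -> np.ndarray:
    allowed = set("()&|~ ")
    stripped = expression
    for name in crit:
        stripped = stripped.replace(name, "")
    if not set(stripped) <= allowed:
        raise UsageError(f"invalid combination expression {expression!r}")
    try:
        return eval(expression, {"__builtins__": {}}, crit)  # noqa: S307 - token-validated
    except Exception as exc:
        raise UsageError(f"cannot evaluate combination {expression!r}: {exc}") from exc


def detect_from_signals(sig: DetectorSignals, cfg: ThresholdConfig) -> DetectionResult:
    crit = _criterion_arrays(sig, cfg)
    fire = _combine(crit, cfg.combination)
    idx = np.flatnonzero(fire)
    if len(idx) == 0:
        return DetectionResult(is_fall=False, detection_frame=None)
    i = int(idx[0])
    triggered = frozenset(name for name, arr in crit.items() if arr[i])
    return DetectionResult(is_fall=True, detection_frame=int(sig.frame[i]),
                           triggered_criteria=triggered)


def detect(rec: IMURecording, cfg: ThresholdConfig | None = None,
           reset_policy: ResetPolicy | None = None) -> DetectionResult:
    """Scan a recording in time order; fire at the first frame satisfying the combination."""
    return detect_from_signals(compute_signals(rec, reset_policy), cfg or ThresholdConfig())


def as_detector(cfg: ThresholdConfig | None = None,
                reset_policy: ResetPolicy | None = None):
    """Adapter for :func:`preimpact.evaluation.evaluate`: recording -> positive frames."""
    cfg = cfg or ThresholdConfig()

    def _detector(rec: IMURecording) -> list[int]:
        res = detect(rec, cfg, reset_policy)
        return [res.detection_frame] if res.is_fall else []

    return _detector


def grid_search_thresholds(dataset: list[tuple[IMURecording, FallLabel | None]],
                           grids: dict[str, list[float]],
                           objective: str = "youden",
                           combination: str = DEFAULT_COMBINATION,
                           reset_policy: ResetPolicy | None = None
                           ) -> tuple[ThresholdConfig, float]:
    """Exhaustive calibration of the four thresholds on a labeled dataset.

    ``grids`` maps any of ``acc_m_g``/``pitch_deg``/``roll_deg``/``vv_ms`` to
    candidate values (missing axes stay at the default).  Each grid point is
    scored file-wise with the pre-impact rule: a fall file counts as detected
    only if the detector fires at or before the labeled impact frame.
    Objectives: ``youden`` (sensitivity + specificity - 1, both as fractions)
    or ``accuracy``.  Ties are broken toward the larger mean lead time, then
    by the lexicographic order of the grid.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise UsageError("grids must contain at least one candidate per axis")
    unknown = set(grids) - {"acc_m_g", "pitch_deg", "roll_deg", "vv_ms"}
    if unknown:
        raise UsageError(f"unknown grid axes: {sorted(unknown)}")
    if objective not in ("youden", "accuracy"):
        raise UsageError(f"unknown objective {objective!r}")
    n_fall = sum(1 for _, lab in dataset if lab is not None)
    n_adl = len(dataset) - n_fall
    if n_fall == 0 or n_adl == 0:
        raise UsageError("grid search requires both fall and ADL recordings")

    signals = [(compute_signals(rec, reset_policy), lab) for rec, lab in dataset]
    axes = ["acc_m_g", "pitch_deg", "roll_deg", "vv_ms"]
    defaults = ThresholdConfig()
    grid_lists = [grids.get(a, [getattr(defaults, a)]) for a in axes]

    best: tuple[float, float, ThresholdConfig] | None = None
    for values in itertools.product(*grid_lists):
        cfg = ThresholdConfig(**dict(zip(axes, values)), combination=combination)
        tp = fn = tn = fp = 0
        leads = []
        for sig, lab in signals:
            res = detect_from_signals(sig, cfg)
            if lab is None:
                if res.is_fall:
                    fp += 1
                else:
                    tn += 1
            else:
                if res.is_fall and res.detection_frame <= lab.impact_frame:
                    tp += 1
                    leads.append(lab.impact_frame - res.detection_frame)
                else:
                    fn += 1
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        score = sens + spec - 1.0 if objective == "youden" else (tp + tn) / len(signals)
        mean_lead = float(np.mean(leads)) if leads else 0.0
        if best is None or (score, mean_lead) > (best[0], best[1]):
            best = (score, mean_lead, cfg)
    assert best is not None
    return best[2], best[0]
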