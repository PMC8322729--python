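"""File-level scoring protocol: confusion counts, metrics, lead times, splits.

A *file* (one trial) is the unit of evaluation.  A fall file counts as
detected (TP) only when the detector fires at or before the labeled impact
frame — the defining property of pre-impact detection; a detection after
impact is a miss.  Any positive on an ADL file is a false positive.  The
lead time of a TP is the interval from the detection frame to the impact
frame.  Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), reported as
percentages; rounding to two decimals happens only at presentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import PreimpactError, UsageError
from .io import FallLabel, IMURecording

Detector = Callable[[IMURecording], Sequence[int]]


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise UsageError("confusion counts must be non-negative")


@dataclass
class EvaluationReport:
    counts: ConfusionCounts
    sensitivity_pct: float
    specificity_pct: float
    lead_times_ms: list[float]
    lead_time_mean_ms: float
    lead_time_sd_ms: float

    def to_dict(self) -> dict:
        c = self.counts
        return {"schema_version": 1,
                "counts": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp},
                "sensitivity_pct": round(self.sensitivity_pct, 2),
                "specificity_pct": round(self.specificity_pct, 2),
                "lead_time_mean_ms": round(self.lead_time_mean_ms, 1),
                "lead_time_sd_ms": round(self.lead_time_sd_ms, 1),
                "n_lead_times": len(self.lead_times_ms)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_table(self, algorithm: str = "detector") -> str:
        """Human-readable row mirroring the benchmark table layout."""
        c = self.counts
        header = (f"{'Algorithm':<12}{'FN':>10}{'FP':>10}{'Sensitivity (%)':>18}"
                  f"{'Specificity (%)':>18}{'Lead time (ms)':>18}")
        lead = f"{self.lead_time_mean_ms:.0f} ± {self.lead_time_sd_ms:.0f}"
        row = (f"{algorithm:<12}{f'{c.fn}/{c.tp + c.fn}':>10}"
               f"{f'{c.fp}/{c.tn + c.fp}':>10}{self.sensitivity_pct:>18.2f}"
               f"{self.specificity_pct:>18.2f}{lead:>18}")
        return header + "\n" + row


class UndefinedMetricError(PreimpactError):
    """Sensitivity/specificity requested with an empty class."""


def confusion_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity_pct, specificity_pct) at full precision."""
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no fall files")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no ADL files")
    return (100.0 * counts.tp / (counts.tp + counts.fn),
            100.0 * counts.tn / (counts.tn + counts.fp))


def lead_time(detection_frame: int, impact_frame: int,
              sample_rate_hz: float = 100.0) -> float:
    """Milliseconds from detection to impact; detection must not follow impact."""
    if detection_frame > impact_frame:
        raise UsageError("detection after impact has no lead time; filter such "
                         "detections before calling lead_time")
    return (impact_frame - detection_frame) / sample_rate_hz * 1000.0


def classify_file(decision_frames: Sequence[int], label: FallLabel | None
                  ) -> tuple[bool, int | None]:
    """Aggregate time-ordered positive frames into one file-level decision.

    Returns ``(predicted_fall, detection_frame)``.  For a fall file only
    positives at or before the impact frame count; for an ADL file any
    positive makes the file a false positive.
    """
    frames = sorted(int(f) for f in decision_frames)
    if label is None:
        return (True, frames[0]) if frames else (False, None)
    pre_impact = [f for f in frames if f <= label.impact_frame]
    if pre_impact:
        return True, pre_impact[0]
    return False, None


def subject_split(subject_ids: Sequence[str], test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive subject-level split, deterministic under ``seed``."""
    if not 0.0 < test_fraction < 1.0:
        raise UsageError("test_fraction must lie in (0, 1)")
    ids = sorted(set(subject_ids))
    if len(ids) < 2:
        raise UsageError("subject split requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(len(ids) * test_fraction))
    n_test = min(max(n_test, 1), len(ids) - 1)
    return sorted(order[n_test:]), sorted(order[:n_test])


def evaluate(dataset: list[tuple[IMURecording, FallLabel | None]],
             detector: Detector) -> EvaluationReport:
    """Run a detector file-by-file and aggregate the pre-impact metrics.

    ``detector`` maps a recording to the frames at which it raises a fall
    alarm (e.g. :func:`preimpact.threshold.as_detector` or
    :func:`preimpact.classifiers.window_detector`).  Fall files are truncated
    at the impact frame before detection — the post-fall phase is excluded
    from the pre-impact problem.
    """
    n_fall = sum(1 for _, lab in dataset if lab is not None)
    if n_fall == 0 or n_fall == len(dataset):
        raise UsageError("evaluation requires both fall and ADL files")
    tp = fn = tn = fp = 0
    leads: list[float] = []
    for rec, lab in dataset:
        rec_eval = rec if lab is None else rec.slice_frames(end_frame=lab.impact_frame)
        pred_fall, det_frame = classify_file(detector(rec_eval), lab)
        if lab is None:
            fp += pred_fall
            tn += not pred_fall
        elif pred_fall:
            tp += 1
            leads.append(lead_time(det_frame, lab.impact_frame, rec.sample_rate_hz))
        else:
            fn += 1
    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    sens, spec = confusion_metrics(counts)
    mean = float(np.mean(leads)) if leads else 0.0
    sd = float(np.std(leads, ddof=1)) if len(leads) > 1 else 0.0
    return EvaluationReport(counts=counts, sensitivity_pct=sens,
                            specificity_pct=spec, lead_times_ms=leads,
                            lead_time_mean_ms=mean, lead_time_sd_ms=sd)
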