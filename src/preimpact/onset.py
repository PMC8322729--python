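"""Semiautomatic fall-onset labeling: sensitive-axis selection + ranked peaks.

Labeling the onset of a fall is harder than labeling the impact (which shows
an unmistakable acceleration spike).  The assistant implemented here selects
a *sensitive axis* from the fall category — falls preceded by dynamic
movement show the clearest onset transient on the y acceleration axis, while
low-dynamics falls (fainting from sitting) show it on the angular-velocity
axis of the fall plane (x for sagittal forward/backward falls, z for frontal
lateral falls) — then ranks local peaks of the absolute sensitive-axis
signal in a window preceding the labeled impact as onset candidates.  The
final choice among candidates remains with a human evaluator; batch mode
auto-accepts the top-ranked candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import UsageError
from .io import IMURecording

#: Default search window before impact: generous margin over the ~746 ms
#: mean duration of a fall.
DEFAULT_SEARCH_WINDOW_S = 1.5
DEFAULT_MIN_PROMINENCE = 0.1
DEFAULT_MAX_CANDIDATES = 5

_AXIS_INDEX = {"AccX": ("acc_g", 0), "AccY": ("acc_g", 1), "AccZ": ("acc_g", 2),
               "GyrX": ("gyro_dps", 0), "GyrY": ("gyro_dps", 1),
               "GyrZ": ("gyro_dps", 2)}


@dataclass
class OnsetCandidate:
    frame: int
    axis: str
    prominence: float
    rank: int


def select_sensitive_axis(rec: IMURecording, task_id: str,
                          preceding_activity: str,
                          fall_plane: str) -> str:
    """Channel showing the clearest onset transient for this fall category.

    ``preceding_activity``: ``dynamic`` (walking, jogging, sitting down,
    getting up) or ``sitting_faint``; ``fall_plane``: ``sagittal``
    (forward/backward) or ``frontal`` (lateral).
    """
    if preceding_activity == "dynamic":
        return "AccY"
    if preceding_activity == "sitting_faint":
        if fall_plane == "sagittal":
            return "GyrX"
        if fall_plane == "frontal":
            return "GyrZ"
        raise UsageError(f"unknown fall plane {fall_plane!r}")
    raise UsageError(f"unknown preceding activity {preceding_activity!r}")


def onset_candidates(rec: IMURecording, axis: str, impact_frame: int,
                     search_window_s: float = DEFAULT_SEARCH_WINDOW_S,
                     min_prominence: float = DEFAULT_MIN_PROMINENCE,
                     max_candidates: int = DEFAULT_MAX_CANDIDATES
                     ) -> list[OnsetCandidate]:
    """Ranked local peaks of ``|axis signal|`` in [impact - window, impact).

    Candidates are ordered by prominence (descending), ties broken toward the
    earlier frame; at most ``max_candidates`` are returned.  All candidate
    frames strictly precede the impact frame.
    """
    if axis not in _AXIS_INDEX:
        raise UsageError(f"unknown axis {axis!r}")
    i_impact = rec.index_of_frame(impact_frame)
    i_lo = max(0, i_impact - int(round(search_window_s * rec.sample_rate_hz)))
    if i_impact <= i_lo:
        raise UsageError("empty onset search window before impact")
    attr, col = _AXIS_INDEX[axis]
    signal = np.abs(getattr(rec, attr)[i_lo:i_impact, col])
    peaks, props = find_peaks(signal, prominence=min_prominence)
    if len(peaks) == 0:
        return []
    # prominence descending, earlier frame first on ties
    order = sorted(range(len(peaks)),
                   key=lambda i: (-props["prominences"][i], peaks[i]))
    out = []
    for rank, i in enumerate(order[:max_candidates], start=1):
        out.append(OnsetCandidate(frame=int(rec.frame[i_lo + peaks[i]]), axis=axis,
                                  prominence=float(props["prominences"][i]),
                                  rank=rank))
    return out
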