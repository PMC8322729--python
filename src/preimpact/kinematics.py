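"""Scalar signals driving the threshold detector.

From a 9-channel recording this module derives: the L2 magnitude of the
acceleration or angular-velocity vector, the posture (pitch/roll) angles,
the gravity-compensated world-frame vertical acceleration, and its time
integral, the vertical velocity.

Conventions
-----------
* World frame: y points up.  An upright, stationary sensor reads
  ``acc_g = (0, -1, 0)`` — the accelerometer channel stores the gravity
  direction in the body frame (g units), minus motion acceleration.
* Euler composition: intrinsic Z-Y-X; the rotation body→world is
  ``Rz(ez) @ Ry(ey) @ Rx(ex)``.  Only the vertical component matters to the
  detector, which is insensitive to the yaw term.
* Angle naming: the angle around the sensor X axis is *pitch* and the angle
  around Z is *roll* (configurable via ``angle_mapping``).
* Sign: downward motion gives *positive* vertical velocity, so the detector
  threshold "vertical velocity >= 0.3 m/s" reads naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UsageError
from .io import IMURecording

#: Standard gravity used for unit conversion (m/s² per g).
G = 9.81

#: Which stored Euler channel plays which postural role.
DEFAULT_ANGLE_MAPPING = {"pitch": "EulerX", "roll": "EulerZ", "yaw": "EulerY"}

_EULER_INDEX = {"EulerX": 0, "EulerY": 1, "EulerZ": 2}


@dataclass
class ScalarSeries:
    """A per-frame scalar signal with its unit and sampling rate."""

    values: np.ndarray
    unit: str
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ResetPolicy:
    """Drift control for the velocity integral.

    When the absolute vertical acceleration stays below ``still_accel_ms2``
    for at least ``still_frames`` consecutive frames the sensor is deemed
    still and the integrated velocity is clamped to zero.  Disable with
    ``enabled=False`` to obtain the raw integral.
    """

    enabled: bool = True
    still_accel_ms2: float = 0.2
    still_frames: int = 25


def magnitude(rec: IMURecording, channel: str) -> ScalarSeries:
    """Per-frame Euclidean norm of the acceleration or gyro 3-vector."""
    if channel == "acc":
        return ScalarSeries(np.linalg.norm(rec.acc_g, axis=1), "g", rec.sample_rate_hz)
    if channel == "gyro":
        return ScalarSeries(np.linalg.norm(rec.gyro_dps, axis=1), "deg/s",
                            rec.sample_rate_hz)
    raise UsageError(f"unknown channel {channel!r}; expected 'acc' or 'gyro'")


def posture_angles(rec: IMURecording,
                   angle_mapping: dict[str, str] | None = None
                   ) -> tuple[ScalarSeries, ScalarSeries]:
    """(pitch, roll) series in degrees under the configured channel mapping."""
    m = angle_mapping or DEFAULT_ANGLE_MAPPING
    pitch = rec.euler_deg[:, _EULER_INDEX[m["pitch"]]]
    roll = rec.euler_deg[:, _EULER_INDEX[m["roll"]]]
    return (ScalarSeries(pitch, "deg", rec.sample_rate_hz),
            ScalarSeries(roll, "deg", rec.sample_rate_hz))


def rotation_matrices(euler_deg: np.ndarray) -> np.ndarray:
    """(n, 3, 3) body→world rotation matrices, intrinsic Z-Y-X composition."""
    e = np.radians(np.atleast_2d(euler_deg))
    cx, sx = np.cos(e[:, 0]), np.sin(e[:, 0])
    cy, sy = np.cos(e[:, 1]), np.sin(e[:, 1])
    cz, sz = np.cos(e[:, 2]), np.sin(e[:, 2])
    n = len(e)
    Rx = np.zeros((n, 3, 3))
    Rx[:, 0, 0] = 1
    Rx[:, 1, 1], Rx[:, 1, 2] = cx, -sx
    Rx[:, 2, 1], Rx[:, 2, 2] = sx, cx
    Ry = np.zeros((n, 3, 3))
    Ry[:, 1, 1] = 1
    Ry[:, 0, 0], Ry[:, 0, 2] = cy, sy
    Ry[:, 2, 0], Ry[:, 2, 2] = -sy, cy
    Rz = np.zeros((n, 3, 3))
    Rz[:, 2, 2] = 1
    Rz[:, 0, 0], Rz[:, 0, 1] = cz, -sz
    Rz[:, 1, 0], Rz[:, 1, 1] = sz, cz
    return Rz @ Ry @ Rx


def vertical_acceleration(rec: IMURecording) -> ScalarSeries:
    """Gravity-compensated world-frame vertical acceleration, m/s², downward positive.

    The per-frame Euler angles rotate the measured body-frame acceleration
    into the world frame; the downward component of that measurement is 1 g
    at rest (pure gravity) and 0 g in ideal free fall, so the body's downward
    acceleration is ``(1 - measured_down_g) * 9.81``.
    """
    R = rotation_matrices(rec.euler_deg)
    world = np.einsum("nij,nj->ni", R, rec.acc_g)
    measured_down_g = -world[:, 1]
    return ScalarSeries((1.0 - measured_down_g) * G, "m/s2", rec.sample_rate_hz)


def vertical_velocity(rec: IMURecording,
                      reset_policy: ResetPolicy | None = None) -> ScalarSeries:
    """Vertical velocity (m/s, downward positive) by cumulative trapezoidal integration.

    Integration drift over long quiet stretches is controlled by the
    stillness-triggered :class:`ResetPolicy`; pass ``ResetPolicy(enabled=False)``
    for the exact discrete integral.  The computation is causal: the value at
    frame t depends only on frames <= t.
    """
    policy = reset_policy if reset_policy is not None else ResetPolicy()
    av = vertical_acceleration(rec).values
    dt = 1.0 / rec.sample_rate_hz
    n = len(av)
    v = np.empty(n)
    v[0] = 0.0
    if not policy.enabled:
        if n > 1:
            v[1:] = np.cumsum((av[1:] + av[:-1]) * 0.5 * dt)
        return ScalarSeries(v, "m/s", rec.sample_rate_hz)
    still = np.abs(av) < policy.still_accel_ms2
    run = 1 if still[0] else 0
    for i in range(1, n):
        run = run + 1 if still[i] else 0
        if run >= policy.still_frames:
            v[i] = 0.0
        else:
            v[i] = v[i - 1] + (av[i] + av[i - 1]) * 0.5 * dt
    return ScalarSeries(v, "m/s", rec.sample_rate_hz)
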