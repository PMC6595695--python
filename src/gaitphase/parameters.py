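"""Within-stride gait events and spatio-temporal stride parameters.

Event definitions are documented stand-ins for the published foot-worn-IMU
conventions: mid-stance (MS) is the minimum of the gyroscope magnitude in the
middle 60% of a stride, toe-off (TO) the GZ maximum in the first half, and
heel-strike (HS) the strongest negative GZ slope in the second half.  All
spatial parameters are computed between two consecutive MS events, where the
foot is assumed stationary: orientation is estimated from the accelerometer
at the first MS (static assumption), gravity is removed, and acceleration is
double-integrated with zero-velocity constraints at both MS anchors plus a
linear velocity-drift correction in between.

Numerical scheme: acceleration -> velocity uses the left-rectangle rule
(exact for piecewise-constant acceleration with jumps on samples), velocity
-> position uses the trapezoid rule (exact for the piecewise-linear velocity
the first step produces).  Angles and turning angles use trapezoidal
quadrature of GZ.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    G0,
    EventDetectionError,
    GaitEvents,
    ImuRecording,
    StrideRecord,
    StrideSegment,
    ValidationError,
)

#: world vertical (superior-inferior axis carries gravity in the sensor frame)
_WORLD_UP = np.array([0.0, 1.0, 0.0])


def detect_events(recording: ImuRecording, segment: StrideSegment) -> GaitEvents:
    """Detect MS, TO and HS sample indices within one stride segment."""
    s, e = segment.start, segment.end
    if e > len(recording):
        raise ValidationError("segment exceeds recording length")
    gz = recording.gz[s:e]
    n = len(gz)
    if n < 5 or np.ptp(gz) == 0:
        raise EventDetectionError("degenerate (constant or too short) GZ segment")
    lo = int(0.2 * n)
    hi = max(lo + 1, int(0.8 * n))
    mag = recording.gyro_magnitude[s + lo : s + hi]
    ms = s + lo + int(np.argmin(mag))
    half = n // 2
    to = s + int(np.argmax(gz[:half]))
    dgz = np.diff(gz)
    hs = s + half + int(np.argmin(dgz[half:]))
    if not to < hs:
        raise EventDetectionError("event ordering TO < HS violated")
    ev = GaitEvents(hs=hs, to=to, ms=ms)
    ev.check_within(segment)
    return ev


def compute_temporal(
    events_i: GaitEvents, events_next: GaitEvents, sampling_rate: float
) -> tuple[float, float, float]:
    """Stride time plus swing/stance fractions from consecutive-stride events.

    Swing spans TO to HS of the cycle terminating the stride; stance is the
    complement, both relative to stride time (consecutive-HS interval)."""
    dhs = events_next.hs - events_i.hs
    if dhs <= 0:
        raise ValidationError("events are not from consecutive strides of one foot")
    stride_time = dhs / sampling_rate
    swing = (events_next.hs - events_next.to) / dhs
    return stride_time, swing, 1.0 - swing


def _orientation_at(recording: ImuRecording, idx: int, window: int = 2) -> Rotation:
    a = max(0, idx - window)
    b = min(len(recording), idx + window + 1)
    g_sensor = np.array(
        [np.mean(recording.ax[a:b]), np.mean(recording.ay[a:b]), np.mean(recording.az[a:b])]
    )
    norm = np.linalg.norm(g_sensor)
    if norm < 1e-6:
        raise EventDetectionError("accelerometer magnitude ~0 at mid-stance; cannot orient")
    rot, _ = Rotation.align_vectors([_WORLD_UP], [g_sensor / norm])
    return rot


def integrate_trajectory(
    recording: ImuRecording, ms_i: int, ms_next: int, height_cm: float
) -> tuple[float, float, float]:
    """Height-normalized stride length and path length, plus toe clearance (m).

    Double-integrates the gravity-corrected acceleration between two
    consecutive MS events with zero-velocity anchors at both ends."""
    if not ms_i < ms_next:
        raise ValidationError("mid-stance indices must be increasing")
    if ms_next - ms_i < 3:
        raise ValidationError("MS-to-MS window shorter than 3 samples")
    if height_cm <= 0:
        raise ValidationError("height must be > 0")
    dt = 1.0 / recording.sampling_rate
    sl = slice(ms_i, ms_next + 1)
    acc_sensor = np.column_stack([recording.ax[sl], recording.ay[sl], recording.az[sl]]) * G0
    rot = _orientation_at(recording, ms_i)
    acc_world = rot.apply(acc_sensor) - _WORLD_UP * G0

    vel = np.vstack([np.zeros(3), np.cumsum(acc_world[:-1] * dt, axis=0)])
    # linear de-drift so velocity is exactly zero at both MS anchors
    frac = np.linspace(0.0, 1.0, len(vel))[:, None]
    vel = vel - frac * vel[-1]

    steps = 0.5 * (vel[1:] + vel[:-1]) * dt
    pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])

    height_m = height_cm / 100.0
    horizontal = pos[-1][[0, 2]]
    stride_length = float(np.linalg.norm(horizontal)) / height_m
    path_length = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))) / height_m
    toe_clearance = float(np.max(pos[:, 1]) - pos[0, 1])
    return stride_length, path_length, toe_clearance


def zupt_velocity(recording: ImuRecording, ms_i: int, ms_next: int) -> np.ndarray:
    """De-drifted world-frame velocity between two MS anchors (for checks)."""
    dt = 1.0 / recording.sampling_rate
    sl = slice(ms_i, ms_next + 1)
    acc_sensor = np.column_stack([recording.ax[sl], recording.ay[sl], recording.az[sl]]) * G0
    rot = _orientation_at(recording, ms_i)
    acc_world = rot.apply(acc_sensor) - _WORLD_UP * G0
    vel = np.vstack([np.zeros(3), np.cumsum(acc_world[:-1] * dt, axis=0)])
    frac = np.linspace(0.0, 1.0, len(vel))[:, None]
    return vel - frac * vel[-1]


def _signed_gz_integral(recording: ImuRecording, a: int, b: int) -> float:
    if a == b:
        return 0.0
    dt = 1.0 / recording.sampling_rate
    lo, hi = (a, b) if a < b else (b, a)
    val = float(np.trapezoid(recording.gz[lo : hi + 1], dx=dt))
    return val if a < b else -val


def compute_angles(recording: ImuRecording, events: GaitEvents) -> tuple[float, float]:
    """Sagittal foot angles (deg) at HS and TO.

    The foot is assumed flat (0 deg) at MS; angles are the GZ integral from MS
    to the event, dorsiflexion-positive."""
    hs_angle = _signed_gz_integral(recording, events.ms, events.hs)
    to_angle = _signed_gz_integral(recording, events.ms, events.to)
    return hs_angle, to_angle


def compute_turning_angle(recording: ImuRecording, ms_i: int, ms_next: int) -> float:
    """Signed turning angle (deg): GZ integrated MS to MS (yaw projection)."""
    if not ms_i < ms_next:
        raise ValidationError("mid-stance indices must be increasing")
    return _signed_gz_integral(recording, ms_i, ms_next)


def compute_stride_velocity(stride_length: float, stride_time: float) -> float:
    """Height-normalized stride velocity (1/s) = stride length / stride time."""
    if stride_time <= 0:
        raise ValidationError("stride_time must be > 0")
    return stride_length / stride_time


def extract_stride_records(
    recording: ImuRecording,
    segments: list[StrideSegment],
    height_cm: float,
    events: list[GaitEvents] | None = None,
) -> list[StrideRecord]:
    """Per-stride parameters for all strides with a following stride.

    Stride ``i`` uses events of strides ``i`` and ``i+1`` (HS-to-HS time,
    MS-to-MS trajectory), so the last segment yields no record."""
    if events is None:
        events = [detect_events(recording, seg) for seg in segments]
    records = []
    for i in range(len(segments) - 1):
        ev_i, ev_n = events[i], events[i + 1]
        stride_time, swing, stance = compute_temporal(ev_i, ev_n, recording.sampling_rate)
        length, path, clearance = integrate_trajectory(recording, ev_i.ms, ev_n.ms, height_cm)
        hs_angle, to_angle = compute_angles(recording, ev_i)
        ta = compute_turning_angle(recording, ev_i.ms, ev_n.ms)
        records.append(
            StrideRecord(
                stride_time=stride_time,
                swing_time=swing,
                stance_time=stance,
                stride_length=length,
                stride_velocity=compute_stride_velocity(length, stride_time),
                hs_angle=hs_angle,
                to_angle=to_angle,
                max_toe_clearance=clearance,
                path_length=path,
                turning_angle=ta,
                foot=recording.foot,
                start_time=segments[i].start / recording.sampling_rate,
            )
        )
    return records
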