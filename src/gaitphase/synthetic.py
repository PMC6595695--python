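"""Synthetic 4x10 m walk-test generator.

Real cohort recordings for this protocol are not publicly deposited, so this
module generates ground-truth stride schedules, IMU-like per-foot signals and
two-class cohorts that emulate the test's structure: four straight ~10 m
bouts separated by three 180-degree turns, with acceleration/deceleration
velocity ramps at bout boundaries.

The per-stride GZ (medio-lateral gyroscope) waveform is a schematic, not a
biomechanical model: a deep trough at each stride boundary (so boundaries are
GZ minima, as the segmentation stage assumes), a positive transient after the
boundary, an exactly-zero "foot flat" window that anchors mid-stance, and a
swing peak.  The two half-waveforms on either side of the flat window each
integrate to zero, so the yaw accumulated between consecutive mid-stance
events is carried purely by an explicit rectangular yaw-rate pulse whose area
equals the scheduled turning angle.  Forward acceleration is a triangular
velocity pulse between mid-stance events whose displacement equals the
scheduled stride length, with the foot exactly at rest at both anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_SAMPLING_RATE,
    GaitEvents,
    ImuRecording,
    ParameterError,
    StrideSegment,
    SubjectRecord,
)

# --------------------------------------------------------------------------
# GZ stride waveform
# --------------------------------------------------------------------------

#: normalized-time window in which the foot is exactly flat (gz == 0)
FLAT0, FLAT1 = 0.32, 0.40

_TROUGH_DEPTH = 400.0  # deg/s, boundary minima
_SIGMA_B = 0.05        # width of boundary troughs and post-boundary bump
_BUMP_CENTER = 0.12
_SWING_CENTER = 0.65
_SIGMA_S = 0.08


def _gauss(u, c, s):
    return np.exp(-((u - c) ** 2) / (2.0 * s**2))


def _calibrate_amplitudes():
    # choose bump/swing amplitudes so each half-waveform integrates to zero,
    # making mid-stance-to-mid-stance yaw independent of the base shape
    u_a = np.linspace(0.0, FLAT0, 20001)
    u_b = np.linspace(FLAT1, 1.0, 20001)
    trough_a = -_TROUGH_DEPTH * np.trapezoid(_gauss(u_a, 0.0, _SIGMA_B), u_a)
    bump_unit = np.trapezoid(_gauss(u_a, _BUMP_CENTER, _SIGMA_B), u_a)
    trough_b = -_TROUGH_DEPTH * np.trapezoid(_gauss(u_b, 1.0, _SIGMA_B), u_b)
    swing_unit = np.trapezoid(_gauss(u_b, _SWING_CENTER, _SIGMA_S), u_b)
    return -trough_a / bump_unit, -trough_b / swing_unit


_BUMP_AMP, _SWING_AMP = _calibrate_amplitudes()


def stride_waveform(u: np.ndarray) -> np.ndarray:
    """Base GZ waveform (deg/s) over normalized stride time ``u`` in [0, 1)."""
    u = np.asarray(u, dtype=float)
    gz = (
        -_TROUGH_DEPTH * _gauss(u, 0.0, _SIGMA_B)
        + _BUMP_AMP * _gauss(u, _BUMP_CENTER, _SIGMA_B)
        + _SWING_AMP * _gauss(u, _SWING_CENTER, _SIGMA_S)
        - _TROUGH_DEPTH * _gauss(u, 1.0, _SIGMA_B)
    )
    gz[(u >= FLAT0) & (u <= FLAT1)] = 0.0
    return gz


# --------------------------------------------------------------------------
# Stride schedules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduledStride:
    """Ground truth for one stride."""

    phase: str                 # acceleration | constant | deceleration | turning
    stride_time: float         # s
    stride_velocity: float     # m/s (not height-normalized)
    turning_angle: float       # deg, signed
    bout_id: int | None


@dataclass
class StrideSchedule:
    """Ordered ground-truth strides of one foot over the whole test."""

    strides: list[ScheduledStride]

    def __len__(self) -> int:
        return len(self.strides)

    @property
    def phases(self) -> list[str]:
        return [s.phase for s in self.strides]

    @property
    def stride_times(self) -> np.ndarray:
        return np.array([s.stride_time for s in self.strides])

    @property
    def velocities(self) -> np.ndarray:
        return np.array([s.stride_velocity for s in self.strides])

    @property
    def turning_angles(self) -> np.ndarray:
        return np.array([s.turning_angle for s in self.strides])


def _ramp_fraction(v_min_frac: float, i: int, n: int) -> float:
    return v_min_frac + (1.0 - v_min_frac) * i / n


def generate_schedule(
    n_bouts: int = 4,
    strides_per_bout: int = 10,
    n_accel: int = 3,
    n_decel: int = 3,
    turn_strides: int = 4,
    v_const: float = 1.3,
    v_min_frac: float = 0.5,
    ta_turn_deg: float = 60.0,
    ta_straight_sd: float = 3.0,
    seed: int | None = 0,
    stride_time_const: float = 1.1,
    cadence_exponent: float = 0.5,
    turn_time_factor: float = 1.2,
    ta_turn_sd: float = 5.0,
    v_noise_sd: float = 0.0,
    t_noise_sd: float = 0.0,
    velocity_shift: float = 0.0,
) -> StrideSchedule:
    """Ground-truth stride schedule for an ``n_bouts`` x 10 m walk test.

    Within each bout the velocity ramps linearly from ``v_min_frac * v_const``
    up to ``v_const`` over the first ``n_accel`` strides and mirrors over the
    last ``n_decel`` strides.  Stride time scales as
    ``stride_time_const * (v_const / v)**cadence_exponent`` so that slower
    strides are both shorter and slower-cadenced.  Turning strides carry a
    positive turning angle near ``ta_turn_deg``; straight strides carry
    ``N(0, ta_straight_sd)``.  ``velocity_shift`` is subtracted additively
    from every straight and turning stride velocity (used by the cohort
    generator to model impairment).
    """
    if n_bouts < 2:
        raise ParameterError("n_bouts must be >= 2")
    if n_accel + n_decel >= strides_per_bout:
        raise ParameterError("n_accel + n_decel must be < strides_per_bout")
    if turn_strides < 1:
        raise ParameterError("turn_strides must be >= 1")
    rng = np.random.default_rng(seed)
    strides: list[ScheduledStride] = []

    def _make_straight(phase: str, v: float, bout_id: int) -> ScheduledStride:
        v = max(0.2, v - velocity_shift + rng.normal(0.0, v_noise_sd) if v_noise_sd else v - velocity_shift)
        t = stride_time_const * (v_const / v) ** cadence_exponent
        if t_noise_sd:
            t *= 1.0 + rng.normal(0.0, t_noise_sd)
        ta = rng.normal(0.0, ta_straight_sd) if ta_straight_sd else 0.0
        return ScheduledStride(phase, t, v, ta, bout_id)

    for bout in range(n_bouts):
        n_const = strides_per_bout - n_accel - n_decel
        for i in range(n_accel):
            v = v_const * _ramp_fraction(v_min_frac, i, n_accel)
            strides.append(_make_straight("acceleration", v, bout))
        for _ in range(n_const):
            strides.append(_make_straight("constant", v_const, bout))
        for k in range(n_decel - 1, -1, -1):
            v = v_const * _ramp_fraction(v_min_frac, k, n_decel)
            strides.append(_make_straight("deceleration", v, bout))
        if bout < n_bouts - 1:
            for _ in range(turn_strides):
                v = max(0.2, 0.5 * v_const - velocity_shift)
                if v_noise_sd:
                    v = max(0.2, v + rng.normal(0.0, v_noise_sd))
                t = stride_time_const * turn_time_factor
                if t_noise_sd:
                    t *= 1.0 + rng.normal(0.0, t_noise_sd)
                ta = max(30.0, rng.normal(ta_turn_deg, ta_turn_sd)) if ta_turn_sd else ta_turn_deg
                strides.append(ScheduledStride("turning", t, v, ta, None))
    return StrideSchedule(strides)


# --------------------------------------------------------------------------
# IMU synthesis
# --------------------------------------------------------------------------


@dataclass
class SyntheticRecording:
    """Both feet's signals plus the ground truth used to generate them."""

    left: ImuRecording
    right: ImuRecording
    segments: dict[str, list[StrideSegment]]
    events: dict[str, list[GaitEvents]]
    schedule: StrideSchedule


def _true_mid_stance(start: int, n: int) -> int:
    # first sample of the exactly-zero flat window
    return start + int(np.ceil(FLAT0 * n))


def _render_foot(
    schedule: StrideSchedule,
    foot: str,
    sampling_rate: float,
    noise_sd: float,
    acc_noise_g: float,
    rng: np.random.Generator,
    phase_offset_s: float,
    pad_s: float = 0.5,
):
    fs = sampling_rate
    times = np.concatenate([[0.0], np.cumsum(schedule.stride_times)])
    starts = np.round((pad_s + phase_offset_s + times) * fs).astype(int)
    n_per = np.diff(starts)
    if np.any(n_per < 20):
        raise ParameterError("stride too short for synthesis at this sampling rate")
    total = starts[-1] + int(round(pad_s * fs))

    gz = np.zeros(total)
    ax_ms2 = np.zeros(total)
    segments = []
    for i, n in enumerate(n_per):
        u = np.arange(n) / n
        gz[starts[i] : starts[i] + n] = stride_waveform(u)
        segments.append(StrideSegment(int(starts[i]), int(starts[i] + n), foot))

    ms = [_true_mid_stance(int(starts[i]), int(n_per[i])) for i in range(len(n_per))]
    margin = max(3, int(round(0.05 * fs)))
    for i in range(len(n_per) - 1):
        p0, p1 = ms[i] + margin, ms[i + 1] - margin
        if p1 - p0 < 4:
            raise ParameterError("mid-stance window too short for pulse placement")
        tau = (p1 - p0) / fs
        # rectangular yaw-rate pulse: area equals the scheduled turning angle
        gz[p0:p1] += schedule.strides[i].turning_angle / tau
        # triangular forward-velocity pulse: displacement equals scheduled length
        length = schedule.strides[i].stride_velocity * schedule.strides[i].stride_time
        pm = p0 + (p1 - p0) // 2
        tau1, tau2 = (pm - p0) / fs, (p1 - pm) / fs
        v_peak = 2.0 * length / tau
        ax_ms2[p0:pm] += v_peak / tau1
        ax_ms2[pm:p1] -= v_peak / tau2

    from .core import G0

    channels = {
        "ax": ax_ms2 / G0,
        "ay": np.ones(total),
        "az": np.zeros(total),
        "gx": np.zeros(total),
        "gy": np.zeros(total),
        "gz": gz,
    }
    clean = ImuRecording.from_channels(foot, {k: v.copy() for k, v in channels.items()}, fs)

    from .parameters import detect_events

    events = [detect_events(clean, seg) for seg in segments]

    if noise_sd > 0:
        for k in ("gx", "gy", "gz"):
            channels[k] = channels[k] + rng.normal(0.0, noise_sd, total)
    if acc_noise_g > 0:
        for k in ("ax", "ay", "az"):
            channels[k] = channels[k] + rng.normal(0.0, acc_noise_g, total)
    rec = ImuRecording.from_channels(foot, channels, fs)
    return rec, segments, events


def synthesize_imu(
    schedule: StrideSchedule,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    acc_noise_g: float | None = None,
) -> SyntheticRecording:
    """Emit left/right IMU signals for a schedule, with ground truth.

    Both feet carry the full stride sequence, the right foot phase-shifted by
    half a stride — a simplification of alternating gait that keeps one
    shared ground-truth schedule per recording.  ``noise_sd`` is white
    gyroscope noise in deg/s; accelerometer noise defaults to
    ``noise_sd / 1000`` g.
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be > 0")
    if acc_noise_g is None:
        acc_noise_g = noise_sd * 1e-3
    rng = np.random.default_rng(seed)
    half_stride = 0.5 * float(np.median(schedule.stride_times))
    left, seg_l, ev_l = _render_foot(
        schedule, "left", sampling_rate, noise_sd, acc_noise_g, rng, 0.0
    )
    right, seg_r, ev_r = _render_foot(
        schedule, "right", sampling_rate, noise_sd, acc_noise_g, rng, half_stride
    )
    return SyntheticRecording(
        left=left,
        right=right,
        segments={"left": seg_l, "right": seg_r},
        events={"left": ev_l, "right": ev_r},
        schedule=schedule,
    )


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two-class cohort description.

    Effect sizes model motor impairment as reported clinically: impaired
    subjects walk slower (``velocity_shift`` m/s subtracted from every
    stride), with inflated stride-time variability (``cv_multiplier`` on the
    stride-time noise) and more strides per turn (``extra_turn_strides``).
    """

    n_subjects: int = 20
    impaired_fraction: float = 0.5
    velocity_shift: float = 0.15
    cv_multiplier: float = 2.0
    extra_turn_strides: int = 1
    v_noise_sd: float = 0.03
    t_noise_sd: float = 0.02
    ta_straight_sd: float = 3.0
    ta_turn_deg: float = 60.0
    strides_per_bout: int = 10
    turn_strides: int = 4
    height_mean_cm: float = 172.6
    height_sd_cm: float = 9.2
    v_const_mean: float = 1.3
    v_const_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ParameterError("n_subjects must be >= 4")
        if not (0.0 < self.impaired_fraction < 1.0):
            raise ParameterError("impaired_fraction must be in (0, 1)")


def generate_cohort(spec: CohortSpec) -> tuple[list[StrideSchedule], list[SubjectRecord]]:
    """Generate per-subject schedules and metadata for a two-class cohort.

    The impairment label is stored in both clinical sub-scores (0 or 1)."""
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_subjects + 1)
    rng = np.random.default_rng(child_seeds[0])
    n_impaired = int(round(spec.impaired_fraction * spec.n_subjects))
    impaired = np.zeros(spec.n_subjects, dtype=bool)
    impaired[rng.permutation(spec.n_subjects)[:n_impaired]] = True

    schedules, subjects = [], []
    for i in range(spec.n_subjects):
        sub_rng = np.random.default_rng(child_seeds[i + 1])
        v_const = spec.v_const_mean + (sub_rng.normal(0, spec.v_const_sd) if spec.v_const_sd else 0.0)
        height = spec.height_mean_cm + (sub_rng.normal(0, spec.height_sd_cm) if spec.height_sd_cm else 0.0)
        is_imp = bool(impaired[i])
        sched = generate_schedule(
            strides_per_bout=spec.strides_per_bout,
            turn_strides=spec.turn_strides + (spec.extra_turn_strides if is_imp else 0),
            v_const=v_const,
            ta_turn_deg=spec.ta_turn_deg,
            ta_straight_sd=spec.ta_straight_sd,
            seed=sub_rng.integers(2**31 - 1),
            v_noise_sd=spec.v_noise_sd,
            t_noise_sd=spec.t_noise_sd * (spec.cv_multiplier if is_imp else 1.0),
            velocity_shift=spec.velocity_shift if is_imp else 0.0,
        )
        schedules.append(sched)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                height=float(max(140.0, height)),
                gait_score=int(is_imp),
                postural_stability_score=int(is_imp),
            )
        )
    return schedules, subjects
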