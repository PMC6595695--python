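"""Domain types shared by every stage of the gait-analysis pipeline.

All sample indexing is 0-based and stride segments are half-open
``[start, end)`` windows so that adjacent strides tile the signal without
ambiguity.  Accelerometer channels are stored in units of g and converted
internally with the standard gravity constant; gyroscope channels are in
deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: standard gravity, m/s^2 — used wherever accelerations in g become m/s^2
G0 = 9.80665

#: default sampling rate of the foot-worn sensors, Hz
DEFAULT_SAMPLING_RATE = 102.4

#: valid stride phase labels
PHASES = ("turning", "acceleration", "constant", "deceleration", "unassigned")

#: the four gait clusters reported per subject
CLUSTERS = ("baseline", "constant", "non_constant", "turning")


class GaitError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GaitError):
    """A file does not have the expected structure (columns, keys)."""


class ValidationError(GaitError):
    """Data violates an invariant (non-monotone time, overlapping strides...)."""


class ParameterError(GaitError):
    """An operation was called with infeasible parameters."""


class EventDetectionError(GaitError):
    """Within-stride gait events could not be detected."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class ImuRecording:
    """Per-foot 6-axis IMU time series.

    Axis convention (sensor mounted laterally on the shoe): x is
    posterior–anterior, y superior–inferior, z medio-lateral.  ``ax..az``
    are in g, ``gx..gz`` in deg/s.
    """

    foot: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ValidationError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        for name in ("t", "ax", "ay", "az", "gx", "gy", "gz"):
            setattr(self, name, _as_float_array(getattr(self, name), name))
        n = len(self.t)
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        for name in ("ax", "ay", "az", "gx", "gy", "gz"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name} length differs from t")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > 1e-9:
            raise ValidationError("timestamps must be uniform at the sampling rate")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def gyro_magnitude(self) -> np.ndarray:
        return np.sqrt(self.gx**2 + self.gy**2 + self.gz**2)

    @classmethod
    def from_channels(
        cls, foot: str, channels: dict, sampling_rate: float = DEFAULT_SAMPLING_RATE
    ) -> "ImuRecording":
        n = len(channels["gz"])
        t = np.arange(n) / sampling_rate
        return cls(foot=foot, t=t, sampling_rate=sampling_rate, **channels)


@dataclass(frozen=True, order=True)
class StrideSegment:
    """Half-open sample window ``[start, end)`` of one stride of one foot."""

    start: int
    end: int
    foot: str = "left"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"invalid segment [{self.start}, {self.end})")
        if self.foot not in ("left", "right"):
            raise ValidationError(f"foot must be 'left' or 'right', got {self.foot!r}")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GaitEvents:
    """Heel-strike, toe-off and mid-stance sample indices within a stride."""

    hs: int
    to: int
    ms: int

    def check_within(self, segment: StrideSegment) -> None:
        for name, idx in (("hs", self.hs), ("to", self.to), ("ms", self.ms)):
            if not (segment.start <= idx < segment.end):
                raise ValidationError(
                    f"event {name}={idx} outside segment [{segment.start}, {segment.end})"
                )


def validate_segments(segments: Sequence[StrideSegment], n_samples: int | None = None) -> None:
    """Check that segments of one foot are in-bounds, ordered and disjoint."""
    prev_end = {}
    for seg in segments:
        if n_samples is not None and seg.end > n_samples:
            raise ValidationError(f"segment [{seg.start}, {seg.end}) exceeds signal length {n_samples}")
        if seg.foot in prev_end and seg.start < prev_end[seg.foot]:
            raise ValidationError(
                f"segments overlap or are unordered at [{seg.start}, {seg.end}) ({seg.foot})"
            )
        prev_end[seg.foot] = seg.end


@dataclass
class StrideRecord:
    """Spatio-temporal parameters of one stride plus its phase label.

    ``stride_length`` and ``path_length`` are dimensionless (metres divided by
    body height in metres); ``stride_velocity`` is height-normalized m/s, i.e.
    1/s.  ``swing_time`` and ``stance_time`` are fractions of ``stride_time``.
    """

    stride_time: float
    swing_time: float
    stance_time: float
    stride_length: float
    stride_velocity: float
    hs_angle: float
    to_angle: float
    max_toe_clearance: float
    path_length: float
    turning_angle: float
    foot: str = "left"
    label: str = "unassigned"
    bout_id: int | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.stride_time <= 0:
            raise ValidationError("stride_time must be > 0")
        if abs(self.swing_time + self.stance_time - 1.0) > 1e-9:
            raise ValidationError("swing_time + stance_time must equal 1")
        if abs(self.stride_velocity - self.stride_length / self.stride_time) > 1e-9:
            raise ValidationError("stride_velocity must equal stride_length / stride_time")
        if self.label not in PHASES:
            raise ValidationError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata: body height and the two clinical sub-scores."""

    subject_id: str
    height: float  # cm
    gait_score: int
    postural_stability_score: int

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValidationError("height must be > 0")
        for s in (self.gait_score, self.postural_stability_score):
            if not (0 <= int(s) <= 4):
                raise ValidationError("clinical scores must be in 0..4")


class GaitClusterSet:
    """Partition bookkeeping for the final stride labels of one subject.

    The turning, constant and non-constant clusters are pairwise disjoint and
    together exhaust all segmented strides; the baseline cluster is the union
    of constant and non-constant (all straight strides).
    """

    def __init__(self, strides: Sequence[StrideRecord]):
        self.strides = list(strides)
        self.check_partition()

    def check_partition(self) -> None:
        for i, s in enumerate(self.strides):
            if s.label == "unassigned":
                raise ValidationError(f"stride {i} escaped labeling (unassigned)")

    def view(self, cluster: str) -> list[StrideRecord]:
        if cluster == "baseline":
            return [s for s in self.strides if s.label in ("acceleration", "constant", "deceleration")]
        if cluster == "constant":
            return [s for s in self.strides if s.label == "constant"]
        if cluster == "non_constant":
            return [s for s in self.strides if s.label in ("acceleration", "deceleration")]
        if cluster == "turning":
            return [s for s in self.strides if s.label == "turning"]
        raise ValidationError(f"unknown cluster {cluster!r}")
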