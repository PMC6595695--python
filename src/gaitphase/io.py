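"""Readers and writers for the plain-text interchange formats.

IMU CSV: columns ``time,ax,ay,az,gx,gy,gz``, one file per foot, '.' decimal.
Annotation JSON: a list of ``{start,end,hs,to,ms,label,foot,bout_id}`` where
``hs/to/ms/label/bout_id`` may be null.  Subject metadata CSV: columns
``subject_id,height,gait_score,postural_stability_score``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    GaitEvents,
    ImuRecording,
    StrideSegment,
    SubjectRecord,
    ValidationError,
    validate_segments,
)

IMU_COLUMNS = ["time", "ax", "ay", "az", "gx", "gy", "gz"]


def read_imu_csv(path, foot: str, sampling_rate: float | None = None) -> ImuRecording:
    """Read one foot's 6-axis recording; the sampling rate is inferred from
    the time column unless given explicitly."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{path}: time column is not strictly increasing")
        if sampling_rate is None:
            sampling_rate = 1.0 / np.mean(dt)
    elif sampling_rate is None:
        raise ValidationError(f"{path}: cannot infer sampling rate from < 2 samples")
    return ImuRecording(
        foot=foot,
        t=t,
        ax=df["ax"].to_numpy(float),
        ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float),
        gx=df["gx"].to_numpy(float),
        gy=df["gy"].to_numpy(float),
        gz=df["gz"].to_numpy(float),
        sampling_rate=sampling_rate,
    )


def write_imu_csv(recording: ImuRecording, path) -> None:
    df = pd.DataFrame(
        {
            "time": recording.t,
            "ax": recording.ax,
            "ay": recording.ay,
            "az": recording.az,
            "gx": recording.gx,
            "gy": recording.gy,
            "gz": recording.gz,
        }
    )
    # 17 significant digits: values round-trip bit-identically, so the
    # uniform-time invariant survives a write/read cycle
    df.to_csv(path, index=False, float_format="%.17g")


def write_annotations(
    segments: Sequence[StrideSegment],
    events: Sequence[GaitEvents | None] | None,
    labels: Sequence[str | None] | None,
    path,
    bout_ids: Sequence[int | None] | None = None,
) -> None:
    """Write per-stride annotations as a JSON list; round-trip is lossless."""
    n = len(segments)
    events = events if events is not None else [None] * n
    labels = labels if labels is not None else [None] * n
    bout_ids = bout_ids if bout_ids is not None else [None] * n
    if not (len(events) == len(labels) == len(bout_ids) == n):
        raise ValidationError("segments, events, labels and bout_ids must have equal length")
    validate_segments(sorted(segments))
    records = []
    for seg, ev, lab, bid in zip(segments, events, labels, bout_ids):
        records.append(
            {
                "start": int(seg.start),
                "end": int(seg.end),
                "foot": seg.foot,
                "hs": None if ev is None else int(ev.hs),
                "to": None if ev is None else int(ev.to),
                "ms": None if ev is None else int(ev.ms),
                "label": lab,
                "bout_id": None if bid is None else int(bid),
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotations(path):
    """Read annotations back as ``(segments, events, labels, bout_ids)``."""
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a JSON list")
    segments, events, labels, bout_ids = [], [], [], []
    for rec in records:
        try:
            segments.append(StrideSegment(int(rec["start"]), int(rec["end"]), rec.get("foot", "left")))
        except KeyError as exc:
            raise FormatError(f"{path}: annotation missing key {exc}") from exc
        if rec.get("hs") is None:
            events.append(None)
        else:
            events.append(GaitEvents(hs=int(rec["hs"]), to=int(rec["to"]), ms=int(rec["ms"])))
        labels.append(rec.get("label"))
        bout_ids.append(rec.get("bout_id"))
    validate_segments(sorted(segments))
    return segments, events, labels, bout_ids


def read_subjects_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = ["subject_id", "height", "gait_score", "postural_stability_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            height=float(r.height),
            gait_score=int(r.gait_score),
            postural_stability_score=int(r.postural_stability_score),
        )
        for r in df.itertuples()
    ]


def write_subjects_csv(subjects: Sequence[SubjectRecord], path) -> None:
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "height": [s.height for s in subjects],
            "gait_score": [s.gait_score for s in subjects],
            "postural_stability_score": [s.postural_stability_score for s in subjects],
        }
    ).to_csv(path, index=False)
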