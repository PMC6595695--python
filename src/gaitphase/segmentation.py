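"""Template-based stride segmentation on the GZ gyroscope axis.

Strides are found by subsequence dynamic time warping (DTW) of a
single-stride GZ template against the continuous signal, followed by
refinement of the segment borders to local GZ minima.  Manual corrections
(the interactive step of semi-automatic workflows) are mechanized as edits
applied from an annotation file.

The DTW is the classic subsequence variant: free start anywhere in the
signal, unit-weight steps (match, insertion, deletion), absolute-difference
local cost on z-normalized series, and accumulated distance normalized by
template length.  Instead of a Sakoe-Chiba band the warping is bounded by a
match-length window (default 0.6-1.8 template lengths), which plays the same
role while still admitting the strongly time-stretched strides of
acceleration and deceleration phases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .core import StrideSegment, ValidationError, validate_segments

#: default acceptance threshold on the z-normalized, length-normalized
#: distance; genuine strides score ~0.1, featureless (flat) windows ~0.7
DEFAULT_DISTANCE_THRESHOLD = 0.4


@dataclass
class Template:
    """One exemplary stride's GZ waveform."""

    waveform: np.ndarray

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1 or len(self.waveform) < 10:
            raise ValidationError("template must be 1-D with >= 10 samples")
        if not np.all(np.isfinite(self.waveform)):
            raise ValidationError("template contains non-finite values")

    def __len__(self) -> int:
        return len(self.waveform)


def canonical_template(n_samples: int = 113) -> Template:
    """Packaged canonical single-stride GZ template (schematic waveform)."""
    from .synthetic import stride_waveform

    return Template(stride_waveform(np.arange(n_samples) / n_samples))


def template_from_segment(gz: np.ndarray, segment: StrideSegment) -> Template:
    return Template(np.asarray(gz, float)[segment.start : segment.end])


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


@njit(cache=True)
def _subseq_dtw_dp(template, signal):  # pragma: no cover - exercised via wrapper
    m, n = len(template), len(signal)
    dist_prev = np.empty(n)
    dist_curr = np.empty(n)
    start_prev = np.empty(n, dtype=np.int64)
    start_curr = np.empty(n, dtype=np.int64)
    for j in range(n):
        dist_prev[j] = abs(template[0] - signal[j])
        start_prev[j] = j
    for i in range(1, m):
        dist_curr[0] = dist_prev[0] + abs(template[i] - signal[0])
        start_curr[0] = 0
        for j in range(1, n):
            c = abs(template[i] - signal[j])
            d_diag = dist_prev[j - 1]
            d_up = dist_prev[j]
            d_left = dist_curr[j - 1]
            if d_diag <= d_up and d_diag <= d_left:
                dist_curr[j] = c + d_diag
                start_curr[j] = start_prev[j - 1]
            elif d_up <= d_left:
                dist_curr[j] = c + d_up
                start_curr[j] = start_prev[j]
            else:
                dist_curr[j] = c + d_left
                start_curr[j] = start_curr[j - 1]
        dist_prev, dist_curr = dist_curr, dist_prev
        start_prev, start_curr = start_curr, start_prev
    return dist_prev, start_prev


def dtw_segment(
    gz: np.ndarray,
    template: Template,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    foot: str = "left",
    min_length_frac: float = 0.6,
    max_length_frac: float = 1.8,
) -> list[StrideSegment]:
    """Detect stride segments by subsequence DTW matching.

    Returns non-overlapping matches with normalized DTW distance at or below
    the threshold, chosen greedily in ascending distance order; ordered by
    start.  Empty or constant signals yield no segments."""
    gz = np.asarray(gz, dtype=float)
    m = len(template)
    if len(gz) <= m or np.std(gz) == 0:
        return []
    dist_end, start_end = _subseq_dtw_dp(_znorm(template.waveform), _znorm(gz))
    dist_end = dist_end / m
    lengths = np.arange(len(gz)) + 1 - start_end
    valid = (
        (dist_end <= distance_threshold)
        & (lengths >= max(2, int(min_length_frac * m)))
        & (lengths <= int(max_length_frac * m))
    )
    order = np.argsort(dist_end, kind="stable")
    taken = np.zeros(len(gz), dtype=bool)
    min_len = max(2, int(min_length_frac * m))
    # candidates brushing an accepted neighbour by a few samples are clipped
    # to the free range instead of discarded
    clip_tol = max(2, int(0.05 * m))
    found: list[StrideSegment] = []
    for j in order:
        if not valid[j]:
            continue
        a, b = int(start_end[j]), int(j) + 1
        a2, b2 = a, b
        while a2 < b2 and taken[a2]:
            a2 += 1
        while b2 > a2 and taken[b2 - 1]:
            b2 -= 1
        if (a2 - a) + (b - b2) > clip_tol or b2 - a2 < min_len or taken[a2:b2].any():
            continue
        taken[a2:b2] = True
        found.append(StrideSegment(a2, b2, foot))
    found.sort(key=lambda s: s.start)
    return found


def refine_by_minima(
    gz: np.ndarray, segments: Sequence[StrideSegment], search_radius_samples: int = 10
) -> list[StrideSegment]:
    """Snap each segment border to the local GZ minimum within the radius.

    Shared borders of adjacent segments move together; on conflict, borders
    are clipped to the midpoint of their original positions so ordering and
    non-overlap are preserved."""
    gz = np.asarray(gz, dtype=float)
    segments = sorted(segments, key=lambda s: (s.foot, s.start))
    validate_segments(segments, len(gz))
    r = int(search_radius_samples)
    out: list[StrideSegment] = []
    by_foot: dict[str, list[StrideSegment]] = {}
    for seg in segments:
        by_foot.setdefault(seg.foot, []).append(seg)
    for foot, segs in by_foot.items():
        # boundary chain: consecutive segments sharing end==start share a border
        bounds = [segs[0].start]
        for prev, seg in zip(segs, segs[1:]):
            bounds.append(prev.end)
            if seg.start != prev.end:
                bounds.append(seg.start)
        bounds.append(segs[-1].end)
        shared = [segs[i].end == segs[i + 1].start for i in range(len(segs) - 1)]

        def _snap(b: int) -> int:
            lo, hi = max(0, b - r), min(len(gz), b + r + 1)
            return lo + int(np.argmin(gz[lo:hi]))

        refined = [_snap(b) for b in bounds]
        for k in range(1, len(refined)):
            if refined[k] <= refined[k - 1]:
                mid = (bounds[k - 1] + bounds[k]) // 2
                refined[k - 1] = min(refined[k - 1], mid)
                refined[k] = max(refined[k], mid + 1)
        # rebuild segments walking the refined boundary chain
        idx = 0
        for i, seg in enumerate(segs):
            a = refined[idx]
            b = refined[idx + 1]
            out.append(StrideSegment(a, b, foot))
            idx += 1 if (i < len(segs) - 1 and shared[i]) else 2
    out.sort(key=lambda s: (s.foot, s.start))
    validate_segments(out, len(gz))
    return out


def apply_corrections(segments: Sequence[StrideSegment], corrections) -> list[StrideSegment]:
    """Apply add/remove/replace edits (a list of dicts or a JSON file path).

    Each edit is ``{"action": "add"|"remove"|"replace", ...}``; ``remove`` and
    ``replace`` address a segment by its exact ``start`` (and ``foot``)."""
    if isinstance(corrections, (str, Path)):
        corrections = json.loads(Path(corrections).read_text())
    result = list(segments)
    for edit in corrections:
        action = edit.get("action")
        if action == "add":
            spec = edit["segment"]
            result.append(StrideSegment(int(spec["start"]), int(spec["end"]), spec.get("foot", "left")))
        elif action in ("remove", "replace"):
            foot = edit.get("foot", "left")
            matches = [
                i for i, s in enumerate(result) if s.start == int(edit["start"]) and s.foot == foot
            ]
            if not matches:
                raise ValidationError(f"no segment with start={edit['start']} ({foot}) to {action}")
            i = matches[0]
            if action == "remove":
                result.pop(i)
            else:
                spec = edit["segment"]
                result[i] = StrideSegment(int(spec["start"]), int(spec["end"]), spec.get("foot", "left"))
        else:
            raise ValidationError(f"unknown edit action {action!r}")
    result.sort(key=lambda s: (s.foot, s.start))
    validate_segments(result)
    return result
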