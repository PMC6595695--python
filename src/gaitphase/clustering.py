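"""Clustering straight strides into constant and non-constant gait.

Straight strides between turns form bouts (nominally the four 10 m walks).
Within each bout, strides are labeled constant or non-constant by one of
nine unsupervised methods:

* ``N%crop`` for N in {5,10,15,20,25}: the first and last N% of strides of
  the bout are non-constant;
* ``median vel`` / ``median t``: after normalizing by the bout median, strides
  outside 0.95-1.05 are non-constant;
* ``distr vel`` / ``distr t``: strides outside mean +/- SD of the bout-mean-
  normalized parameter are non-constant;
* ``3means vel`` / ``3means t``: 1-D k-means with K=3 and five random center
  initializations; the run with the largest cluster separation (minimum
  pairwise center distance) wins, and the smallest and largest centers become
  the thresholds;
* ``perc vel`` / ``perc t``: the empirical 25th/75th percentiles (linear
  interpolation) become the thresholds.

A post-processing automaton then enforces the natural order acceleration ->
constant -> deceleration: non-constant strides may only survive inside the
first/last 25% band of the bout (band size ``ceil(0.25 n)``); within the head
band everything up to the last raw non-constant stride becomes acceleration,
mirrored at the tail for deceleration, and every other stride becomes
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ParameterError, ValidationError

CROP_METHODS = {f"{n}%crop": n for n in (5, 10, 15, 20, 25)}
THRESHOLD_METHODS = {
    "median": "median",
    "distr": "distr",
    "3means": "kmeans3",
    "perc": "percentile",
}
#: all method names accepted by :func:`cluster_bout`
METHOD_NAMES = list(CROP_METHODS) + [
    f"{m} {p}" for m in THRESHOLD_METHODS for p in ("vel", "t")
]


@dataclass(frozen=True)
class ThresholdPair:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValidationError("lower threshold must be <= upper")


@dataclass
class Bout:
    """Ordered straight strides (both feet merged by time) between turns."""

    stride_indices: list[int]  # indices into the subject's merged stride list
    bout_id: int

    def __len__(self) -> int:
        return len(self.stride_indices)


def split_into_bouts(n_strides: int, turning_flags) -> list[Bout]:
    """Maximal runs of straight strides between turns become bouts."""
    flags = np.asarray(turning_flags, dtype=bool)
    if len(flags) != n_strides:
        raise ValidationError("turning_flags length must match stride count")
    bouts: list[Bout] = []
    run: list[int] = []
    for i in range(n_strides):
        if flags[i]:
            if run:
                bouts.append(Bout(run, len(bouts)))
                run = []
        else:
            run.append(i)
    if run:
        bouts.append(Bout(run, len(bouts)))
    return bouts


def normalize_bout(values) -> np.ndarray:
    """Divide by the bout mean (the per-bout normalization of both parameters)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ParameterError("bout must contain at least one stride")
    mean = np.mean(values)
    if mean == 0:
        raise ParameterError("bout mean is zero; cannot normalize")
    return values / mean


def crop_labels(n_strides: int, n_percent: float) -> np.ndarray:
    """Boolean non-constant mask: first and last ``round(n_percent% * n)`` strides.

    Rounding is half-up; if the two crops cover the bout, all strides are
    non-constant."""
    if n_strides < 1:
        raise ParameterError("empty bout")
    k = int(math.floor(n_percent / 100.0 * n_strides + 0.5))
    non_constant = np.zeros(n_strides, dtype=bool)
    if k > 0:
        non_constant[:k] = True
        non_constant[n_strides - k :] = True
    return non_constant


def _percentile(values: np.ndarray, q: float) -> float:
    """Linear interpolation between order statistics at rank q*(n-1)."""
    s = np.sort(values)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    return float(s[lo] + (pos - lo) * (s[hi] - s[lo]))


def _kmeans_1d(values: np.ndarray, k: int, rng: np.random.Generator, n_init: int, max_iter: int = 100):
    distinct = np.unique(values)
    if len(distinct) < k:
        raise ParameterError(f"k-means needs >= {k} distinct values")
    best = None
    for _ in range(n_init):
        # k-means++-style seeding: subsequent centers drawn with probability
        # proportional to squared distance from the nearest chosen center,
        # so well-separated modes are all covered with high probability
        chosen = [rng.choice(distinct)]
        while len(chosen) < k:
            d2 = np.min(np.abs(distinct[:, None] - np.array(chosen)[None, :]), axis=1) ** 2
            if d2.sum() == 0:
                chosen.append(rng.choice(distinct))
            else:
                chosen.append(rng.choice(distinct, p=d2 / d2.sum()))
        centers = np.sort(np.array(chosen))
        for _ in range(max_iter):
            # ties broken toward the lower-index center
            d = np.abs(values[:, None] - centers[None, :])
            assign = np.argmin(d, axis=1)
            new_centers = centers.copy()
            for c in range(k):
                members = values[assign == c]
                if len(members):
                    new_centers[c] = members.mean()
            new_centers = np.sort(new_centers)
            if np.allclose(new_centers, centers, rtol=0, atol=1e-12):
                centers = new_centers
                break
            centers = new_centers
        separation = np.min(np.diff(np.sort(centers)))
        if best is None or separation > best[0]:
            best = (separation, centers)
    return best[1]


def threshold_labels(
    values,
    method: str,
    seed: int | None = 0,
) -> tuple[ThresholdPair, np.ndarray]:
    """Non-constant mask from lower/upper thresholds on normalized values.

    ``method`` is one of median/distr/kmeans3/percentile.  A stride is
    constant iff ``lower < value < upper`` (strict on both sides).  Returns
    the thresholds on the normalized scale together with the mask."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ParameterError("threshold methods need at least 3 strides per bout")
    if method == "median":
        med = np.median(values)
        if med == 0:
            raise ParameterError("bout median is zero; cannot normalize")
        norm = values / med
        pair = ThresholdPair(0.95, 1.05)
    elif method == "distr":
        norm = normalize_bout(values)
        sd = float(np.std(norm, ddof=1))
        pair = ThresholdPair(float(np.mean(norm)) - sd, float(np.mean(norm)) + sd)
    elif method == "kmeans3":
        norm = normalize_bout(values)
        centers = _kmeans_1d(norm, 3, np.random.default_rng(seed), n_init=5)
        pair = ThresholdPair(float(centers[0]), float(centers[-1]))
    elif method == "percentile":
        norm = normalize_bout(values)
        pair = ThresholdPair(_percentile(norm, 0.25), _percentile(norm, 0.75))
    else:
        raise ParameterError(f"unknown threshold method {method!r}")
    non_constant = ~((norm > pair.lower) & (norm < pair.upper))
    return pair, non_constant


def postprocess_labels(raw_non_constant) -> np.ndarray:
    """Enforce acceleration* constant* deceleration* within one bout.

    Returns an array of labels from {"acceleration", "constant",
    "deceleration"}.  Non-constant strides can only occur inside the first and
    last ``ceil(0.25 n)`` strides."""
    raw = np.asarray(raw_non_constant, dtype=bool)
    n = len(raw)
    if n == 0:
        return np.empty(0, dtype=object)
    if n == 1:
        # a one-stride bout has no within-bout contrast to tell acceleration
        # from deceleration; calling it constant keeps reversal symmetry
        return np.array(["constant"], dtype=object)
    band = math.ceil(0.25 * n)
    labels = np.full(n, "constant", dtype=object)
    head = np.flatnonzero(raw[:band])
    if len(head):
        labels[: head[-1] + 1] = "acceleration"
    tail = np.flatnonzero(raw[n - band :])
    if len(tail):
        labels[n - band + tail[0] :] = "deceleration"
    return labels


def cluster_bout(
    velocities,
    stride_times,
    method_name: str,
    seed: int | None = 0,
    postprocess: bool = True,
) -> np.ndarray:
    """Label the strides of one bout by any of the named methods.

    ``velocities``/``stride_times`` are the height-normalized stride velocity
    and the stride time of the bout's strides in time order.  Returns labels
    in {"acceleration", "constant", "deceleration"} (post-processed) or a
    raw boolean→label mapping with non-constant reported as "acceleration"/
    "deceleration" only via post-processing; with ``postprocess=False`` raw
    non-constant strides are labeled "acceleration" if in the first half,
    else "deceleration"."""
    velocities = np.asarray(velocities, dtype=float)
    stride_times = np.asarray(stride_times, dtype=float)
    if len(velocities) != len(stride_times):
        raise ValidationError("velocities and stride_times must align")
    n = len(velocities)
    if method_name in CROP_METHODS:
        raw = crop_labels(n, CROP_METHODS[method_name])
    else:
        parts = method_name.rsplit(" ", 1)
        if len(parts) != 2 or parts[0] not in THRESHOLD_METHODS or parts[1] not in ("vel", "t"):
            raise ParameterError(f"unknown clustering method {method_name!r}")
        series = velocities if parts[1] == "vel" else stride_times
        _, raw = threshold_labels(series, THRESHOLD_METHODS[parts[0]], seed=seed)
    if postprocess:
        return postprocess_labels(raw)
    labels = np.full(n, "constant", dtype=object)
    half = n // 2
    labels[np.flatnonzero(raw[:half])] = "acceleration"
    labels[half + np.flatnonzero(raw[half:])] = "deceleration"
    return labels
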