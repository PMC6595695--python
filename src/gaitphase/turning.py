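"""Turning-stride isolation from per-stride turning angles, per foot.

Strides whose absolute turning angle (TA) exceeds a hard threshold (default
20 deg) are turning strides.  A gamma distribution (location fixed at zero,
chosen because |TA| is positive and single-tailed) is then fitted by maximum
likelihood to the |TA| of the remaining strides, and any remaining stride in
the fitted upper tail (default: above the 90% quantile) that is index-
adjacent to an already-marked stride is marked as well, iterated to a fixed
point.  The hard-threshold set is never shrunk by the gamma step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GaitError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HARD_THRESHOLD_DEG = 20.0
DEFAULT_TAIL_Q = 0.9


@dataclass(frozen=True)
class Turn:
    """A maximal run of consecutive turning strides."""

    start_index: int
    n_strides: int
    turning_time: float  # s, sum of stride times in the run


@dataclass
class TurningResult:
    is_turning: np.ndarray  # bool per stride
    turns: list[Turn]
    tail_threshold_deg: float | None  # None when the gamma step was skipped


def gamma_tail_threshold(values, q: float = DEFAULT_TAIL_Q) -> float:
    """q-quantile of a zero-location max-likelihood gamma fit to the values.

    Degenerate samples (zero variance) fall back to the empirical quantile,
    where the MLE is undefined."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ParameterError("need at least 3 values for the gamma fit")
    if np.any(values <= 0):
        raise ValidationError("gamma fit requires strictly positive values")
    if not (0.0 < q < 1.0):
        raise ParameterError("q must be in (0, 1)")
    if np.ptp(values) == 0:
        return float(np.quantile(values, q))
    shape, _, scale = stats.gamma.fit(values, floc=0)
    return float(stats.gamma.ppf(q, shape, scale=scale))


def isolate_turning(
    ta_sequence_deg,
    q: float = DEFAULT_TAIL_Q,
    hard_threshold_deg: float = DEFAULT_HARD_THRESHOLD_DEG,
    stride_times=None,
    iterate: bool = True,
) -> TurningResult:
    """Classify each stride of one foot as turning or straight.

    ``iterate=False`` applies the adjacency rule in a single pass instead of
    running it to a fixed point.  ``stride_times`` (s) are used for the turns'
    ``turning_time``; they default to NaN durations when absent."""
    ta = np.abs(np.asarray(ta_sequence_deg, dtype=float))
    if ta.ndim != 1 or len(ta) == 0:
        raise ParameterError("TA sequence must be 1-D and non-empty")
    marked = ta > hard_threshold_deg

    tail_threshold: float | None = None
    residual = ta[~marked]
    residual = residual[residual > 0]
    if len(residual) < 3:
        logger.warning("fewer than 3 positive residual TAs; skipping gamma tail step")
    elif np.any(marked):
        tail_threshold = gamma_tail_threshold(residual, q)
        while True:
            adjacent = np.zeros_like(marked)
            adjacent[1:] |= marked[:-1]
            adjacent[:-1] |= marked[1:]
            new = (~marked) & adjacent & (ta >= tail_threshold)
            if not new.any():
                break
            marked |= new
            if not iterate:
                break

    turns = group_turns(marked, stride_times)
    return TurningResult(is_turning=marked, turns=turns, tail_threshold_deg=tail_threshold)


def group_turns(is_turning, stride_times=None) -> list[Turn]:
    """Group maximal runs of turning strides into turns with summed times."""
    flags = np.asarray(is_turning, dtype=bool)
    if stride_times is None:
        times = np.full(len(flags), np.nan)
    else:
        times = np.asarray(stride_times, dtype=float)
        if len(times) != len(flags):
            raise ValidationError("stride_times length must match flags")
    turns: list[Turn] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            turns.append(Turn(start_index=i, n_strides=j - i, turning_time=float(np.sum(times[i:j]))))
            i = j
        else:
            i += 1
    return turns
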