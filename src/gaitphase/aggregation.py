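"""Per-subject feature vectors: mean and CV per parameter and gait cluster.

For the straight-gait clusters (baseline, constant, non-constant) each of the
ten stride parameters contributes a mean and a coefficient of variation
(CV = sd / |mean|, sd with ddof=1), pooled over feet and bouts.  The signed
turning angle of straight strides is aggregated as |TA|, since a CV of a
zero-mean signed quantity is meaningless.  The turning cluster contributes
per-turn aggregates (mean number of strides, mean turning time) plus
mean and CV over all turning strides of stride length, stride time, stride
velocity and path length.

CVs are reported as missing (NaN) when a cluster has fewer than two strides
or its mean is ~0; means are missing for empty clusters.  Missingness is
explicit and never imputed here.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .core import CLUSTERS, StrideRecord, ValidationError
from .turning import Turn

#: parameters aggregated for straight-gait clusters, in canonical order
STRAIGHT_PARAMETERS = (
    "stride_time",
    "swing_time",
    "stance_time",
    "stride_length",
    "stride_velocity",
    "hs_angle",
    "to_angle",
    "max_toe_clearance",
    "path_length",
    "turning_angle",
)

#: per-stride parameters aggregated for the turning cluster
TURNING_STRIDE_PARAMETERS = ("stride_length", "stride_time", "stride_velocity", "path_length")


def _mean_cv(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    if len(values) < 2 or abs(mean) < 1e-12:
        return mean, math.nan
    return mean, float(np.std(values, ddof=1) / abs(mean))


def straight_feature_names() -> list[str]:
    names = []
    for p in STRAIGHT_PARAMETERS:
        names.extend([f"{p}_mean", f"{p}_cv"])
    return names


def turning_feature_names() -> list[str]:
    names = ["n_strides_per_turn_mean", "turning_time_mean"]
    for p in TURNING_STRIDE_PARAMETERS:
        names.extend([f"turning_{p}_mean", f"turning_{p}_cv"])
    return names


def aggregate(strides: Sequence[StrideRecord], cluster_name: str) -> dict[str, float]:
    """Mean and CV of each straight-gait parameter over a cluster's strides."""
    if cluster_name not in ("baseline", "constant", "non_constant"):
        raise ValidationError(f"aggregate() handles straight clusters, not {cluster_name!r}")
    features: dict[str, float] = {}
    for p in STRAIGHT_PARAMETERS:
        values = np.array([getattr(s, p) for s in strides], dtype=float)
        if p == "turning_angle":
            values = np.abs(values)
        mean, cv = _mean_cv(values)
        features[f"{p}_mean"] = mean
        features[f"{p}_cv"] = cv
    return features


def aggregate_turning(
    turns: Sequence[Turn], turning_strides: Sequence[StrideRecord]
) -> dict[str, float]:
    """Turning-cluster features: per-turn means plus per-stride mean/CV."""
    features: dict[str, float] = {}
    if len(turns) == 0:
        features["n_strides_per_turn_mean"] = math.nan
        features["turning_time_mean"] = math.nan
    else:
        features["n_strides_per_turn_mean"] = float(np.mean([t.n_strides for t in turns]))
        features["turning_time_mean"] = float(np.mean([t.turning_time for t in turns]))
    for p in TURNING_STRIDE_PARAMETERS:
        values = np.array([getattr(s, p) for s in turning_strides], dtype=float)
        mean, cv = _mean_cv(values)
        features[f"turning_{p}_mean"] = mean
        features[f"turning_{p}_cv"] = cv
    return features


def subject_feature_row(strides: Sequence[StrideRecord], turns: Sequence[Turn]) -> dict[str, dict[str, float]]:
    """All four clusters' feature dicts for one labeled subject.

    Also asserts the partition bookkeeping: baseline = constant + non-constant
    and every stride carries a final label."""
    labels = [s.label for s in strides]
    if any(l == "unassigned" for l in labels):
        raise ValidationError("unassigned strides in final output")
    constant = [s for s in strides if s.label == "constant"]
    non_constant = [s for s in strides if s.label in ("acceleration", "deceleration")]
    turning = [s for s in strides if s.label == "turning"]
    baseline = [s for s in strides if s.label != "turning"]
    if len(baseline) != len(constant) + len(non_constant):
        raise ValidationError("cluster partition violated")
    return {
        "baseline": aggregate(baseline, "baseline"),
        "constant": aggregate(constant, "constant"),
        "non_constant": aggregate(non_constant, "non_constant"),
        "turning": aggregate_turning(turns, turning),
    }
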