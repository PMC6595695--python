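"""Isolate turning strides, then split straight strides into constant and
non-constant gait with one of the nine clustering methods."""

import numpy as np

from gaitphase.clustering import cluster_bout, split_into_bouts
from gaitphase.synthetic import generate_schedule
from gaitphase.turning import isolate_turning

schedule = generate_schedule(seed=2)
result = isolate_turning(schedule.turning_angles, stride_times=schedule.stride_times)
print(f"turning strides: {int(result.is_turning.sum())} in {len(result.turns)} turns")
print(f"gamma tail threshold: {result.tail_threshold_deg:.1f} deg")

bouts = split_into_bouts(len(schedule), result.is_turning)
print(f"straight bouts: {len(bouts)}")
for bout in bouts:
    vel = schedule.velocities[bout.stride_indices]
    times = schedule.stride_times[bout.stride_indices]
    labels = cluster_bout(vel, times, "distr vel", seed=0)
    counts = {l: list(labels).count(l) for l in ("acceleration", "constant", "deceleration")}
    print(f"  bout {bout.bout_id}: {counts}")
# Each 10 m bout should start with acceleration strides and end with
# deceleration strides; the middle plateau is the constant gait cluster.
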