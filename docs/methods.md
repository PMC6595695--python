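# Methods

This note documents the models, conventions and numerical choices behind
`gaitphase`, what the synthetic generator does and does not emulate, and the
known limitations.

## Signal model and conventions

A foot-worn 6-axis IMU (accelerometer in g, gyroscope in deg/s) is sampled
at 102.4 Hz, one sensor per shoe, laterally mounted: x posterior–anterior,
y superior–inferior (gravity), z medio-lateral. The medio-lateral gyroscope
axis GZ carries the stride cycle; stride borders are local GZ minima.
Sample indexing is 0-based and stride segments are half-open `[start, end)`
so adjacent strides tile the signal. Accelerations convert to m/s² with
g₀ = 9.80665 m/s².

## Stride segmentation

Subsequence DTW (free start, unit-weight match/insert/delete steps, L1 local
cost) matches a z-normalized single-stride template against the z-normalized
GZ signal; accumulated distance is divided by the template length. Candidate
matches are accepted greedily in ascending distance under a threshold
(default 0.4 — genuine strides score ≈ 0.1 and featureless windows ≈ 0.7 on
this normalization), with non-overlap enforced; candidates brushing an
accepted neighbour by ≤ 5% of the template length are clipped rather than
discarded, which prevents 1-sample conflicts from deleting otherwise perfect
matches. Warping is bounded by a match-length window of 0.6–1.8 template
lengths instead of a Sakoe–Chiba band: acceleration/deceleration strides are
legitimately stretched ~40% relative to steady-state strides, which a 25%
band would reject. Borders are then snapped to the local GZ minimum within a
±10-sample radius; shared borders of adjacent strides move together, and
conflicts clip to the midpoint of the original borders. The interactive
correction step of semi-automatic workflows is mechanized as add / remove /
replace edits read from a JSON file.

## Gait events (documented stand-ins)

The published event-detection chains for this sensor setup are not restated
in full anywhere we can implement from, so the package uses simple,
configurable stand-ins with the same roles:

* **MS (mid-stance)** — minimum of the gyroscope magnitude in the middle
  60% of the stride (foot approximately still);
* **TO (toe-off)** — GZ maximum in the first half;
* **HS (heel-strike)** — strongest negative GZ first difference in the
  second half.

Stride time is the interval between consecutive HS events; swing time is
TO→HS of the cycle terminating the stride, stance its complement, both as
fractions of stride time.

## Trajectory integration (ZUPT)

Between two consecutive MS events the foot is assumed stationary at both
ends. Orientation is estimated once, at the first MS, from the mean
accelerometer vector over ±2 samples (static assumption) and applied to the
whole window; gravity (1 g along world-up) is subtracted. Acceleration →
velocity uses the left-rectangle rule, which is exact for piecewise-constant
acceleration with jumps on sample boundaries; a linear velocity ramp is then
subtracted so velocity is exactly zero at both MS anchors; velocity →
position uses the trapezoid rule, exact for the piecewise-linear velocity
the first step produces. Stride length is the horizontal displacement norm,
path length the 3-D arc length (both divided by body height in metres, so
"stride velocity" is in units of height per second), toe clearance the peak
vertical excursion in metres. Foot angles at HS and TO are trapezoidal GZ
integrals from MS (assumed flat-foot, 0°), dorsiflexion-positive. The
turning angle is the trapezoidal GZ integral from MS to MS — a yaw
projection that is accurate while the sensor's z-axis is near-vertical
during turning; a full 3-D orientation filter is deliberately out of scope.

## Turning isolation

Per foot: (1) mark |TA| > 20°; (2) fit a gamma distribution (location fixed
at 0, maximum likelihood) to the |TA| of the remaining strides — gamma
because |TA| is positive and single-tailed; (3) iterate to a fixed point:
any unmarked stride with |TA| at or above the fitted 90% quantile that is
index-adjacent to a marked stride becomes turning. The hard-threshold set is
never shrunk. A single-pass variant is available since it is unknowable
whether the original procedure iterated. Degenerate samples (zero variance)
fall back to the empirical quantile; fewer than 3 positive residuals skip
the gamma step with a warning. Note the expansion step is *designed* to
absorb the upper tail of the straight-stride |TA| distribution next to
turns, so on cohorts whose straight TA is N(0, 3°) roughly 8–10% of
turn-adjacent straight strides are absorbed; turn-level detection (3 turns
per 4×10 m test) is unaffected.

## Clustering and post-processing

Straight strides between turns form bouts, both feet merged by stride start
time. Parameters are normalized per bout: by the bout mean generally, by the
bout median for the median method (each method normalizes per its own
definition). Thresholds per method: median → 0.95/1.05; distr → mean ± SD
(ddof = 1); 3means → 1-D K-means, K = 3, five seeded random initializations
(3 distinct values drawn uniformly; assignment ties break toward the
lower-index center), keeping the run with the largest separation, defined as
the minimum pairwise distance between the three centers, thresholds = the
outer centers; perc → 25th/75th percentiles with linear interpolation
between order statistics. A stride is constant iff
lower < value < upper, strict on both sides — with 3means the thresholds are
themselves centers of non-constant strides, and inclusive bounds would
absorb them.

The post-processor confines non-constant strides to the first/last
ceil(0.25 n) strides of a bout: in the head band everything up to the last
raw non-constant stride becomes *acceleration*, mirrored from the tail for
*deceleration*, all else *constant*. Crop counts use half-up rounding; the
band uses ceil so it is never empty. A one-stride bout is labeled constant —
with no within-bout contrast, acceleration vs deceleration is undefined, and
this keeps the automaton exactly symmetric under bout reversal. By default
post-processing applies to all nine methods including the crops (for crops
it is a no-op repainting of the same bands); a raw mode is exposed. Bouts
too small for a threshold method (< 3 strides, typically 1–2 stride
fragments between turns) are treated as transition strides: raw
non-constant, then post-processed.

## Aggregation

Per subject and cluster, each parameter contributes mean and CV
(sd(ddof=1)/|mean|), feet pooled. The signed turning angle of straight
strides aggregates as |TA| — a CV of a zero-mean signed quantity is
meaningless. CVs are missing (NaN) below 2 strides or when |mean| < 1e-12;
empty clusters are all-missing. No minimum-stride-count filter is imposed
(the non-constant cluster legitimately has few strides; its CVs are noisy,
which is part of the signal under study). Missingness is explicit here and
only imputed inside the validation stage, from training data.

## Clinical validation

Stratified 60/40 split (per class, round(0.6·n) to training, at least one
subject on each side) keyed to one seed so all cluster/method comparisons
are paired. Training is balanced by random undersampling of the majority
class. Features are imputed by the training median and z-scored with
training statistics; the top 5 features by Fisher score
(μ₁−μ₀)²/(σ₁²+σ₀²), sample variances ddof = 1, ties toward the earlier
canonical column, are selected on the training set. The SVM grid is
C ∈ {0.01, 0.05, 0.1, 0.5, 1, 5, 10, 20, 30, 40, 50, 100} ×
γ ∈ {0, 0.01, 0.05, 0.1, 0.5, 1, 5, 10, 20, 40, 50, 100}, γ = 0 meaning a
linear kernel; inner stratified 5-fold CV maximizes mean AUC of the
continuous decision score (single-class folds are skipped with a warning;
grid ties resolve to the earlier grid entry). AUC uses the midrank
statistic, equivalent to trapezoidal ROC integration. Test rows never touch
imputation, standardization, selection or tuning. No multiple-testing
control is applied across the many cluster × method AUCs — the comparison
is descriptive.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions for all tests. A schedule has 4
bouts of 10 strides per foot (3 acceleration, 4 constant, 3 deceleration),
separated by 3 turning runs of 4 strides; steady-state velocity 1.3 m/s
(subject SD 0.1), stride time 1.1 s scaled by (v_const/v)^0.5 so slower
strides are longer *and* slower-cadenced; velocities ramp linearly from 50%
of steady state; turning strides carry +60° ± 5° each (signs fixed positive;
direction is irrelevant downstream, where |TA| is used) and straight strides
N(0, 3°). Cohorts are half impaired with, by default, 0.15 m/s slower
strides, doubled stride-time noise (CV multiplier 2) and one extra stride
per turn — effect sizes on the strong end of what is reported clinically,
chosen so a small simulated cohort is decisively separable.

The emitted GZ waveform is schematic: Gaussian boundary troughs (so borders
are GZ minima), a post-boundary transient, an exactly-zero foot-flat window
anchoring MS, and a swing peak; the two half-waveforms each integrate to
zero, so MS-to-MS yaw is carried purely by an explicit rectangular yaw-rate
pulse whose area equals the scheduled TA. Forward motion is a triangular
velocity pulse between MS events whose displacement equals the scheduled
stride length, with margins so the foot is exactly at rest at the anchors.
Both feet carry the full stride sequence, the right foot shifted by half a
stride. Not emulated: genuine double support and alternating single-foot
strides, vertical foot kinematics (toe clearance is ~0 by construction),
soft-tissue and sensor-drift artifacts, freezing-of-gait episodes, and any
biomechanically realistic waveform shape. Passing tests therefore show the
chain is correct under its stated assumptions, not that it is robust to
every artifact of real recordings.

## Numerical choices and degenerate inputs

* Timestamps must be uniform within 1e-9 s; IMU CSVs are written with 17
  significant digits and read with round-trip float parsing so files
  round-trip bit-identically.
* Constant or too-short GZ segments raise event-detection errors; empty or
  constant signals yield zero DTW matches (not an error).
* k-means requires ≥ 3 distinct values; median normalization requires a
  nonzero median; bout normalization a nonzero mean.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; reruns of the pipeline with
  one config produce byte-identical output files and manifests.
* Problem sizes in the test-suite and acceptance script (200-seed turning
  sweeps, 10⁵-draw gamma fits, 120-subject feature cohorts, 8–24-subject
  full-pipeline cohorts) were chosen to exercise every stage at
  desk-simulation scale.

## Known limitations

* Gait-event definitions are stand-ins; absolute values of swing/stance
  fractions and foot angles will differ from systems implementing the
  original published detectors.
* The yaw projection under-measures TA if the sensor tilts strongly during
  turning.
* The generator's impairment model is deliberately simple (three effect
  sizes); it cannot probe which cluster is *most* informative the way a real
  cohort can, only that the machinery detects injected effects and stays at
  chance under the null.
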