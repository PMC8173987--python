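# Methods

## Problem and signal model

Foot-worn IMUs record six channels (3-axis accelerometer, m/s²; 3-axis
gyroscope, deg/s) per foot, nominally at 102.4 Hz, expressed in a shared
body frame (medial-lateral, posterior-anterior, superior-inferior). The
segmentation signal is gyr_ml, the angular velocity in the sagittal plane.
A stride is the interval between two consecutive negative gyr_ml peaks:
the peak just before the swing phase (stride begin) and the peak right
after the stance phase (stride end). Borders are *samples*, not
boundaries between samples; consecutive strides may share exactly one
border sample. All intervals in the package are 0-based with inclusive
endpoints.

## Preprocessing

- Body-frame transform: an orthonormal mounting rotation per sensor; for
  the right foot the ml axes are sign-flipped after rotation so the
  negative-peak convention holds on both feet and one segmentation
  pipeline serves both. The mirroring convention is an inference — mounting
  rotations are device-specific inputs here.
- Gravity alignment: the stillest 0.5 s window with mean gyro norm below
  5 deg/s serves as the static frame; the shortest-arc rotation maps its
  mean acceleration vector onto (0, 0, +9.81) m/s². The 5 deg/s threshold
  and window length are package choices; absence of a static frame is an
  explicit error so callers can skip alignment.
- Filtering: 4th-order Butterworth low-pass at 10 Hz, applied
  forward-backward (zero phase, squared magnitude response). Decimation
  keeps every second sample (102.4 → 51.2 Hz); the 10 Hz low-pass is the
  de-facto anti-alias filter since the new Nyquist is 25.6 Hz. All
  segmentation runs at 51.2 Hz, where ±60 ms equals ±3 samples.
- Border snapping: a border index is moved to the gyr_ml minimum within a
  centered 200 ms window (truncated at signal bounds, ties toward the
  smaller index). The window is re-centered on the found minimum until
  stable, which makes snapping idempotent; on actual stride borders (deep
  negative peaks) the first step is already stable.
- Activity windows: maximal runs where a 1 s moving average of the gyro
  norm exceeds a threshold, merged across sub-1 s gaps. Smoothing and
  merge spans are package choices; the threshold is a required argument
  because no universal value exists.

## Features

Per-sample sliding windows (shift one sample; length `round(window_ms *
fs/1000)` forced odd for exact centering; clipped, never padded, at
signal bounds — padding would invent data exactly where transitions
live). Features: the raw sample; the least-squares line slope over the
window in per-second units (`grad`); the population variance (`var`); and
the three coefficients of a second-order polynomial fit (`polyfit`,
ordered quadratic/linear/constant) on a window-centered time axis in
seconds, so the constant coefficient is the smoothed signal value.
Features are z-scored per feature column within each walking bout;
near-constant columns are zeroed as a guard. Samples outside bouts are
never decoded and stay untouched.

## The two-class HMM

**Stride model** (n states, default 25): strict left-right chain,
self-loop and forward edge per state, sequence forced to start in the
first and end in the last state (start/end distributions are deltas).
**Transition model** (m states, default 5): left-right chain with a wrap
edge from last to first state; uniform start/end over all states. Both
use diagonal-covariance GMM emissions (default 8 components; variance
floor 1e-6). Defaults follow the hyperparameters that a nested
cross-validated grid search selects for free-living gait (25/5 states, 8
components, 220 ms windows, raw + gradient features); the synthetic
experiments here use the smaller 10/3/1 configuration, which is already
sufficient on generated data.

Initialization splits every training sequence into `n` contiguous,
equal-as-possible segments; state *i*'s mixture is initialized from the
pooled *i*-th segments (k-means++ partitioning for multi-component
mixtures, seeded). Allowed transition-row edges start uniform (0.5/0.5).

Baum-Welch runs in log space with batched forward-backward (sequences
grouped by length), re-estimating transitions and mixture parameters
while start/end distributions and structural zeros are preserved exactly
(EM with a fixed parameter subset remains monotone). Training stops at
ten iterations — sufficient in practice and a deliberate cap — or when the
relative log-likelihood improvement drops below 1e-4. Per-sample emission
log-densities are floored at −700 to avoid −inf cascades.

**Combination.** Each training segment (stride or transition) is decoded
with its own class model; decoded states are merged per bout (transition
states keep indices 0…m−1, stride states are offset by m) and all merged
state transitions are counted into the combined (n+m)² matrix. Additive
smoothing 1e-12 is applied only to structurally plausible edges (the
sub-model structures plus observed cross edges); start/end distributions
are estimated from merged-sequence endpoints with add-one smoothing (the
combined model may therefore begin mid-stride, with small probability).
Emissions are copied unchanged.

**Prediction.** Viterbi decoding (log space, ties toward the lowest state
index) over each walking-bout window. Border candidates are class changes
and the stride-model wrap. Each border snaps to the gyr_ml minimum over
the two state-occupancy runs flanking the change, with each run truncated
to 0.25 s next to the change point: an unbounded transition run would
otherwise pull bout-edge borders onto unrelated dips in the pre/post-gait
movement. Strides are assembled from consecutive border pairs bracketing
stride-class runs; an interval whose snapped borders invert is dropped.

**Training-set construction.** Bout windows are expanded by a pad
(default 1.5 s) before feature extraction, decoding and training, because
bouts span first-stride-start to last-stride-end and the movement into
and out of gait would otherwise fall outside every decoded region. Within
an expanded bout, labeled strides become stride sequences (a border
sample shared by two strides is owned by the later one so segments tile
the bout) and the remaining runs become transition sequences — at least
the leading and trailing one per bout, plus any within-bout rests.
Transition slivers shorter than the transition state count (one or two
samples between snapped borders) carry no information and are skipped.

## DTW baseline

Template: all training strides linearly resampled to the rounded mean
stride length, averaged per sample, divided by a fixed 500 deg/s
amplitude scale (the printed threshold range 2.0–5.0 presupposes
normalized amplitudes; the scale is configurable). Matching: subsequence
DTW with free start (first template row initialized with the local cost
everywhere), steps {match, insertion, deletion} without slope weighting,
squared-difference local cost. Match candidates are local minima of the
final accumulated-cost row below the threshold; starts are recovered by
traceback (diagonal preferred on ties). Overlaps are resolved greedily by
ascending cost; candidates may share up to a quarter template length so
consecutive strides with a shared border survive. Matched borders are
snapped with the 200 ms rule; degenerate intervals are dropped. Because
the cost normalization of the original tool is not transferable across
implementations, the threshold is re-tuned on training data over the
printed 2.0…5.0/0.25 grid (ties toward the smaller threshold); on clean
synthetic data every true match costs well below 2.0, so the tuner picks
the grid minimum.

## Synthetic data generator

The generator emulates the statistical structure the method assumes — it
is the test bed, not a biomechanical simulation:

- Stride waveform: quadratic negative border dips (depth 150 deg/s,
  half-width 35 ms) pinned to the first and last sample, a Gaussian
  positive swing lobe (400 deg/s around 35% of the stride), a near-zero
  stance plateau with a faint oscillation. With zero noise the border
  samples undercut every interior sample by ≥ 0.25 of the dip depth, so
  200 ms snapping is stable by construction.
- Stride duration 1.1 ± 0.08 s; additive Gaussian sensor noise (default
  5 deg/s); per-stride lognormal amplitude jitter; per-subject lognormal
  amplitude/duration offsets (10%).
- Bouts: strides concatenated sharing border samples; irregular smoothed
  low-amplitude movement (50 deg/s scale) flanks each bout; the right foot
  lags the left by half a stride; bouts are separated by 3–6 s of rest, so
  the ≥4-stride / ≤2.5 s-rest bout definition recovers exactly the
  generated bouts.
- Short-bout heterogeneity mode: bouts of ≤15 strides get doubled
  duration/amplitude jitter, mild swing-shape jitter, and a 50% fraction
  of "atypical" strides with a reduced, biphasic swing profile
  (emulating turning/shuffling steps whose morphology deviates from the
  average gait cycle while their border peaks stay prominent). This is
  the mechanism behind the bout-length trend: template matching misses
  atypical strides at any threshold in the grid, while the HMM still
  tracks their border-swing-stance sequence.
- All randomness flows through one `numpy.random.Generator` seeded from
  the config; identical config + seed reproduces datasets bit for bit.

What the generator does **not** model: realistic accelerometry beyond
gravity plus noise, freezing of gait, turning-in-place, sensor drift or
calibration error, or genuinely non-stationary free-living context.
Passing the synthetic experiments therefore demonstrates correctness of
the algorithms and the direction of the method contrast, not clinical
performance.

## Evaluation framework

Greedy one-to-one matching in start order (each reference takes the first
unused compatible prediction) under the ±3-sample tolerance on both
borders; a brute-force maximum-bipartite-matching cross-check runs in the
test suite, where greedy attains the maximum on all sampled instances —
with a ±3-sample tolerance and ≥40-sample strides, ambiguous multi-matches
are essentially impossible by construction. Undefined ratios are reported
as 0 with a degenerate flag so pooled tables never propagate NaNs. Counts
are pooled (micro-averaged) before ratios, per split and per bout-length
bin; the bins are 4–15, 15–30, 30–50, 50–100, 100–200 and >200 strides
per bout (both feet). Subject-level k-fold splitting keeps train and test
subjects disjoint; grid search enumerates configurations in fixed
lexicographic order (deterministic tie-break) and records untrainable
configurations as failed instead of crashing.

## Problem sizes used in the experiments

The recovery experiment uses 8 synthetic subjects (5 train / 3 test), six
bouts each covering all six length bins (6–220 strides, ≈1500 test
strides); the trend experiment uses 8 subjects with eight bouts each,
over-sampling short bouts (three per subject in the 4–15 bin) so the
short-bin estimate rests on ≈90 strides per subject group. These sizes
give stable metrics while keeping a full run in the minutes range on one
CPU.

## Known limitations

- The combined model's start/end smoothing means decoding can in
  principle open or close mid-stride; on padded bout windows this is
  harmless because windows start and end in rest.
- Greedy matching is not provably maximum for arbitrary tolerances; the
  test suite bounds the gap empirically at zero for the tolerance used.
- The DTW cost scale (500 deg/s) and the overlap allowance (quarter
  template) are conventions, configurable but not tuned.
- Gravity alignment assumes at least one 0.5 s static frame; recordings
  that never rest need the caller to skip alignment.
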