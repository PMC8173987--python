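# strideseg

Stride segmentation of foot-worn IMU gait recordings with a **two-class
hidden Markov model** and a **subsequence-DTW template-matching baseline**,
plus everything needed to exercise both methods without real sensor data: a
synthetic gait generator with exact ground-truth labels, signal
preprocessing, windowed feature extraction and a tolerance-window
evaluation framework.

## Who this is for

Researchers and engineers working on wearable gait analysis (e.g. movement
disorders such as Parkinson's disease) who need to cut continuous
foot-mounted IMU streams into individual strides before spatio-temporal
gait parameters can be computed. Free-living recordings are dominated by
short, heterogeneous walking bouts where classic template matching
degrades; the HMM approach models stride heterogeneity explicitly.

## The method

A stride is delimited by two consecutive negative peaks of the
sagittal-plane angular velocity gyr_ml (the peaks just before the swing
phase and just after the stance phase). Segmentation is a two-class
problem:

- **Stride model** — a strict left-right Markov chain `s_0 … s_{n-1}`
  (self-loops `p_{i,i}` and forward edges `p_{i,i+1}` only), forced to
  start in `s_0` and end in `s_{n-1}`; each state carries a
  diagonal-covariance Gaussian-mixture (GMM) emission over windowed
  features of gyr_ml.
- **Transition model** — a left-right chain over `m` states extended by a
  wrap edge from the last to the first state; sequences may start and end
  in any state. It absorbs all within-bout movement that is not a labeled
  stride.

Both sub-models are initialized by naively splitting each training
sequence into equal sections and trained unsupervised with Baum-Welch
(capped at ten iterations). They are then flattened into one combined
`(n+m)`-state model: each training segment is decoded with its own class
model, the decoded state sequences are merged per walking bout, and all
observed state transitions are counted to estimate the combined transition
matrix (emissions are copied unchanged). At prediction time the combined
model is decoded with Viterbi; any change between transition- and
stride-class states, plus the stride-model wrap `s_{n-1} -> s_0`, marks a
stride border, which is snapped to the local gyr_ml minimum.

The baseline builds a stride template by linearly resampling all training
strides to their mean length and averaging per sample, then matches it
anywhere in the signal with subsequence dynamic time warping under a
maximum warping-cost threshold (grid-searched over 2.0…5.0 in steps of
0.25).

Evaluation matches predicted to reference strides one-to-one; a stride
counts as a true positive only if **both** borders fall within ±60 ms
(±3 samples at the working rate of 51.2 Hz) of the reference, summarized
as precision, recall and F1 (harmonic mean). Walking bouts are runs of at
least four strides (both feet combined) with no internal rest longer than
2.5 s.

## Worked example

```python
import strideseg as ss

# synthetic cohort: 4 subjects, 3 walking bouts each, labeled ground truth
config = ss.SyntheticGaitConfig(seed=7, noise_sd_dps=5.0)
dataset = ss.generate_dataset(n_subjects=4, bouts_per_subject=3,
                              bout_length_sampler=ss.bin_spanning_sampler((8, 20, 40)),
                              config=config)

# 10 Hz zero-phase low-pass, decimate 102.4 -> 51.2 Hz, re-index labels
working = [ss.decimate_labeled_recording(rec) for rec in dataset]
train, test = working[:3], working[3:]

hmm = ss.HmmStrideSegmenter(n_stride_states=10, n_transition_states=3,
                            n_components=1, seed=7).fit(train)
m = ss.evaluate_split(hmm, test)
print(f"HMM  TP={m.tp} FP={m.fp} FN={m.fn} precision={m.precision:.3f} "
      f"recall={m.recall:.3f} F1={m.f1:.3f}")

dtw = ss.DtwStrideSegmenter(seed=7).fit(train)   # tunes max cost on train
m = ss.evaluate_split(dtw, test)
print(f"DTW  TP={m.tp} FP={m.fp} FN={m.fn} F1={m.f1:.3f}")
```

prints

```
HMM  TP=62 FP=6 FN=6 precision=0.912 recall=0.912 F1=0.912
DTW  TP=68 FP=0 FN=0 F1=1.000
```

i.e. on this small clean cohort the HMM recovers 62 of 68 held-out strides
with both borders within ±60 ms, and template matching is essentially
perfect — clean, homogeneous gait is DTW's best case. The picture inverts
on heterogeneous short bouts (see the bout-length experiment run by the
acceptance script).

A CLI mirrors the library:
`strideseg simulate | preprocess | train | segment | dtw-template |
segment-dtw | evaluate`.

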