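"""Scikit-learn-style segmenter estimators.

:class:`HmmStrideSegmenter` is the proposed method: per walking bout,
labeled strides become stride training sequences and the remaining
within-bout samples become transition sequences; the two left-right
sub-models are trained with Baum-Welch (ten-iteration cap) and flattened
into one combined model that is decoded with Viterbi at prediction time.
:class:`DtwStrideSegmenter` is the reference method: an averaged stride
template matched with subsequence DTW under a maximum warping-cost
threshold (tuned on the training data when not fixed).

Both estimators fit on lists of :class:`~strideseg.containers.LabeledRecording`
at the working sampling rate and predict per-foot stride-interval lists.
Decoding happens inside walking-bout windows expanded by a small pad so the
movement into and out of gait is part of the decoded region.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import dtw as _dtw
from . import hmm as _hmm
from .containers import Interval, LabeledRecording
from .evaluation import match_strides
from .features import FeatureConfig, FeatureSequence, sliding_window_features, \
    zscore_per_bout
from .preprocessing import snap_to_minimum


def expand_bout(bout: Interval, n_samples: int, fs: float,
                pad_s: float = 1.5) -> Interval:
    """Widen a bout interval by ``pad_s`` on each side, clipped to the signal."""
    pad = int(round(pad_s * fs))
    return max(0, bout[0] - pad), min(n_samples - 1, bout[1] + pad)


def _bout_features(sig: np.ndarray, region: Interval, fs: float,
                   config: FeatureConfig) -> FeatureSequence:
    rs, re = region
    feats = sliding_window_features(sig[rs:re + 1], fs, config)
    if config.standardize:
        feats = zscore_per_bout(feats, [(0, re - rs)])
    feats.source_bout = region
    return feats


def _segment_bout(feats: FeatureSequence, strides: Sequence[Interval],
                  region: Interval) -> List[Tuple[str, FeatureSequence, Interval]]:
    """Tile a bout region into stride/transition segments.

    A border sample shared by two consecutive strides is owned by the later
    stride, so segments tile the region contiguously.
    """
    rs, re = region
    n = re - rs + 1
    label = np.full(n, -1, dtype=int)
    for k, (s, e) in enumerate(strides):
        label[s - rs:e - rs + 1] = k
    segments = []
    start = 0
    for t in range(1, n + 1):
        if t == n or label[t] != label[start]:
            cls = "transition" if label[start] < 0 else "stride"
            sub = FeatureSequence(values=feats.values[start:t],
                                  feature_names=list(feats.feature_names),
                                  fs=feats.fs)
            segments.append((cls, sub, (rs + start, rs + t - 1)))
            start = t
    return segments


def _repair(intervals: List[Interval]) -> List[Interval]:
    intervals = sorted(intervals)
    out: List[Interval] = []
    for s, e in intervals:
        if out and s < out[-1][1]:
            s = out[-1][1]
        if e > s:
            out.append((s, e))
    return out


class HmmStrideSegmenter(BaseEstimator):
    """Two-class HMM stride segmenter with GMM emissions.

    Parameters
    ----------
    n_stride_states, n_transition_states : int
        States of the stride and transition sub-models (the combined model
        has their sum, transition states first).
    n_components : int
        Gaussian mixture components per state.
    window_ms : float
        Sliding feature window length.
    feature_set : tuple of str
        Any of ``raw``, ``grad``, ``var``, ``polyfit``.
    standardize : bool
        Per-bout z-scoring of each feature column.
    max_iter : int
        Baum-Welch iteration cap (ten, following the training protocol).
    bout_pad_s : float
        Padding added around each walking bout before feature extraction and
        decoding, so transitions into/out of gait are observable.
    seed : int
        Seeds mixture initialization; training itself is deterministic.
    """

    def __init__(self, n_stride_states: int = 25, n_transition_states: int = 5,
                 n_components: int = 8, window_ms: float = 220.0,
                 feature_set: Tuple[str, ...] = ("raw", "grad"),
                 standardize: bool = True, max_iter: int = 10, tol: float = 1e-4,
                 bout_pad_s: float = 1.5, snap_window_ms: float = 200.0,
                 seed: int = 0):
        self.n_stride_states = n_stride_states
        self.n_transition_states = n_transition_states
        self.n_components = n_components
        self.window_ms = window_ms
        self.feature_set = feature_set
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.bout_pad_s = bout_pad_s
        self.snap_window_ms = snap_window_ms
        self.seed = seed

    def _feature_config(self) -> FeatureConfig:
        return FeatureConfig(window_ms=self.window_ms,
                             feature_set=tuple(self.feature_set),
                             standardize=self.standardize)

    def fit(self, X: Sequence[LabeledRecording], y=None) -> "HmmStrideSegmenter":
        if not len(X):
            raise ValueError("training set must contain at least one recording")
        config = self._feature_config()
        stride_seqs: List[np.ndarray] = []
        transition_seqs: List[np.ndarray] = []
        bouts: List[List[Tuple[str, FeatureSequence]]] = []

        for rec in X:
            fs = rec.sampling_rate_hz
            n = len(rec)
            for foot, r in rec.recordings.items():
                sig = r.gyr_ml
                foot_strides = rec.strides_per_foot.get(foot, [])
                for bout in rec.bouts:
                    region = expand_bout(bout, n, fs, self.bout_pad_s)
                    inside = [iv for iv in foot_strides
                              if bout[0] <= iv[0] and iv[1] <= bout[1]]
                    if not inside:
                        continue
                    feats = _bout_features(sig, region, fs, config)
                    segments = _segment_bout(feats, inside, region)
                    kept: List[Tuple[str, FeatureSequence]] = []
                    for cls, sub, _ in segments:
                        if cls == "stride":
                            if len(sub) < self.n_stride_states:
                                raise ValueError(
                                    f"stride segment of {len(sub)} samples in "
                                    f"{rec.subject_id}/{foot} is shorter than "
                                    f"n_stride_states={self.n_stride_states}")
                            stride_seqs.append(sub.values)
                            kept.append((cls, sub))
                        else:
                            # sliver gaps between snapped borders carry no
                            # transition information; absorb them by skipping
                            if len(sub) >= self.n_transition_states:
                                transition_seqs.append(sub.values)
                                kept.append((cls, sub))
                    bouts.append(kept)

        if not stride_seqs:
            raise ValueError("no labeled strides in the training set")
        if not transition_seqs:
            raise ValueError("no transition segments in the training set")

        stride_init = _hmm.init_left_right_model(
            stride_seqs, self.n_stride_states, self.n_components,
            wrap_edge=False, free_ends=False, seed=self.seed)
        transition_init = _hmm.init_left_right_model(
            transition_seqs, self.n_transition_states, self.n_components,
            wrap_edge=True, free_ends=True, seed=self.seed + 1)

        self.stride_model_, self.stride_report_ = _hmm.baum_welch(
            stride_init, stride_seqs, max_iter=self.max_iter, tol=self.tol)
        self.transition_model_, self.transition_report_ = _hmm.baum_welch(
            transition_init, transition_seqs, max_iter=self.max_iter, tol=self.tol)

        self.model_ = _hmm.combine_models(self.transition_model_,
                                          self.stride_model_, bouts)
        self.n_stride_sequences_ = len(stride_seqs)
        self.n_transition_sequences_ = len(transition_seqs)
        return self

    def predict(self, rec: LabeledRecording) -> Dict[str, List[Interval]]:
        """Per-foot snapped stride intervals inside the recording's bouts."""
        if not hasattr(self, "model_"):
            raise RuntimeError("segmenter is not fitted")
        config = self._feature_config()
        out: Dict[str, List[Interval]] = {}
        fs = rec.sampling_rate_hz
        n = len(rec)
        for foot, r in rec.recordings.items():
            sig = r.gyr_ml
            found: List[Interval] = []
            for bout in rec.bouts:
                region = expand_bout(bout, n, fs, self.bout_pad_s)
                feats = _bout_features(sig, region, fs, config)
                strides, _ = _hmm.predict_strides(
                    self.model_, feats, sig[region[0]:region[1] + 1], fs,
                    offset=region[0])
                found.extend(strides)
            out[foot] = _repair(found)
        return out


class DtwStrideSegmenter(BaseEstimator):
    """Template-matching segmenter via subsequence DTW.

    When ``max_cost`` is None, the threshold is grid-searched on the
    training recordings (maximizing pooled F1; ties resolve toward the
    smaller threshold).
    """

    def __init__(self, max_cost: Optional[float] = None,
                 grid: Tuple[float, ...] = _dtw.DtwConfig().grid,
                 scale_dps: float = _dtw.DEFAULT_SCALE_DPS,
                 bout_pad_s: float = 1.5, snap_window_ms: float = 200.0,
                 tol_samples: int = 3, seed: int = 0):
        self.max_cost = max_cost
        self.grid = grid
        self.scale_dps = scale_dps
        self.bout_pad_s = bout_pad_s
        self.snap_window_ms = snap_window_ms
        self.tol_samples = tol_samples
        self.seed = seed

    def fit(self, X: Sequence[LabeledRecording], y=None) -> "DtwStrideSegmenter":
        if not len(X):
            raise ValueError("training set must contain at least one recording")
        strides = []
        for rec in X:
            for foot, r in rec.recordings.items():
                sig = r.gyr_ml
                for s, e in rec.strides_per_foot.get(foot, []):
                    strides.append(sig[s:e + 1])
        if not strides:
            raise ValueError("no labeled strides in the training set")
        self.template_ = _dtw.build_template(strides, self.scale_dps)

        if self.max_cost is not None:
            self.max_cost_ = float(self.max_cost)
        else:
            self.max_cost_ = self._tune_threshold(X)
        return self

    def _tune_threshold(self, X: Sequence[LabeledRecording]) -> float:
        max_overlap = max(1, self.template_.length // 4)
        totals = {c: [0, 0, 0] for c in self.grid}
        for rec in X:
            fs = rec.sampling_rate_hz
            n = len(rec)
            for foot, r in rec.recordings.items():
                sig = r.gyr_ml
                ref = rec.strides_per_foot.get(foot, [])
                matrices = []
                for bout in rec.bouts:
                    region = expand_bout(bout, n, fs, self.bout_pad_s)
                    seg = sig[region[0]:region[1] + 1]
                    if len(seg) < self.template_.length / 2:
                        continue
                    D = _dtw.accumulated_cost_matrix(self.template_, seg)
                    matrices.append((region, D))
                for cost in self.grid:
                    found: List[Interval] = []
                    for region, D in matrices:
                        for m in _dtw.matches_from_matrix(D, cost, max_overlap):
                            a = snap_to_minimum(sig, region[0] + m.start_sample,
                                                self.snap_window_ms, fs)
                            b = snap_to_minimum(sig, region[0] + m.end_sample,
                                                self.snap_window_ms, fs)
                            if b > a:
                                found.append((a, b))
                    tp, fp, fn, _ = match_strides(_repair(found), ref,
                                                  self.tol_samples)
                    totals[cost][0] += tp
                    totals[cost][1] += fp
                    totals[cost][2] += fn
        best_cost, best_f1 = None, -1.0
        for cost in self.grid:
            tp, fp, fn = totals[cost]
            f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
            if f1 > best_f1:
                best_cost, best_f1 = float(cost), f1
        return best_cost

    def predict(self, rec: LabeledRecording) -> Dict[str, List[Interval]]:
        if not hasattr(self, "template_"):
            raise RuntimeError("segmenter is not fitted")
        config = _dtw.DtwConfig(max_cost=self.max_cost_, grid=tuple(self.grid))
        out: Dict[str, List[Interval]] = {}
        fs = rec.sampling_rate_hz
        n = len(rec)
        for foot, r in rec.recordings.items():
            regions = [expand_bout(b, n, fs, self.bout_pad_s) for b in rec.bouts]
            out[foot] = _dtw.dtw_predict_strides(
                self.template_, r, config, self.snap_window_ms, regions)
        return out


def fit_segmenter(recordings: Sequence[LabeledRecording], hyperparams: dict,
                  seed: int = 0):
    """Functional wrapper: fit the HMM segmenter and return the combined model."""
    seg = HmmStrideSegmenter(**hyperparams, seed=seed).fit(recordings)
    return seg.model_
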