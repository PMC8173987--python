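"""Walking-bout definition, tolerance-window stride matching and the
cross-validation / grid-search harness.

A predicted stride counts as a true positive only if *both* of its borders
fall within a centered tolerance window (±60 ms, i.e. ±3 samples at
51.2 Hz) of the matched reference stride's borders. A walking bout is a run
of at least four strides (both feet combined, merged on one timeline) with
no internal rest gap longer than 2.5 s.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]

#: stride-count bin edges: (4..15], (15..30], (30..50], (50..100], (100..200], >200
BOUT_LENGTH_BIN_EDGES = (15, 30, 50, 100, 200)
BOUT_LENGTH_BIN_LABELS = ("4<=N<=15", "15<N<=30", "30<N<=50", "50<N<=100",
                          "100<N<=200", "N>200")


@dataclass
class MatchMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


def define_walking_bouts(strides_both_feet: Dict[str, Sequence[Interval]],
                         fs: float, min_strides: int = 4,
                         max_rest_s: float = 2.5) -> List[Interval]:
    """Merge both feet's strides on one timeline and segment into bouts.

    A new bout begins whenever the gap between one stride's end and the next
    stride's start exceeds ``max_rest_s`` (a gap exactly equal is kept
    together); candidate bouts with fewer than ``min_strides`` strides (both
    feet combined) are discarded. Each bout spans the first stride start to
    the last stride end.
    """
    merged: List[Interval] = []
    for foot, ivs in strides_both_feet.items():
        prev = None
        for s, e in ivs:
            if prev is not None and s < prev:
                raise ValueError(f"stride list for {foot!r} is not sorted by start")
            prev = s
            merged.append((int(s), int(e)))
    merged.sort()
    if not merged:
        return []
    max_gap = max_rest_s * fs
    bouts: List[Interval] = []
    group: List[Interval] = [merged[0]]
    for iv in merged[1:]:
        if iv[0] - group[-1][1] > max_gap:
            if len(group) >= min_strides:
                bouts.append((group[0][0], max(e for _, e in group)))
            group = [iv]
        else:
            group.append(iv)
    if len(group) >= min_strides:
        bouts.append((group[0][0], max(e for _, e in group)))
    return bouts


def match_strides(predicted: Sequence[Interval], reference: Sequence[Interval],
                  tol_samples: int = 3,
                  ) -> Tuple[int, int, int, List[Tuple[int, int]]]:
    """One-to-one stride matching under a symmetric border tolerance.

    A (prediction, reference) pair is compatible iff both start and end
    offsets are within ``tol_samples``. Matching is a greedy sweep in start
    order: each reference takes the first unused compatible prediction.

    Returns ``(tp, fp, fn, matched index pairs)``.
    """
    if tol_samples < 0:
        raise ValueError("tol_samples must be >= 0")
    pred = sorted(range(len(predicted)), key=lambda i: predicted[i])
    ref = sorted(range(len(reference)), key=lambda i: reference[i])
    used = [False] * len(predicted)
    pairs: List[Tuple[int, int]] = []
    for r in ref:
        rs, re = reference[r]
        for p in pred:
            if used[p]:
                continue
            ps, pe = predicted[p]
            if ps > rs + tol_samples:
                break
            if abs(ps - rs) <= tol_samples and abs(pe - re) <= tol_samples:
                used[p] = True
                pairs.append((p, r))
                break
    tp = len(pairs)
    return tp, len(predicted) - tp, len(reference) - tp, pairs


def compute_metrics(tp: int, fp: int, fn: int) -> MatchMetrics:
    """Precision, recall and their harmonic mean (F1) from raw counts.

    Undefined ratios (zero denominators) are reported as 0 with the
    degenerate flag set, so pooled tables never propagate non-numbers.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MatchMetrics(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                        f1=f1, degenerate=degenerate)


def bout_length_bin(n_strides: int) -> str:
    for edge, label in zip(BOUT_LENGTH_BIN_EDGES, BOUT_LENGTH_BIN_LABELS):
        if n_strides <= edge:
            return label
    return BOUT_LENGTH_BIN_LABELS[-1]


def group_metrics_by_bout_length(
        per_bout_results: Iterable[Tuple[int, int, int, int]],
        ) -> Dict[str, MatchMetrics]:
    """Pool (stride count, tp, fp, fn) rows into stride-count bins.

    Counts are micro-averaged (pooled before computing ratios); empty bins
    are omitted. Bins follow the 4-15 / 15-30 / 30-50 / 50-100 / 100-200 /
    >200 stride grouping.
    """
    pooled: Dict[str, List[int]] = {}
    for n_strides, tp, fp, fn in per_bout_results:
        label = bout_length_bin(n_strides)
        acc = pooled.setdefault(label, [0, 0, 0])
        acc[0] += tp
        acc[1] += fp
        acc[2] += fn
    return {label: compute_metrics(*pooled[label])
            for label in BOUT_LENGTH_BIN_LABELS if label in pooled}


@dataclass
class CvFolds:
    """Disjoint train/test subject splits, optionally with inner folds."""

    folds: List[Tuple[List[str], List[str]]]  # (train_ids, test_ids)
    inner: List[List[Tuple[List[str], List[str]]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("a subject appears in both train and test")


def make_subject_folds(subject_ids: Sequence[str], k: int = 4, seed: int = 0,
                       inner_k: int = 0) -> CvFolds:
    """Shuffle subjects with ``seed`` and split into k near-equal test groups."""
    ids = list(subject_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    groups = [list(g) for g in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    inner = []
    for gi, test in enumerate(groups):
        train = [s for gj, g in enumerate(groups) for s in g if gj != gi]
        folds.append((train, [str(s) for s in test]))
        if inner_k:
            inner.append(make_subject_folds(train, inner_k, seed + 1 + gi).folds)
    return CvFolds(folds=folds, inner=inner)


def evaluate_split(segmenter, recordings, tol_samples: int = 3) -> MatchMetrics:
    """Pooled metrics of a fitted segmenter over a list of labeled recordings."""
    tp = fp = fn = 0
    for rec in recordings:
        predicted = segmenter.predict(rec)
        for foot, ref in rec.strides_per_foot.items():
            t, f, n, _ = match_strides(predicted.get(foot, []), ref, tol_samples)
            tp += t
            fp += f
            fn += n
    return compute_metrics(tp, fp, fn)


def evaluate_per_bout(segmenter, recordings, tol_samples: int = 3,
                      ) -> List[Tuple[int, int, int, int]]:
    """Per-bout (stride count, tp, fp, fn) rows for bout-length grouping.

    The bout stride count pools both feet (the bout definition's
    convention); predictions are assigned to the bout whose interval
    contains them, within the border tolerance at the bout edges.
    """
    rows: List[Tuple[int, int, int, int]] = []
    for rec in recordings:
        predicted = segmenter.predict(rec)
        for bs, be in rec.bouts:
            n_strides = sum(1 for ivs in rec.strides_per_foot.values()
                            for s, e in ivs if bs <= s and e <= be)
            tp = fp = fn = 0
            for foot, ref in rec.strides_per_foot.items():
                r_in = [iv for iv in ref if bs <= iv[0] and iv[1] <= be]
                p_in = [iv for iv in predicted.get(foot, [])
                        if bs - tol_samples <= iv[0] and iv[1] <= be + tol_samples]
                t, f, n, _ = match_strides(p_in, r_in, tol_samples)
                tp, fp, fn = tp + t, fp + f, fn + n
            rows.append((n_strides, tp, fp, fn))
    return rows


def grid_search(grid: Dict[str, Sequence], folds: CvFolds, data: Sequence,
                seed: int = 0, segmenter_factory=None,
                tol_samples: int = 3):
    """Exhaustive hyperparameter search maximizing mean pooled F1 over folds.

    ``grid`` maps estimator parameter names to candidate values; candidates
    are enumerated in fixed lexicographic grid order, so ties resolve toward
    the first configuration. Configurations that fail to train are recorded
    with ``f1 = nan`` and excluded from the ranking. Returns ``(best params,
    table)`` where the table is a pandas DataFrame with one row per
    configuration.
    """
    import pandas as pd
    from .estimators import HmmStrideSegmenter

    if not grid or not len(data):
        raise ValueError("grid and data must be non-empty")
    factory = segmenter_factory or (lambda **kw: HmmStrideSegmenter(**kw))
    by_subject = {rec.subject_id: rec for rec in data}
    names = list(grid.keys())
    rows = []
    best = None
    best_f1 = -np.inf
    for combo in itertools.product(*(grid[n] for n in names)):
        params = dict(zip(names, combo))
        fold_f1 = []
        failed = False
        for train_ids, test_ids in folds.folds:
            try:
                seg = factory(**params, seed=seed)
                seg.fit([by_subject[s] for s in train_ids if s in by_subject])
                metrics = evaluate_split(
                    seg, [by_subject[s] for s in test_ids if s in by_subject],
                    tol_samples)
                fold_f1.append(metrics.f1)
            except (ValueError, RuntimeError):
                failed = True
                break
        mean_f1 = float("nan") if failed else float(np.mean(fold_f1))
        rows.append({**{k: (v if np.isscalar(v) else str(v))
                        for k, v in params.items()},
                     "mean_f1": mean_f1, "failed": failed})
        if not failed and mean_f1 > best_f1:
            best_f1 = mean_f1
            best = params
    return best, pd.DataFrame(rows)
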