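"""Subsequence dynamic-time-warping stride segmentation (reference method).

A stride template is built by linearly resampling every training stride to
the mean stride length and averaging per sample. The template is then
matched anywhere inside a gyr_ml signal with subsequence DTW (free start:
the first template row is initialized with the local cost at every signal
position; steps match/insertion/deletion; squared-difference local cost on
amplitude-normalized signals). Match candidates are local minima of the
accumulated-cost final row below a maximum-cost threshold; match starts are
recovered by path traceback and overlapping candidates are resolved
greedily by ascending cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .containers import BodyFrameRecording, Interval
from .preprocessing import snap_to_minimum

#: fixed amplitude divisor (deg/s) applied to signals before matching
DEFAULT_SCALE_DPS = 500.0


@dataclass
class DtwTemplate:
    waveform: np.ndarray
    scale_dps: float = DEFAULT_SCALE_DPS

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if len(self.waveform) < 2:
            raise ValueError("template must have at least 2 samples")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("template must be finite")

    @property
    def length(self) -> int:
        return len(self.waveform)


@dataclass(frozen=True)
class DtwConfig:
    max_cost: float = 3.5
    grid: Tuple[float, ...] = tuple(np.arange(2.0, 5.0 + 1e-9, 0.25).round(2))

    def __post_init__(self) -> None:
        if self.max_cost <= 0:
            raise ValueError("max_cost must be positive")


@dataclass
class DtwMatch:
    start_sample: int
    end_sample: int
    cost: float

    def __post_init__(self) -> None:
        if self.start_sample > self.end_sample:
            raise ValueError("start must be <= end")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


def build_template(strides: Sequence[np.ndarray],
                   scale_dps: float = DEFAULT_SCALE_DPS) -> DtwTemplate:
    """Average training strides into a template.

    Each stride is linearly interpolated to the rounded mean stride length,
    the per-sample mean is taken, and the waveform is divided by the fixed
    amplitude scale.
    """
    strides = [np.asarray(s, dtype=float) for s in strides]
    if not strides:
        raise ValueError("at least one stride is required")
    for s in strides:
        if len(s) < 2:
            raise ValueError("each stride must have at least 2 samples")
    target = int(round(float(np.mean([len(s) for s in strides]))))
    target = max(target, 2)
    grid_t = np.linspace(0.0, 1.0, target)
    resampled = [np.interp(grid_t, np.linspace(0.0, 1.0, len(s)), s)
                 for s in strides]
    waveform = np.mean(resampled, axis=0) / scale_dps
    return DtwTemplate(waveform=waveform, scale_dps=scale_dps)


def _accumulated_cost_py(local: np.ndarray) -> np.ndarray:
    L, N = local.shape
    D = np.empty((L, N))
    D[0] = local[0]  # free start anywhere in the signal
    for i in range(1, L):
        prev = D[i - 1]
        cur = D[i]
        carry = np.inf
        for j in range(N):
            diag = prev[j - 1] if j > 0 else np.inf
            carry = local[i, j] + min(prev[j], diag, carry)
            cur[j] = carry
    return D


try:  # pragma: no cover - exercised implicitly when numba is present
    import numba

    _accumulated_cost_jit = numba.njit(cache=True)(_accumulated_cost_py)

    def _accumulated_cost(local: np.ndarray) -> np.ndarray:
        return _accumulated_cost_jit(local)
except Exception:  # pragma: no cover
    _accumulated_cost = _accumulated_cost_py


def accumulated_cost_matrix(template: DtwTemplate,
                            signal: np.ndarray) -> np.ndarray:
    """(L, N) subsequence DTW accumulated-cost matrix with free start.

    Local cost is the squared difference on amplitude-scaled signals; the
    first template row is initialized with the local cost at every signal
    position so a match may begin anywhere.
    """
    signal = np.asarray(signal, dtype=float) / template.scale_dps
    L = template.length
    if len(signal) < L / 2:
        raise ValueError("template longer than twice the signal")
    local = (template.waveform[:, None] - signal[None, :]) ** 2
    return _accumulated_cost(local)


def _traceback_start(D: np.ndarray, end: int) -> int:
    """Signal column where the match ending at column ``end`` begins."""
    i, j = D.shape[0] - 1, int(end)
    while i > 0:
        best_val, best_i, best_j = D[i - 1, j], i - 1, j  # vertical
        if j > 0 and D[i, j - 1] < best_val:  # horizontal
            best_val, best_i, best_j = D[i, j - 1], i, j - 1
        if j > 0 and D[i - 1, j - 1] <= best_val:  # diagonal preferred on ties
            best_val, best_i, best_j = D[i - 1, j - 1], i - 1, j - 1
        i, j = best_i, best_j
    return j


def matches_from_matrix(D: np.ndarray, max_cost: float,
                        max_overlap: int) -> List[DtwMatch]:
    """Extract non-overlapping matches below threshold from a cost matrix."""
    final = D[-1]
    n = len(final)
    if n == 0:
        return []
    if n == 1:
        cand = [0] if final[0] < max_cost else []
    else:
        le_prev = np.ones(n, dtype=bool)
        le_prev[1:] = final[1:] <= final[:-1]
        le_next = np.ones(n, dtype=bool)
        le_next[:-1] = final[:-1] <= final[1:]
        first_of_plateau = np.ones(n, dtype=bool)
        first_of_plateau[1:] = final[1:] != final[:-1]
        cand = [int(j) for j in np.flatnonzero(
            le_prev & le_next & first_of_plateau & (final < max_cost))]

    raw = [DtwMatch(start_sample=_traceback_start(D, j), end_sample=j,
                    cost=float(final[j])) for j in cand]

    raw.sort(key=lambda m: (m.cost, m.start_sample))
    accepted: List[DtwMatch] = []
    for m in raw:
        ok = all(min(m.end_sample, a.end_sample)
                 - max(m.start_sample, a.start_sample) + 1 <= max_overlap
                 for a in accepted)
        if ok:
            accepted.append(m)
    accepted.sort(key=lambda m: m.start_sample)
    return accepted


def subsequence_dtw(template: DtwTemplate, signal: np.ndarray,
                    max_cost: float) -> List[DtwMatch]:
    """All non-overlapping template matches with accumulated cost < max_cost.

    Overlap resolution keeps the lower-cost match (greedy by ascending
    cost); matches may share up to a quarter template length of samples so
    consecutive strides with a shared border survive.
    """
    D = accumulated_cost_matrix(template, signal)
    return matches_from_matrix(D, max_cost, max(1, template.length // 4))


def dtw_predict_strides(template: DtwTemplate, recording: BodyFrameRecording,
                        config: DtwConfig,
                        snap_window_ms: float = 200.0,
                        regions: Sequence[Interval] | None = None,
                        ) -> List[Interval]:
    """Match the template over gyr_ml and convert matches into snapped strides.

    ``regions`` optionally restricts matching to windows of the recording
    (e.g. walking bouts); borders are snapped with the 200 ms minimum rule
    and degenerate strides (end <= start after snapping) are dropped.
    """
    sig = recording.gyr_ml
    fs = recording.sampling_rate_hz
    if regions is None:
        regions = [(0, len(sig) - 1)] if len(sig) else []
    strides: List[Interval] = []
    for rs, re_ in regions:
        seg = sig[rs:re_ + 1]
        if len(seg) < template.length / 2:
            continue
        for m in subsequence_dtw(template, seg, config.max_cost):
            a = rs + m.start_sample
            b = rs + m.end_sample
            a = snap_to_minimum(sig, a, snap_window_ms, fs)
            b = snap_to_minimum(sig, b, snap_window_ms, fs)
            if b > a:
                strides.append((a, b))
    strides.sort()
    # drop duplicates produced by snapping adjacent matches to the same minima
    out: List[Interval] = []
    for s, e in strides:
        if out and s < out[-1][1]:
            s = max(s, out[-1][1])
        if e > s:
            out.append((s, e))
    return out
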