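"""Sliding-window feature extraction for the gyr_ml signal.

One feature row is produced per input sample (windows shift by one sample).
Available features: the raw sample, the least-squares slope of a linear fit
over the window (``grad``, per-second units), the population variance
(``var``) and the three coefficients of a second-order polynomial fit
(``polyfit``, ordered quadratic/linear/constant on a window-centered time
axis in seconds, so the constant coefficient is the smoothed value at the
sample).

Windows are forced to odd length for exact centering and clipped (never
padded) at the signal bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

VALID_FEATURES = ("raw", "grad", "var", "polyfit")


@dataclass(frozen=True)
class FeatureConfig:
    window_ms: float = 220.0
    feature_set: Tuple[str, ...] = ("raw", "grad")
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if not self.feature_set:
            raise ValueError("feature_set must be non-empty")
        object.__setattr__(self, "feature_set", tuple(self.feature_set))
        for f in self.feature_set:
            if f not in VALID_FEATURES:
                raise ValueError(f"unknown feature {f!r}; valid: {VALID_FEATURES}")

    @property
    def feature_names(self) -> List[str]:
        names: List[str] = []
        for f in self.feature_set:
            if f == "polyfit":
                names += ["poly2", "poly1", "poly0"]
            else:
                names.append(f)
        return names


@dataclass
class FeatureSequence:
    values: np.ndarray
    feature_names: List[str]
    fs: float
    source_bout: Tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples x n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _window_length(window_ms: float, fs: float) -> int:
    w = int(round(window_ms * fs / 1000.0))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def sliding_window_features(signal: np.ndarray, fs: float,
                            config: FeatureConfig) -> FeatureSequence:
    """Compute per-sample windowed features of a gyr_ml signal."""
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("signal must have at least 3 samples")
    w = min(_window_length(config.window_ms, fs), n if n % 2 == 1 else n - 1)
    half = w // 2

    cols: List[np.ndarray] = []
    need_grad = "grad" in config.feature_set
    need_var = "var" in config.feature_set
    need_poly = "polyfit" in config.feature_set

    grad = np.empty(n) if need_grad else None
    var = np.empty(n) if need_var else None
    poly = np.empty((n, 3)) if need_poly else None

    if need_grad or need_var or need_poly:
        # interior: full centered windows, vectorized
        win = np.lib.stride_tricks.sliding_window_view(x, w)  # (n-w+1, w)
        t = (np.arange(w) - half) / fs  # seconds, centered
        interior = slice(half, n - half)
        if need_grad:
            grad[interior] = win @ t / np.dot(t, t)
        if need_var:
            var[interior] = win.var(axis=1)
        if need_poly:
            design = np.column_stack([t ** 2, t, np.ones(w)])
            pinv = np.linalg.pinv(design)  # (3, w)
            poly[interior] = win @ pinv.T
        # edges: clipped windows, kept centered on the sample (t=0 at sample)
        edge_idx = list(range(half)) + list(range(n - half, n))
        for i in edge_idx:
            lo, hi = max(0, i - half), min(n, i + half + 1)
            seg = x[lo:hi]
            tt = (np.arange(lo, hi) - i) / fs
            if need_grad:
                tc = tt - tt.mean()
                denom = np.dot(tc, tc)
                grad[i] = np.dot(tc, seg) / denom if denom > 0 else 0.0
            if need_var:
                var[i] = seg.var()
            if need_poly:
                if len(seg) >= 3:
                    d = np.column_stack([tt ** 2, tt, np.ones(len(tt))])
                    poly[i] = np.linalg.lstsq(d, seg, rcond=None)[0]
                else:
                    poly[i] = (0.0, 0.0, float(seg.mean()))

    for f in config.feature_set:
        if f == "raw":
            cols.append(x)
        elif f == "grad":
            cols.append(grad)
        elif f == "var":
            cols.append(var)
        elif f == "polyfit":
            cols.append(poly)

    values = np.column_stack(cols)
    return FeatureSequence(values=values, feature_names=config.feature_names, fs=fs)


def zscore_per_bout(features: FeatureSequence,
                    bouts: Sequence[Tuple[int, int]]) -> FeatureSequence:
    """Z-score each feature column independently within each bout.

    Samples outside every bout are left untouched (they are never decoded);
    columns with near-zero spread within a bout are zeroed as a guard.
    """
    values = features.values.copy()
    n = len(values)
    for s, e in bouts:
        if not (0 <= s <= e < n):
            raise ValueError(f"bout [{s}, {e}] outside feature sequence of length {n}")
        if e <= s:
            raise ValueError(f"empty bout [{s}, {e}]")
        block = values[s:e + 1]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        degenerate = sd < 1e-12
        sd = np.where(degenerate, 1.0, sd)
        block = (block - mean) / sd
        block[:, degenerate] = 0.0
        values[s:e + 1] = block
    return FeatureSequence(values=values, feature_names=list(features.feature_names),
                           fs=features.fs, source_bout=features.source_bout)
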