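"""Signal conditioning for the segmentation pipeline.

The segmenter consumes the sagittal-plane angular velocity (gyr_ml) after a
zero-phase 10 Hz low-pass and a factor-two decimation (102.4 Hz -> 51.2 Hz).
This module also provides the utility operators used by annotation and
prediction: gravity alignment, activity-window extraction and the 200 ms
minimum-snapping rule that pins stride borders to the local gyr_ml minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import signal as sps
from scipy.spatial.transform import Rotation

from .containers import BodyFrameRecording, Interval, LabeledRecording

GRAVITY_MS2 = 9.81
#: gyro-norm mean threshold (deg/s) below which a 0.5 s window counts as static
STATIC_GYRO_THRESHOLD_DPS = 5.0
STATIC_WINDOW_S = 0.5


@dataclass(frozen=True)
class ActivityWindow:
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.start_sample > self.end_sample:
            raise ValueError("start must be <= end")


class NoStaticFrameError(RuntimeError):
    """No static window was found for gravity alignment."""


def to_body_frame(recording: BodyFrameRecording, rotation: np.ndarray,
                  foot: str) -> BodyFrameRecording:
    """Rotate a sensor-frame recording into the body frame.

    For the right foot the ml axes are sign-flipped after rotation so both
    feet share the gyr_ml polarity and a single segmentation pipeline applies
    to either side.
    """
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3) or not np.allclose(
            rotation @ rotation.T, np.eye(3), atol=1e-6):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    if abs(abs(np.linalg.det(rotation)) - 1.0) > 1e-6:
        raise ValueError("rotation must have |det| = 1")
    acc = recording.acc @ rotation.T
    gyr = recording.gyr @ rotation.T
    if foot == "right":
        acc = acc.copy()
        gyr = gyr.copy()
        acc[:, 0] *= -1.0
        gyr[:, 0] *= -1.0
    elif foot != "left":
        raise ValueError(f"foot must be 'left' or 'right', got {foot!r}")
    out = recording.with_channels(acc, gyr)
    return replace(out, foot=foot)


def _find_static_frame(recording: BodyFrameRecording) -> Tuple[int, int]:
    n = len(recording)
    w = max(1, int(round(STATIC_WINDOW_S * recording.sampling_rate_hz)))
    if n < w:
        raise NoStaticFrameError("recording shorter than the static window")
    norm = np.linalg.norm(recording.gyr, axis=1)
    means = np.convolve(norm, np.ones(w) / w, mode="valid")
    idx = int(np.argmin(means))
    if means[idx] >= STATIC_GYRO_THRESHOLD_DPS:
        raise NoStaticFrameError(
            f"no static frame: min {STATIC_WINDOW_S} s gyro-norm mean "
            f"{means[idx]:.1f} deg/s >= {STATIC_GYRO_THRESHOLD_DPS} deg/s")
    return idx, idx + w


def align_gravity(recording: BodyFrameRecording) -> BodyFrameRecording:
    """Align the accelerometer si axis to gravity using a static frame.

    Finds the stillest 0.5 s window (gyro-norm mean below threshold), then
    applies the shortest-arc rotation taking the mean static acceleration
    vector onto (0, 0, +g) to both the accelerometer and the gyroscope.
    """
    s, e = _find_static_frame(recording)
    mean_acc = recording.acc[s:e].mean(axis=0)
    norm = np.linalg.norm(mean_acc)
    if norm == 0:
        raise NoStaticFrameError("static accelerometer vector is zero")
    target = np.array([0.0, 0.0, 1.0])
    rot, _ = Rotation.align_vectors(target[None, :], (mean_acc / norm)[None, :])
    mat = rot.as_matrix()
    return recording.with_channels(recording.acc @ mat.T, recording.gyr @ mat.T)


def lowpass_zero_phase(series: np.ndarray, fs: float, cutoff_hz: float = 10.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    series = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff_hz:
        raise ValueError("fs must exceed twice the cutoff frequency")
    if len(series) < 3 * order + 1:
        raise ValueError(f"series of length {len(series)} too short for order-{order} filter")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, series)


def decimate_by_two(series: np.ndarray, fs: float) -> Tuple[np.ndarray, float]:
    """Keep every second sample starting at index 0; returns (series, fs/2).

    Assumes the 10 Hz low-pass has already been applied, which satisfies
    anti-aliasing at the new Nyquist frequency.
    """
    series = np.asarray(series)
    return series[::2], fs / 2.0


def decimate_recording(recording: BodyFrameRecording,
                       cutoff_hz: float = 10.0, order: int = 4) -> BodyFrameRecording:
    """Low-pass all six channels and decimate the recording by two."""
    fs = recording.sampling_rate_hz
    out = {}
    from .containers import CHANNELS
    for c in CHANNELS:
        x = getattr(recording, c)
        if len(x) >= 3 * order + 1:
            x = lowpass_zero_phase(x, fs, cutoff_hz, order)
        out[c] = x[::2]
    return BodyFrameRecording(sampling_rate_hz=fs / 2.0, foot=recording.foot, **out)


def detect_activity_windows(recording: BodyFrameRecording, threshold_dps: float,
                            min_duration_s: float = 1.0,
                            smooth_s: float = 1.0,
                            merge_gap_s: float = 1.0) -> List[ActivityWindow]:
    """Maximal runs where the smoothed gyro norm exceeds a threshold.

    The norm is smoothed with a centered moving average (``smooth_s``); runs
    separated by less than ``merge_gap_s`` are merged, and runs shorter than
    ``min_duration_s`` are dropped.
    """
    if threshold_dps < 0:
        raise ValueError("threshold_dps must be >= 0")
    n = len(recording)
    if n == 0:
        return []
    fs = recording.sampling_rate_hz
    norm = np.linalg.norm(recording.gyr, axis=1)
    w = max(1, int(round(smooth_s * fs)))
    kernel = np.ones(w) / w
    smoothed = np.convolve(norm, kernel, mode="same")
    active = smoothed >= threshold_dps if threshold_dps > 0 else np.ones(n, bool)
    # extract maximal runs
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = [0] if active[0] else []
    ends = []
    for e in edges:
        if active[e]:
            ends.append(e)
        else:
            starts.append(e + 1)
    if active[-1]:
        ends.append(n - 1)
    runs = list(zip(starts, ends))
    # merge runs separated by < merge_gap_s
    merged: List[List[int]] = []
    gap = merge_gap_s * fs
    for s, e in runs:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = min_duration_s * fs
    return [ActivityWindow(s, e) for s, e in merged if (e - s + 1) >= min_len]


def snap_to_minimum(gyr_ml: np.ndarray, index: int, window_ms: float = 200.0,
                    fs: float = 51.2) -> int:
    """Snap a border index to the gyr_ml minimum in a centered window.

    The window extends ``round(window_ms * fs / 1000)`` samples to each side,
    truncated at the signal bounds. Ties break toward the smallest index.
    The window is re-centered on the found minimum until stable, which makes
    the operation idempotent; on stride borders (deep negative peaks) the
    first step is already stable.
    """
    gyr_ml = np.asarray(gyr_ml)
    n = len(gyr_ml)
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range for signal of length {n}")
    half = int(round(window_ms * fs / 1000.0))
    while True:
        lo = max(0, index - half)
        hi = min(n, index + half + 1)
        new = lo + int(np.argmin(gyr_ml[lo:hi]))
        if new == index:
            return index
        # guard against cycling between equal-valued minima
        if gyr_ml[new] == gyr_ml[index] and new > index:
            return index
        index = new


def _reindex_border(i: int) -> int:
    return int(round(i / 2.0))


def decimate_labeled_recording(rec: LabeledRecording,
                               snap_window_ms: float = 200.0) -> LabeledRecording:
    """Decimate all per-foot recordings and re-index annotations to fs/2.

    Border samples are mapped with ``round(i/2)`` and then re-snapped to the
    local gyr_ml minimum so they stay on the negative peaks that define them.
    """
    recs = {foot: decimate_recording(r) for foot, r in rec.recordings.items()}
    fs = next(iter(recs.values())).sampling_rate_hz
    n = len(next(iter(recs.values())))
    strides = {}
    for foot, ivs in rec.strides_per_foot.items():
        sig = recs[foot].gyr_ml
        out: List[Interval] = []
        for s, e in ivs:
            s2 = snap_to_minimum(sig, min(_reindex_border(s), n - 1), snap_window_ms, fs)
            e2 = snap_to_minimum(sig, min(_reindex_border(e), n - 1), snap_window_ms, fs)
            if e2 > s2:
                out.append((s2, e2))
        # snapping may merge a border shared by consecutive strides; enforce order
        out = _repair_overlaps(out)
        strides[foot] = out
    from .evaluation import define_walking_bouts
    bouts = define_walking_bouts(strides, fs)
    return LabeledRecording(recordings=recs, strides_per_foot=strides,
                            bouts=bouts, subject_id=rec.subject_id)


def _repair_overlaps(intervals: List[Interval]) -> List[Interval]:
    out: List[Interval] = []
    for s, e in intervals:
        if out and s < out[-1][1]:
            s = out[-1][1]
        if e > s:
            out.append((s, e))
    return out
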