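"""Core data containers shared across the pipeline.

All stride and bout intervals are 0-based sample-index pairs ``(start, end)``
with *both* border samples inclusive: a stride ``[a, b]`` owns samples
``a..b``, and consecutive strides may share exactly one border sample.
Borders are defined as signal samples (the negative gyr_ml peaks), not as
boundaries between samples, which is why the inclusive convention is used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

#: canonical channel order of a body-frame recording
CHANNELS = ("acc_ml", "acc_pa", "acc_si", "gyr_ml", "gyr_pa", "gyr_si")

Interval = Tuple[int, int]


@dataclass
class BodyFrameRecording:
    """A six-channel IMU stream in the shared body frame.

    Axes follow the medial-lateral (ml), posterior-anterior (pa),
    superior-inferior (si) convention; accelerations in m/s^2, angular
    velocities in deg/s.
    """

    acc_ml: np.ndarray
    acc_pa: np.ndarray
    acc_si: np.ndarray
    gyr_ml: np.ndarray
    gyr_pa: np.ndarray
    gyr_si: np.ndarray
    sampling_rate_hz: float
    foot: str = "left"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {self.foot!r}")
        arrays = [np.asarray(getattr(self, c), dtype=float) for c in CHANNELS]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all channels must have equal length")
        for c, a in zip(CHANNELS, arrays):
            setattr(self, c, a)

    def __len__(self) -> int:
        return len(self.acc_ml)

    @property
    def acc(self) -> np.ndarray:
        """(n, 3) acceleration matrix in (ml, pa, si) order."""
        return np.column_stack([self.acc_ml, self.acc_pa, self.acc_si])

    @property
    def gyr(self) -> np.ndarray:
        """(n, 3) angular-velocity matrix in (ml, pa, si) order."""
        return np.column_stack([self.gyr_ml, self.gyr_pa, self.gyr_si])

    def with_channels(self, acc: np.ndarray, gyr: np.ndarray) -> "BodyFrameRecording":
        return replace(
            self,
            acc_ml=acc[:, 0], acc_pa=acc[:, 1], acc_si=acc[:, 2],
            gyr_ml=gyr[:, 0], gyr_pa=gyr[:, 1], gyr_si=gyr[:, 2],
        )

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        time_s = np.arange(n) / self.sampling_rate_hz
        data = {"time_s": time_s}
        data.update({c: getattr(self, c) for c in CHANNELS})
        return pd.DataFrame(data)


def _validate_intervals(intervals: Sequence[Interval], n_samples: int | None,
                        what: str) -> List[Interval]:
    out: List[Interval] = []
    prev_end = None
    prev_start = None
    for iv in intervals:
        s, e = int(iv[0]), int(iv[1])
        if s < 0 or s >= e:
            raise ValueError(f"{what} interval [{s}, {e}] must satisfy 0 <= start < end")
        if n_samples is not None and e >= n_samples:
            raise ValueError(f"{what} interval [{s}, {e}] exceeds recording length {n_samples}")
        if prev_start is not None and s < prev_start:
            raise ValueError(f"{what} intervals must be sorted by start")
        if prev_end is not None and s < prev_end:
            # consecutive strides may share exactly one border sample
            raise ValueError(
                f"{what} intervals [{prev_start}, {prev_end}] and [{s}, {e}] overlap "
                "beyond a shared border sample")
        prev_start, prev_end = s, e
        out.append((s, e))
    return out


@dataclass
class AnnotationDocument:
    """Stride-border and walking-bout annotations for one recording."""

    sampling_rate_hz: float
    strides: Dict[str, List[Interval]]
    bouts: List[Interval] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.strides = {
            foot: _validate_intervals(ivs, None, f"stride({foot})")
            for foot, ivs in self.strides.items()
        }
        bouts = []
        for s, e in self.bouts:
            s, e = int(s), int(e)
            if s < 0 or s >= e:
                raise ValueError(f"bout interval [{s}, {e}] must satisfy 0 <= start < end")
            bouts.append((s, e))
        self.bouts = bouts


@dataclass
class LabeledRecording:
    """Per-foot body-frame streams plus ground-truth strides and bouts.

    Both feet share one time axis and sampling rate; bouts are defined on the
    merged (both-feet) stride timeline.
    """

    recordings: Dict[str, BodyFrameRecording]
    strides_per_foot: Dict[str, List[Interval]]
    bouts: List[Interval]
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.recordings.values()}
        if len(lengths) > 1:
            raise ValueError("per-foot recordings must share one length")
        n = lengths.pop() if lengths else 0
        for foot, ivs in self.strides_per_foot.items():
            self.strides_per_foot[foot] = _validate_intervals(ivs, n, f"stride({foot})")
        self.bouts = [(int(s), int(e)) for s, e in self.bouts]
        for s, e in self.bouts:
            if s < 0 or s >= e or e >= n:
                raise ValueError(f"bout [{s}, {e}] outside recording of length {n}")
        for foot, ivs in self.strides_per_foot.items():
            for s, e in ivs:
                if not any(bs <= s and e <= be for bs, be in self.bouts):
                    raise ValueError(f"stride [{s}, {e}] ({foot}) lies in no bout")

    @property
    def sampling_rate_hz(self) -> float:
        return next(iter(self.recordings.values())).sampling_rate_hz

    def __len__(self) -> int:
        return len(next(iter(self.recordings.values())))

    def annotations(self, provenance: str = "") -> AnnotationDocument:
        return AnnotationDocument(
            sampling_rate_hz=self.sampling_rate_hz,
            strides={f: list(v) for f, v in self.strides_per_foot.items()},
            bouts=list(self.bouts),
            provenance=provenance,
        )
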