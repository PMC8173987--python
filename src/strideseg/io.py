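"""Readers/writers for the IMU CSV dialect and the annotation JSON document.

The CSV dialect is one header row ``time_s,acc_ml,acc_pa,acc_si,gyr_ml,
gyr_pa,gyr_si``, comma separated, '.' decimal point, time in seconds from
recording start, accelerations in m/s^2 and angular rates in deg/s.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .containers import CHANNELS, AnnotationDocument, BodyFrameRecording

CSV_COLUMNS: List[str] = ["time_s", *CHANNELS]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


def read_imu_csv(path, foot: str = "left") -> BodyFrameRecording:
    """Read a body-frame recording from the IMU CSV dialect.

    The sampling rate is inferred from the median time step; the time axis
    must be strictly increasing with a constant step within 1% tolerance.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols != CSV_COLUMNS:
        for got, want in zip(cols, CSV_COLUMNS):
            if got != want:
                raise FormatError(
                    f"unexpected column {got!r} where {want!r} was expected in {path}")
        raise FormatError(f"expected columns {CSV_COLUMNS}, got {cols} in {path}")
    if len(df) == 0:
        return BodyFrameRecording(*(np.empty(0) for _ in CHANNELS),
                                  sampling_rate_hz=102.4, foot=foot)
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"time_s is not strictly increasing in {path}")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise FormatError(f"sampling interval not constant within 1% in {path}")
        fs = 1.0 / med
    else:
        fs = 102.4
    kwargs = {c: df[c].to_numpy(dtype=float) for c in CHANNELS}
    return BodyFrameRecording(sampling_rate_hz=fs, foot=foot, **kwargs)


def write_imu_csv(recording: BodyFrameRecording, path) -> None:
    """Write a recording in the CSV dialect; byte-deterministic (9 significant
    digits) for identical input."""
    if recording is None:
        raise ValueError("recording must not be None")
    df = recording.to_dataframe()
    df.to_csv(path, index=False, float_format="%.9g")


def read_annotations(path) -> AnnotationDocument:
    """Read and validate an annotation document from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        doc = AnnotationDocument(
            sampling_rate_hz=float(raw["sampling_rate_hz"]),
            strides={foot: [tuple(iv) for iv in ivs]
                     for foot, ivs in raw["strides"].items()},
            bouts=[tuple(iv) for iv in raw.get("bouts", [])],
            provenance=str(raw.get("provenance", "")),
        )
    except KeyError as exc:
        raise FormatError(f"annotation document missing field {exc} in {path}") from exc
    return doc


def write_annotations(doc: AnnotationDocument, path) -> None:
    payload = {
        "sampling_rate_hz": doc.sampling_rate_hz,
        "strides": {foot: [list(iv) for iv in ivs] for foot, ivs in doc.strides.items()},
        "bouts": [list(iv) for iv in doc.bouts],
        "provenance": doc.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
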