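"""Synthetic foot-worn IMU gait recordings with exact ground-truth labels.

The generator emulates the statistical structure the segmenter assumes: the
sagittal-plane angular velocity (gyr_ml) of each stride shows sharp negative
peaks at both stride borders, a positive mid-swing peak and a near-zero
stance plateau; strides concatenate into walking bouts that share border
samples; irregular low-amplitude "transition" movement flanks each bout; the
two feet alternate with a half-stride phase offset; bouts are separated by
rest. Per-subject and per-stride lognormal jitter provides heterogeneity,
with an optional short-bout mode that makes short bouts markedly more
irregular (emulating the more heterogeneous strides of short free-living
bouts).

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .containers import BodyFrameRecording, Interval, LabeledRecording
from .evaluation import define_walking_bouts

GRAVITY_MS2 = 9.81
#: half-width (s) of the quadratic border dip; narrow enough that the border
#: sample is a sharp minimum at 102.4 Hz
BORDER_DIP_WIDTH_S = 0.035


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Generation parameters; defaults mimic slow-to-normal adult gait."""

    sampling_rate_hz: float = 102.4
    stride_duration_s: Tuple[float, float] = (1.1, 0.08)  # mean, sd
    border_peak_amp_dps: float = 150.0
    swing_peak_amp_dps: float = 400.0
    noise_sd_dps: float = 5.0
    transition_amp_dps: float = 50.0
    rest_gap_s: Tuple[float, float] = (3.0, 6.0)  # min, max
    subject_variability: float = 0.10
    short_bout_heterogeneity: bool = False
    #: bouts with at most this many strides (both feet) get extra jitter
    short_bout_max_strides: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.stride_duration_s[0] <= 0 or self.rest_gap_s[0] <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd_dps < 0:
            raise ValueError("noise_sd_dps must be >= 0")
        if not self.border_peak_amp_dps > self.transition_amp_dps:
            raise ValueError(
                "border_peak_amp_dps must exceed transition_amp_dps so borders "
                "stay distinguishable from transition movement")


def generate_stride_waveform(duration_s: float, config: SyntheticGaitConfig,
                             rng: np.random.Generator,
                             border_amp: float | None = None,
                             swing_amp: float | None = None,
                             swing_lobes: Sequence[Tuple[float, float, float]]
                             = ((0.35, 0.10, 1.0),),
                             ) -> Tuple[np.ndarray, Tuple[int, int]]:
    """One stride of gyr_ml; the first and last samples are the two borders.

    The noiseless waveform is a sum of smooth lobes: quadratic negative dips
    of depth ``border_peak_amp_dps`` pinned to both end samples, Gaussian
    swing lobes given as ``(phase center, phase width, relative height)``
    triples (by default one positive lobe around 35% of the stride), and a
    small oscillation on the stance plateau.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = config.sampling_rate_hz
    L = int(round(duration_s * fs)) + 1
    if L < 3:
        raise ValueError("duration too short for the sampling rate")
    border_amp = config.border_peak_amp_dps if border_amp is None else border_amp
    swing_amp = config.swing_peak_amp_dps if swing_amp is None else swing_amp

    t = np.arange(L) / fs
    phase = t / duration_s
    y = np.zeros(L)
    for center, width, height in swing_lobes:
        y += height * swing_amp * np.exp(-((phase - center) / width) ** 2)
    # gentle stance oscillation, near-zero plateau (60-95%)
    y += 0.04 * swing_amp * np.sin(2 * np.pi * (phase - 0.6)) * (phase > 0.55)
    # quadratic border dips pinned to the end samples
    w = BORDER_DIP_WIDTH_S
    for t0 in (0.0, t[-1]):
        dt = np.abs(t - t0)
        lobe = np.where(dt < w, (1.0 - dt / w) ** 2, 0.0)
        y -= border_amp * lobe
    if config.noise_sd_dps > 0:
        y = y + rng.normal(0.0, config.noise_sd_dps, size=L)
    return y, (0, L - 1)


def _smooth_noise(n: int, rng: np.random.Generator, fs: float,
                  smooth_s: float = 0.15) -> np.ndarray:
    """Unit-variance low-frequency noise (moving-average-smoothed white noise)."""
    if n == 0:
        return np.zeros(0)
    w = max(1, int(round(smooth_s * fs)))
    x = rng.normal(size=n + w)
    kernel = np.ones(w) / w
    y = np.convolve(x, kernel, mode="valid")[:n]
    sd = y.std()
    return y / sd if sd > 0 else y


def _fill_channels(gyr_ml: np.ndarray, config: SyntheticGaitConfig,
                   rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Accompanying axes: gravity on acc_si plus low-amplitude noise."""
    n = len(gyr_ml)
    noise = config.noise_sd_dps
    return {
        "gyr_ml": gyr_ml,
        "gyr_pa": 0.1 * gyr_ml + noise * rng.normal(size=n),
        "gyr_si": 0.05 * gyr_ml + noise * rng.normal(size=n),
        "acc_ml": 0.2 * rng.normal(size=n),
        "acc_pa": 0.001 * np.abs(gyr_ml) + 0.2 * rng.normal(size=n),
        "acc_si": GRAVITY_MS2 + 0.002 * np.abs(gyr_ml) + 0.2 * rng.normal(size=n),
    }


def _transition_flourish(duration_s: float, config: SyntheticGaitConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Irregular non-gait movement flanking a bout."""
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    y = config.transition_amp_dps * 0.6 * _smooth_noise(n, rng, fs)
    # a couple of gentle bumps so the movement is not pure noise
    for _ in range(rng.integers(1, 3)):
        c = rng.uniform(0.2, 0.8) * n
        width = rng.uniform(0.1, 0.3) * fs
        y += rng.uniform(-0.8, 0.8) * config.transition_amp_dps * np.exp(
            -((np.arange(n) - c) / max(width, 1.0)) ** 2)
    return np.clip(y, -0.95 * config.border_peak_amp_dps,
                   config.swing_peak_amp_dps)


def generate_bout(n_strides: int, config: SyntheticGaitConfig,
                  rng: np.random.Generator,
                  amp_scale: float = 1.0, dur_scale: float = 1.0,
                  jitter_scale: float = 1.0, atypical_prob: float = 0.0,
                  ) -> Tuple[Dict[str, np.ndarray], List[Interval]]:
    """One foot's walking bout: strides sharing border samples, flanked by
    transition movement. Returns the six-channel block and stride intervals
    relative to the block."""
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    mean_dur, sd_dur = config.stride_duration_s
    mean_dur *= dur_scale
    sd_dur *= jitter_scale
    pre = _transition_flourish(rng.uniform(0.8, 1.6), config, rng)
    parts: List[np.ndarray] = [pre]
    intervals: List[Interval] = []
    cursor = len(pre)
    for i in range(n_strides):
        dur = float(np.clip(rng.normal(mean_dur, sd_dur),
                            0.55 * mean_dur, 1.6 * mean_dur))
        amp_mult = amp_scale * float(rng.lognormal(0.0, 0.05 * jitter_scale))
        # heterogeneous (short-bout) strides also vary in morphology,
        # emulating initiation/termination/turning and shuffling strides
        shape_sd = 0.02 * max(jitter_scale - 1.0, 0.0)
        center = float(np.clip(rng.normal(0.35, shape_sd), 0.25, 0.50))
        width = float(0.10 * rng.lognormal(0.0, 2.0 * shape_sd))
        if rng.uniform() < atypical_prob:
            # shuffling/turning stride: reduced, biphasic swing profile with
            # a mid-stride counter-rotation dip; the border peaks stay
            # prominent (they define the stride)
            lobes = ((center - 0.06, 0.06, rng.uniform(0.35, 0.55)),
                     (center + 0.10, 0.06, -rng.uniform(0.25, 0.40)))
        else:
            lobes = ((center, width, 1.0),)
        seg, _ = generate_stride_waveform(
            dur, config, rng,
            border_amp=config.border_peak_amp_dps * amp_mult,
            swing_amp=config.swing_peak_amp_dps * amp_mult,
            swing_lobes=lobes)
        if i == 0:
            parts.append(seg)
            intervals.append((cursor, cursor + len(seg) - 1))
            cursor += len(seg)
        else:
            # share the border sample with the previous stride
            parts.append(seg[1:])
            start = cursor - 1
            intervals.append((start, start + len(seg) - 1))
            cursor += len(seg) - 1
    post = _transition_flourish(rng.uniform(0.8, 1.6), config, rng)
    parts.append(post)
    gyr_ml = np.concatenate(parts)
    return _fill_channels(gyr_ml, config, rng), intervals


def generate_dataset(n_subjects: int, bouts_per_subject: int,
                     bout_length_sampler: Callable[[np.random.Generator], int],
                     config: SyntheticGaitConfig) -> List[LabeledRecording]:
    """Generate one labeled recording per subject.

    ``bout_length_sampler(rng)`` returns the number of strides (both feet
    combined) of one bout; the per-foot counts are the ceiling/floor halves
    and the right foot lags the left by half a stride. Per-subject lognormal
    offsets scale amplitude and stride duration. Fully reproducible from
    ``config.seed``.
    """
    if n_subjects < 1 or bouts_per_subject < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    recordings = []
    for subj in range(n_subjects):
        amp_scale = float(rng.lognormal(0.0, config.subject_variability))
        dur_scale = float(rng.lognormal(0.0, config.subject_variability))
        mean_dur = config.stride_duration_s[0] * dur_scale

        blocks: Dict[str, List[np.ndarray]] = {"left": [], "right": []}
        strides: Dict[str, List[Interval]] = {"left": [], "right": []}
        cursor = {"left": 0, "right": 0}

        def _append_rest(foot: str, n: int) -> None:
            if n <= 0:
                return
            gyr = 0.5 * _smooth_noise(n, rng, fs) + 0.3 * rng.normal(size=n)
            blocks[foot].append(_fill_channels(gyr, config, rng))
            cursor[foot] += n

        for b in range(bouts_per_subject):
            n_total = int(bout_length_sampler(rng))
            if n_total < 1:
                raise ValueError("bout_length_sampler returned a non-positive count")
            n_left = (n_total + 1) // 2
            n_right = n_total - n_left
            short = (config.short_bout_heterogeneity
                     and n_total <= config.short_bout_max_strides)
            jitter = 2.0 if short else 1.0
            atypical = 0.5 if short else 0.0
            half_stride = int(round(0.5 * mean_dur * fs))

            gap = rng.uniform(*config.rest_gap_s) if b > 0 else rng.uniform(1.0, 2.0)
            bout_start = max(cursor["left"], cursor["right"]) + int(round(gap * fs))
            _append_rest("left", bout_start - cursor["left"])
            _append_rest("right", bout_start + half_stride - cursor["right"])

            for foot, n_f in (("left", n_left), ("right", max(n_right, 1))):
                block, ivs = generate_bout(
                    n_f, config, rng, amp_scale=amp_scale, dur_scale=dur_scale,
                    jitter_scale=jitter, atypical_prob=atypical)
                off = cursor[foot]
                blocks[foot].append(block)
                strides[foot].extend((s + off, e + off) for s, e in ivs)
                cursor[foot] += len(block["gyr_ml"])

        # equalize lengths with trailing rest
        total = max(cursor.values()) + int(round(1.5 * fs))
        for foot in ("left", "right"):
            _append_rest(foot, total - cursor[foot])

        recs = {}
        for foot in ("left", "right"):
            channels = {c: np.concatenate([blk[c] for blk in blocks[foot]])
                        for c in blocks[foot][0]}
            recs[foot] = BodyFrameRecording(sampling_rate_hz=fs, foot=foot,
                                            **channels)
        bouts = define_walking_bouts(strides, fs)
        recordings.append(LabeledRecording(
            recordings=recs, strides_per_foot=strides, bouts=bouts,
            subject_id=f"subject{subj:02d}"))
    return recordings


def bin_spanning_sampler(counts: Sequence[int] = (6, 20, 40, 70, 150, 220),
                         ) -> Callable[[np.random.Generator], int]:
    """Cycle deterministically through bout lengths covering all length bins."""
    state = {"i": -1}

    def sampler(rng: np.random.Generator) -> int:
        state["i"] += 1
        return int(counts[state["i"] % len(counts)])

    return sampler
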