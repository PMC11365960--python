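"""Amplitude-threshold syllable segmentation.

Zebra-finch syllables are separated by ~50 ms silent gaps, so boundaries can
be recovered from the RMS amplitude envelope: frames above an automated
threshold form candidate syllables, sub-``min_gap`` silences are merged
(within-syllable amplitude dips must not split a syllable), and runs shorter
than the minimum syllable length (default 5 ms) are discarded.

Two threshold rules are available. ``percentile`` (default) tracks the noise
floor as the envelope's 20th percentile and puts the threshold ``margin_db``
above it; ``fixed_db`` puts it a fixed number of dB above a robust floor
estimate (5th percentile). Times are seconds from waveform start, half-open
``[onset, offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SegmentationParams", "SyllableSegment", "compute_envelope", "segment"]

#: numerical floor for the dB envelope
FLOOR_DB = -120.0


@dataclass(frozen=True)
class SegmentationParams:
    frame_ms: float = 5.0
    hop_ms: float = 1.0
    threshold_mode: str = "percentile"  # 'percentile' | 'fixed_db'
    threshold_value: float = 20.0  # percentile, or dB above floor for fixed_db
    margin_db: float = 10.0  # percentile mode: dB added above the tracked floor
    min_syllable_ms: float = 5.0
    min_gap_ms: float = 5.0

    def __post_init__(self) -> None:
        if not (self.frame_ms >= self.hop_ms > 0):
            raise ValueError("need frame_ms >= hop_ms > 0")
        if self.min_syllable_ms < 0 or self.min_gap_ms < 0:
            raise ValueError("min_syllable_ms and min_gap_ms must be >= 0")
        if self.threshold_mode not in ("percentile", "fixed_db"):
            raise ValueError("threshold_mode must be 'percentile' or 'fixed_db'")


@dataclass(frozen=True)
class SyllableSegment:
    onset: float
    offset: float
    label: str | None = None

    def __post_init__(self) -> None:
        if not (self.offset > self.onset):
            raise ValueError(f"offset {self.offset} must exceed onset {self.onset}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def compute_envelope(
    w: np.ndarray, sample_rate: float, frame_ms: float = 5.0, hop_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMS in dB relative to full scale (1.0).

    Returns ``(frame_start_times_s, env_db)`` with one value per hop and
    ``floor((n - frame) / hop) + 1`` frames; the envelope is clamped at
    -120 dB. Rejects waveforms shorter than one frame.
    """
    frame_n = int(round(frame_ms / 1000.0 * sample_rate))
    hop_n = int(round(hop_ms / 1000.0 * sample_rate))
    if frame_n <= 0 or hop_n <= 0:
        raise ValueError("frame and hop must be at least one sample")
    if len(w) < frame_n:
        raise ValueError(f"waveform ({len(w)} samples) shorter than one frame ({frame_n})")
    # O(n) sliding mean-square via cumulative sum
    csum = np.concatenate([[0.0], np.cumsum(np.asarray(w, dtype=np.float64) ** 2)])
    n_frames = (len(w) - frame_n) // hop_n + 1
    starts = np.arange(n_frames) * hop_n
    ms = (csum[starts + frame_n] - csum[starts]) / frame_n
    floor = 10.0 ** (FLOOR_DB / 10.0)
    env_db = 10.0 * np.log10(np.maximum(ms, floor))
    times = starts / sample_rate
    return times, env_db


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as half-open (start, stop) frame index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def _refine_bounds(
    w: np.ndarray, sample_rate: float, i0: int, i1: int, thr_db: float
) -> tuple[int, int] | None:
    """Trim a coarse supra-threshold span to where a 1 ms RMS window crosses.

    The 5 ms analysis frame smears boundaries by up to a frame; a fine
    sample-hop pass inside the span recovers them to ~1 ms.
    """
    win = max(1, int(round(0.001 * sample_rate)))
    x = np.asarray(w[i0:i1], dtype=np.float64)
    if len(x) < win:
        return None
    csum = np.concatenate([[0.0], np.cumsum(x**2)])
    ms = (csum[win:] - csum[:-win]) / win
    mask = ms > 10.0 ** (thr_db / 10.0)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    return i0 + int(idx[0]), i0 + int(idx[-1]) + win


def segment(
    w: np.ndarray, sample_rate: float, params: SegmentationParams = SegmentationParams()
) -> list[SyllableSegment]:
    """Detect syllables as supra-threshold envelope runs.

    All-silent input yields an empty list. Output segments are sorted,
    disjoint and at least ``min_syllable_ms`` long.
    """
    times, env = compute_envelope(w, sample_rate, params.frame_ms, params.hop_ms)
    if params.threshold_mode == "percentile":
        thr = np.percentile(env, params.threshold_value) + params.margin_db
    else:
        thr = np.percentile(env, 5.0) + params.threshold_value
    thr = min(thr, -1.0)  # never demand more than near-full-scale energy
    mask = env > thr
    runs = _runs(mask)

    # merge across sub-min_gap silences
    frame_n = int(round(params.frame_ms / 1000.0 * sample_rate))
    hop_n = int(round(params.hop_ms / 1000.0 * sample_rate))
    frame_s = params.frame_ms / 1000.0
    merged: list[tuple[int, int]] = []
    max_gap_frames = params.min_gap_ms / params.hop_ms
    for r in runs:
        if merged and (r[0] - merged[-1][1]) < max_gap_frames:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)

    segs = []
    for start, stop in merged:
        i0 = start * hop_n
        i1 = (stop - 1) * hop_n + frame_n
        fine = _refine_bounds(w, sample_rate, i0, i1, thr)
        if fine is not None:
            onset, offset = fine[0] / sample_rate, fine[1] / sample_rate
        else:
            onset, offset = times[start], times[stop - 1] + frame_s
        if (offset - onset) * 1000.0 >= params.min_syllable_ms:
            segs.append(SyllableSegment(onset, offset))
    return segs
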