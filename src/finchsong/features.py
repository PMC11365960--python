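"""Per-frame spectral features for syllable renditions.

The six features follow the Sound Analysis Pro tradition for birdsong:

* ``pitch`` -- frequency of the dominant cepstral quefrency peak, searched in
  the 300-8000 Hz band (Hz),
* ``goodness`` -- that cepstral peak's height, a periodicity measure
  (unitless),
* ``wiener_entropy`` -- ln(geometric mean / arithmetic mean) of the in-band
  power spectrum; 0 for white noise, strongly negative for pure tones,
* ``fm`` -- frequency modulation, arctan of the ratio between the time- and
  frequency-derivative norms of the spectrogram (radians, in [0, pi/2]),
* ``am`` -- amplitude modulation, the time derivative of log amplitude (1/s),
* ``amplitude_db`` -- frame RMS in dB re full scale.

Spectra come from a single Gaussian-windowed FFT per frame (default frame
9.27 ms = 371 samples at 40 kHz, hop 1 ms), a deliberate simplification of
SAP's multitaper estimates; absolute parity with SAP2011 is out of scope and
only relative comparisons between scores are interpreted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import gaussian

from .segmentation import SyllableSegment

__all__ = [
    "FEATURE_NAMES",
    "FeatureTrack",
    "FeatureScaling",
    "extract_features",
    "estimate_scaling",
]

FEATURE_NAMES = ("pitch", "goodness", "wiener_entropy", "fm", "am", "amplitude_db")

#: analysis band, Hz
BAND = (300.0, 8000.0)
DEFAULT_FRAME_MS = 9.27
DEFAULT_HOP_MS = 1.0
_TINY = 1e-12
#: MAD floor so scales stay strictly positive
SCALE_EPS = 1e-6


@dataclass
class FeatureTrack:
    """Ordered per-frame feature vectors for one syllable rendition."""

    syllable_id: str
    times: np.ndarray  # frame-centre times, s, strictly increasing
    values: np.ndarray  # shape (n_frames, 6), columns = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"values must be (n, {len(FEATURE_NAMES)})")
        if len(self.times) != len(self.values) or len(self.times) < 1:
            raise ValueError("need >= 1 frame with matching times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(FEATURE_NAMES))
        df.insert(0, "time_s", self.times)
        return df


@dataclass
class FeatureScaling:
    """Robust per-feature location/scale plus a background distance sample.

    Location is the median and scale the median absolute deviation over a
    reference corpus; the stored background distances (between random scaled
    frame pairs of that corpus) calibrate the similarity threshold.
    """

    location: np.ndarray
    scale: np.ndarray
    background_distances: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise ValueError("all scales must be > 0")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.location) / self.scale

    def distance_threshold(self, q: float = 0.5) -> float:
        """q-quantile of the background frame-pair distance distribution."""
        return max(float(np.quantile(self.background_distances, q)), SCALE_EPS)


def _spectrogram(x: np.ndarray, sample_rate: float, frame_n: int, hop_n: int):
    """Gaussian-windowed power spectrogram; returns (frames_raw, S, freqs)."""
    frames = sliding_window_view(x, frame_n)[::hop_n]
    win = gaussian(frame_n, std=frame_n / 6.0)
    nfft = 1 << (frame_n - 1).bit_length()
    spec = np.fft.rfft(frames * win, n=nfft, axis=1)
    S = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate)
    return frames, S, freqs


def extract_features(
    w: np.ndarray,
    sample_rate: float,
    seg: SyllableSegment,
    frame_ms: float = DEFAULT_FRAME_MS,
    hop_ms: float = DEFAULT_HOP_MS,
) -> FeatureTrack:
    """Compute the six SAP-style features for one segment of ``w``.

    Unvoiced frames keep their (meaningless but finite) cepstral pitch
    estimate; masking is left to downstream weighting so the distance
    computation never faces missing data.
    """
    i0 = max(int(round(seg.onset * sample_rate)), 0)
    i1 = min(int(round(seg.offset * sample_rate)), len(w))
    x = np.asarray(w[i0:i1], dtype=np.float64)
    frame_n = int(round(frame_ms / 1000.0 * sample_rate))
    hop_n = max(int(round(hop_ms / 1000.0 * sample_rate)), 1)
    if len(x) < frame_n:
        raise ValueError(
            f"segment {seg.onset:.4f}-{seg.offset:.4f}s shorter than one analysis frame"
        )

    frames, S, freqs = _spectrogram(x, sample_rate, frame_n, hop_n)
    n_frames = len(frames)
    band = (freqs >= BAND[0]) & (freqs <= BAND[1])
    # light spectral smoothing stands in for multitaper variance reduction;
    # without it the chi-square fluctuations of a single periodogram bias the
    # entropy of white noise to -gamma ~ -0.58 instead of ~0
    kernel = np.ones(5) / 5.0
    S_smooth = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, S)
    Sb = S_smooth[:, band]

    # Wiener entropy: ln(gmean / amean) of in-band power, <= 0 by AM-GM
    log_S = np.log(Sb + _TINY)
    wiener = np.mean(log_S, axis=1) - np.log(np.mean(Sb, axis=1) + _TINY)
    wiener = np.minimum(wiener, 0.0)

    # pitch and goodness from the power cepstrum (inverse FFT of the power
    # spectrum, i.e. the windowed-frame autocorrelation): its quefrency
    # envelope is set by the analysis window rather than the spectral bump
    # width, so periodic sounds peak at 1/f0 with sub-bin accuracy. The
    # search keeps to interior local maxima so the decaying envelope at the
    # search edge never masquerades as a peak. Goodness is the peak height
    # normalised by lag-0 power: ~1 for strongly periodic frames, ~0 for noise.
    cd = np.fft.irfft(S, axis=1)
    cd = cd / np.maximum(cd[:, :1], _TINY)
    q_lo = max(int(np.floor(sample_rate / BAND[1])), 2)
    q_hi = min(int(np.ceil(sample_rate / BAND[0])), cd.shape[1] - 2)
    cb = cd[:, q_lo : q_hi + 1]
    interior = (cb > cd[:, q_lo - 1 : q_hi]) & (cb >= cd[:, q_lo + 1 : q_hi + 2])
    masked = np.where(interior, cb, -np.inf)
    has_peak = interior.any(axis=1)
    best = np.max(masked, axis=1)
    # octave-error suppression: smallest lag within 90% of the strongest peak
    near_best = masked >= 0.9 * np.maximum(best[:, None], _TINY)
    first_good = np.argmax(near_best, axis=1)
    q_peak = np.where(has_peak, first_good, np.argmax(cb, axis=1)) + q_lo
    # parabolic interpolation for sub-bin quefrency precision
    rows = np.arange(n_frames)
    c0, c1, c2 = cd[rows, q_peak - 1], cd[rows, q_peak], cd[rows, q_peak + 1]
    denom = c0 - 2 * c1 + c2
    shift = np.where(np.abs(denom) > _TINY, 0.5 * (c0 - c2) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    pitch = sample_rate / (q_peak + shift)
    goodness = np.maximum(cd[rows, q_peak], 0.0)

    # frequency modulation from spectrogram derivatives (log power)
    L = np.log(Sb + _TINY)
    if n_frames > 1:
        dLdt = np.gradient(L, axis=0)
    else:
        dLdt = np.zeros_like(L)
    dLdf = np.gradient(L, axis=1)
    fm = np.arctan2(np.linalg.norm(dLdt, axis=1), np.linalg.norm(dLdf, axis=1) + _TINY)

    # amplitude and its log-derivative
    rms = np.sqrt(np.mean(frames**2, axis=1))
    amplitude_db = 20.0 * np.log10(np.maximum(rms, 1e-6))
    hop_s = hop_n / sample_rate
    if n_frames > 1:
        am = np.gradient(np.log(np.maximum(rms, 1e-6))) / hop_s
    else:
        am = np.zeros(n_frames)

    times = seg.onset + (np.arange(n_frames) * hop_n + frame_n / 2.0) / sample_rate
    values = np.column_stack([pitch, goodness, wiener, fm, am, amplitude_db])
    sid = seg.label if seg.label is not None else f"{seg.onset:.4f}"
    return FeatureTrack(sid, times, values)


def estimate_scaling(
    corpus_tracks: list[FeatureTrack],
    max_frames: int = 5000,
    n_pairs: int = 20000,
    seed: int = 0,
) -> FeatureScaling:
    """Median/MAD scaling plus background distances from a reference corpus.

    Requires >= 100 frames in total. MAD is floored at a small epsilon so
    degenerate corpora still yield a valid (if uninformative) scaling. The
    background sample is drawn with a fixed seed so scalings are reproducible.
    """
    if not corpus_tracks:
        raise ValueError("need at least one track")
    all_frames = np.concatenate([t.values for t in corpus_tracks], axis=0)
    if len(all_frames) < 100:
        raise ValueError(f"need >= 100 frames to estimate scaling, got {len(all_frames)}")
    location = np.median(all_frames, axis=0)
    scale = np.maximum(np.median(np.abs(all_frames - location), axis=0), SCALE_EPS)

    rng = np.random.default_rng(seed)
    if len(all_frames) > max_frames:
        keep = rng.choice(len(all_frames), size=max_frames, replace=False)
        sample = all_frames[keep]
    else:
        sample = all_frames
    scaled = (sample - location) / scale
    i = rng.integers(0, len(scaled), size=n_pairs)
    j = rng.integers(0, len(scaled), size=n_pairs)
    ok = i != j
    dists = np.linalg.norm(scaled[i[ok]] - scaled[j[ok]], axis=1)
    return FeatureScaling(location, scale, np.sort(dists))
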