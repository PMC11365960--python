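"""Percent-similarity scoring between syllable renditions.

Two renditions are compared symmetrically across their time courses: both
feature tracks are linearly time-rescaled to a common length (the rounded mean
of the two), each frame pair's Euclidean distance is computed in robustly
scaled (median/MAD) feature space, and a frame pair counts as *similar* when
its distance falls below the q-quantile (default q = 0.5) of the background
distance distribution between random frames of the reference corpus. The
score is 100 x the similar-frame fraction, so identical renditions score 100
and unrelated sounds score near 100*q of chance frame agreement or below.

Also provided: self-similarity statistics over rendition pairs (mean +/- std,
the quantities the sigma-threshold novelty criterion consumes),
cross-similarity score sets between syllable types, and empirical cumulative
density (ECD) curves with bootstrap 95% confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .features import FeatureScaling, FeatureTrack

__all__ = [
    "SimilarityScore",
    "SelfSimilarityStats",
    "ECDCurve",
    "syllable_similarity",
    "self_similarity",
    "cross_similarity",
    "ecd_with_ci",
]

DEFAULT_BACKGROUND_Q = 0.5


@dataclass(frozen=True)
class SimilarityScore:
    value: float  # percent in [0, 100]
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"score {self.value} outside [0, 100]")


@dataclass(frozen=True)
class SelfSimilarityStats:
    label: str
    mean: float
    std: float
    n_pairs: int


@dataclass
class ECDCurve:
    """Point ECDF over sorted score values with pointwise bootstrap bands."""

    values: np.ndarray
    probs: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_bootstrap: int


def _resample(values: np.ndarray, k: int) -> np.ndarray:
    """Linear time-rescaling of an (n, d) track to k frames."""
    n = len(values)
    if n == k:
        return values
    src = np.linspace(0.0, 1.0, n)
    dst = np.linspace(0.0, 1.0, k)
    out = np.empty((k, values.shape[1]))
    for c in range(values.shape[1]):
        out[:, c] = np.interp(dst, src, values[:, c])
    return out


def syllable_similarity(
    a: FeatureTrack,
    b: FeatureTrack,
    scaling: FeatureScaling,
    q: float = DEFAULT_BACKGROUND_Q,
) -> SimilarityScore:
    """Percent similarity between two renditions, symmetric by construction.

    Linear rescaling pairs frame k of one track with frame k of the other in
    both directions, so the two orderings yield the same frame pairing and
    the averaged score equals either one; symmetry is exact.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("tracks must have at least 2 frames")
    k = max(int(round((len(a) + len(b)) / 2.0)), 2)
    fa = scaling.transform(_resample(a.values, k))
    fb = scaling.transform(_resample(b.values, k))
    d = np.linalg.norm(fa - fb, axis=1)
    thr = scaling.distance_threshold(q)
    value = 100.0 * float(np.mean(d < thr))
    return SimilarityScore(value, (a.syllable_id, b.syllable_id))


def self_similarity(
    renditions: list[FeatureTrack],
    scaling: FeatureScaling,
    n_max: int = 10,
    q: float = DEFAULT_BACKGROUND_Q,
) -> SelfSimilarityStats:
    """Mean +/- std of pairwise scores among the first ``n_max`` renditions.

    With n renditions used, n_pairs = n(n-1)/2. Std is the sample standard
    deviation (ddof=1) over pairs, 0 when only one pair exists.
    """
    if len(renditions) < 2:
        raise ValueError("need >= 2 renditions")
    use = renditions[:n_max]
    scores = np.array(
        [syllable_similarity(x, y, scaling, q).value for x, y in combinations(use, 2)]
    )
    std = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    label = use[0].syllable_id
    return SelfSimilarityStats(label, float(np.mean(scores)), std, len(scores))


def cross_similarity(
    group_a: dict[str, list[FeatureTrack]],
    group_b: dict[str, list[FeatureTrack]],
    scaling: FeatureScaling,
    n_max: int = 10,
    q: float = DEFAULT_BACKGROUND_Q,
) -> dict[tuple[str, str], np.ndarray]:
    """Full pairwise score sets for every type pair (up to n_max renditions each).

    When a type is compared against the very same rendition list (the diagonal
    of ``cross_similarity(A, A)``) unordered pairs are used, reproducing the
    ``self_similarity`` pair set. Empty types are skipped with a warning.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    out: dict[tuple[str, str], np.ndarray] = {}
    for la, tracks_a in group_a.items():
        if not tracks_a:
            warnings.warn(f"type {la!r} has no renditions; skipped")
            continue
        for lb, tracks_b in group_b.items():
            if not tracks_b:
                warnings.warn(f"type {lb!r} has no renditions; skipped")
                continue
            ta, tb = tracks_a[:n_max], tracks_b[:n_max]
            if tracks_a is tracks_b:
                pairs = combinations(ta, 2)
            else:
                pairs = product(ta, tb)
            scores = [syllable_similarity(x, y, scaling, q).value for x, y in pairs]
            out[(la, lb)] = np.asarray(scores)
    return out


def ecd_with_ci(
    scores, n_bootstrap: int = 1000, seed: int = 0
) -> ECDCurve:
    """Empirical cumulative density with pointwise 95% bootstrap bands.

    The point curve is the ECDF evaluated at the sorted scores; bands are the
    pointwise 2.5/97.5 percentiles of ECDFs over ``n_bootstrap`` resamples
    (with replacement, same n), clamped to bracket the point curve.
    Deterministic given ``seed``.
    """
    scores = np.sort(np.asarray(scores, dtype=np.float64))
    n = len(scores)
    if n < 5:
        raise ValueError("need >= 5 scores for an ECD curve")
    # right-continuous ECDF evaluated at the grid (ties share one value)
    probs = np.searchsorted(scores, scores, side="right") / n
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, n))
    for i in range(n_bootstrap):
        resample = np.sort(rng.choice(scores, size=n, replace=True))
        boot[i] = np.searchsorted(resample, scores, side="right") / n
    ci_lo = np.minimum(np.percentile(boot, 2.5, axis=0), probs)
    ci_hi = np.maximum(np.percentile(boot, 97.5, axis=0), probs)
    return ECDCurve(scores, probs, ci_lo, ci_hi, n_bootstrap)
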