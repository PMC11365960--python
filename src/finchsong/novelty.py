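"""Repertoire-change detection: the sigma-threshold novelty rule and the
embedding/clustering cross-check.

A candidate syllable type is *novel* when its cross-similarity to every
pre-existing type falls more than ``z`` (default 1.96) standard deviations
below that type's self-similarity mean -- a one-sided reading, since novelty
means *lower* similarity. The dispersion used is each pre-existing type's own
self-similarity std; a pooled mode (all pre-existing self scores lumped
together) is available for sensitivity analyses.

The independent cross-check embeds fixed-length per-syllable feature
summaries with UMAP and clusters the embedding with HDBSCAN; clusters whose
membership is >= 95% final-epoch count as new. Distribution comparisons
delegate to scipy's nonparametric tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

from .features import FeatureTrack

__all__ = [
    "NoveltyCriterion",
    "NoveltyVerdict",
    "ClusterComparison",
    "classify_novel",
    "classify_novel_pooled",
    "count_new_syllables",
    "summary_vectors",
    "embed_and_cluster",
    "compare_score_groups",
]


@dataclass(frozen=True)
class NoveltyCriterion:
    """One-sided-below z-threshold applied against every pre-existing type."""

    z: float = 1.96

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be > 0")


@dataclass(frozen=True)
class NoveltyVerdict:
    candidate: str
    #: per pre-existing type: cross_mean - (self_mean - z * self_std); novel iff all < 0
    margins: dict[str, float]
    is_novel: bool


@dataclass
class ClusterComparison:
    """UMAP embedding + HDBSCAN labels of baseline/final syllables."""

    embedding: np.ndarray  # (n, 2)
    cluster: np.ndarray  # HDBSCAN labels, -1 = noise (excluded from counting)
    epoch: np.ndarray  # per-syllable epoch tag
    n_new_clusters: int


def classify_novel(
    candidate: str,
    self_stats: dict,
    cross_means: dict[str, float],
    criterion: NoveltyCriterion = NoveltyCriterion(),
) -> NoveltyVerdict:
    """Apply the z-sigma rule: novel iff below threshold for *all* pre-existing types.

    ``self_stats`` maps each pre-existing type to its SelfSimilarityStats (or
    any object with .mean/.std); ``cross_means`` maps each pre-existing type
    to the mean cross-similarity of the candidate against it. A missing cross
    entry is incomplete evidence and is rejected.
    """
    if not self_stats:
        raise ValueError("need >= 1 pre-existing type")
    missing = set(self_stats) - set(cross_means)
    if missing:
        raise ValueError(f"missing cross-similarity for types: {sorted(missing)}")
    margins = {
        p: float(cross_means[p] - (st.mean - criterion.z * st.std))
        for p, st in self_stats.items()
    }
    return NoveltyVerdict(candidate, margins, all(m < 0 for m in margins.values()))


def classify_novel_pooled(
    candidate: str,
    self_scores,
    cross_scores,
    criterion: NoveltyCriterion = NoveltyCriterion(),
) -> NoveltyVerdict:
    """Pooled variant: one margin against all pre-existing self scores lumped."""
    self_scores = np.asarray(self_scores, dtype=np.float64)
    cross_scores = np.asarray(cross_scores, dtype=np.float64)
    if len(self_scores) < 2 or len(cross_scores) < 1:
        raise ValueError("need >= 2 pooled self scores and >= 1 cross score")
    thr = self_scores.mean() - criterion.z * self_scores.std(ddof=1)
    margin = float(cross_scores.mean() - thr)
    return NoveltyVerdict(candidate, {"pooled": margin}, margin < 0)


def count_new_syllables(verdicts: list[NoveltyVerdict]) -> int:
    """Number of candidate types judged novel (one subject, one epoch pair)."""
    return sum(v.is_novel for v in verdicts)


def summary_vectors(tracks: list[FeatureTrack]) -> np.ndarray:
    """Fixed-length summaries for clustering: mean and std of each of the six
    features plus duration -- 13 values per syllable."""
    out = np.empty((len(tracks), 13))
    for i, t in enumerate(tracks):
        out[i, :6] = t.values.mean(axis=0)
        out[i, 6:12] = t.values.std(axis=0)
        out[i, 12] = t.duration
    return out


def embed_and_cluster(
    vectors: np.ndarray,
    epochs,
    n_neighbors: int = 15,
    min_cluster_size: int = 25,
    min_dist: float = 0.1,
    final_tag: str = "final",
    purity: float = 0.95,
    seed: int = 0,
) -> ClusterComparison:
    """2-D UMAP embedding + HDBSCAN clustering of per-syllable summaries.

    New clusters are those whose (non-noise) membership is at least
    ``purity`` final-epoch. Deterministic given ``seed``. Requires >= 50
    syllables and non-degenerate (not all-identical) vectors.
    """
    import umap  # deferred: heavy import
    from sklearn.cluster import HDBSCAN

    vectors = np.asarray(vectors, dtype=np.float64)
    epochs = np.asarray(list(epochs))
    if len(vectors) != len(epochs):
        raise ValueError("vectors and epoch tags must align")
    if len(vectors) < 50:
        raise ValueError(f"need >= 50 syllables, got {len(vectors)}")
    if not np.all(np.isfinite(vectors)):
        raise ValueError("vectors must be finite")
    if np.all(np.ptp(vectors, axis=0) == 0):
        raise ValueError("degenerate input: all vectors identical")

    # z-score columns (constant columns left centred at 0)
    mu = vectors.mean(axis=0)
    sd = vectors.std(axis=0)
    sd[sd == 0] = 1.0
    zv = (vectors - mu) / sd

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    emb = reducer.fit_transform(zv)
    labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(emb)

    n_new = 0
    for c in np.unique(labels):
        if c < 0:  # noise
            continue
        members = epochs[labels == c]
        if np.mean(members == final_tag) >= purity:
            n_new += 1
    return ClusterComparison(emb, labels, epochs, n_new)


_TESTS = {
    "kruskal_wallis": lambda groups: ss.kruskal(*groups),
    "wilcoxon_signed_rank": lambda groups: ss.wilcoxon(*groups),
    "wilcoxon_rank_sum": lambda groups: ss.ranksums(*groups),
    "friedman": lambda groups: ss.friedmanchisquare(*groups),
}


def compare_score_groups(groups: dict[str, list], test: str) -> tuple[float, float]:
    """Nonparametric comparison of named score groups via scipy.stats.

    ``wilcoxon_signed_rank`` and ``friedman`` require matched (equal-length)
    groups; ``wilcoxon_signed_rank`` and ``wilcoxon_rank_sum`` take exactly two.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    arrays = [np.asarray(g, dtype=np.float64) for g in groups.values()]
    if test in ("wilcoxon_signed_rank", "wilcoxon_rank_sum") and len(arrays) != 2:
        raise ValueError(f"{test} requires exactly 2 groups")
    if test in ("wilcoxon_signed_rank", "friedman"):
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError(f"{test} requires matched group lengths, got {sorted(lengths)}")
    res = _TESTS[test](arrays)
    return float(res.statistic), float(res.pvalue)
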