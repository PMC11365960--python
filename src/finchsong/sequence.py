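"""Syllable-sequence statistics: transition matrices, stereotypy scores and
novel-syllable positioning.

Song stereotypy is summarised by two classical ratios computed over a pooled
set of bouts ("per song"):

* sequence linearity = (# distinct notes) / (# distinct transition types);
  1 for a song that always follows one linear path,
* sequence consistency = (# transitions following their source's typical,
  i.e. modal, successor) / (# total transitions); 1 for a fully
  stereotyped song.

Transitions are counted between adjacent syllables within a bout, never
across bout boundaries (bouts are separated by silence). Introductory notes
are excluded by default, mirroring their separate annotation in the field.
The positioning of novel syllables relative to completed core-motif ends
(bin 0 = immediately after the motif's last syllable, negative = inside the
motif) is summarised as a relative-probability histogram.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabeledBout",
    "TransitionMatrix",
    "SequenceStats",
    "PositionHistogram",
    "transition_matrix",
    "sequence_linearity",
    "sequence_consistency",
    "sequence_stats",
    "novel_position_histogram",
    "bouts_from_table",
]

DEFAULT_INTRO_LABELS = frozenset({"i"})


@dataclass
class LabeledBout:
    """One bout's ordered syllable labels (optionally with onset times)."""

    labels: list[str]
    onsets: list[float] | None = None
    subject: str = ""
    epoch: str = ""

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("bout must contain at least one syllable")
        if self.onsets is not None and len(self.onsets) != len(self.labels):
            raise ValueError("onsets must align with labels")


@dataclass
class TransitionMatrix:
    labels: list[str]
    counts: pd.DataFrame  # rows = source, columns = successor
    proportions: pd.DataFrame  # row-normalised; all-zero rows stay zero


@dataclass(frozen=True)
class SequenceStats:
    linearity: float
    consistency: float
    n_bouts: int


@dataclass
class PositionHistogram:
    """Relative probabilities of novel-syllable positions w.r.t. motif ends."""

    bins: np.ndarray  # integer positions; 0 = immediately after motif end
    probs: np.ndarray  # sums to 1 over counted occurrences
    n_occurrences: int
    n_skipped: int  # novel occurrences with no preceding completed motif


def _sequences(bouts: list[LabeledBout], include_intro: bool,
               intro_labels=DEFAULT_INTRO_LABELS) -> list[list[str]]:
    if include_intro:
        return [list(b.labels) for b in bouts]
    return [[lab for lab in b.labels if lab not in intro_labels] for b in bouts]


def _transitions(seqs: list[list[str]]):
    for seq in seqs:
        for a, b in zip(seq, seq[1:]):
            yield a, b


def transition_matrix(
    bouts: list[LabeledBout],
    include_intro: bool = False,
    intro_labels=DEFAULT_INTRO_LABELS,
) -> TransitionMatrix:
    """Counts and row-normalised proportions of adjacent within-bout pairs."""
    if not bouts:
        raise ValueError("need >= 1 bout")
    seqs = _sequences(bouts, include_intro, intro_labels)
    alphabet = sorted({lab for seq in seqs for lab in seq})
    if not alphabet:
        raise ValueError("empty alphabet after intro filtering")
    idx = {lab: k for k, lab in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), len(alphabet)), dtype=np.int64)
    for a, b in _transitions(seqs):
        counts[idx[a], idx[b]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    props = np.divide(counts, row_sums, where=row_sums > 0,
                      out=np.zeros_like(counts, dtype=np.float64))
    cdf = pd.DataFrame(counts, index=alphabet, columns=alphabet)
    pdf = pd.DataFrame(props, index=alphabet, columns=alphabet)
    return TransitionMatrix(alphabet, cdf, pdf)


def sequence_linearity(
    bouts: list[LabeledBout],
    include_intro: bool = False,
    intro_labels=DEFAULT_INTRO_LABELS,
) -> float:
    """Distinct notes / distinct transition types, pooled over the bout set."""
    seqs = _sequences(bouts, include_intro, intro_labels)
    notes = {lab for seq in seqs for lab in seq}
    pairs = set(_transitions(seqs))
    if not pairs:
        raise ValueError("no transitions observed; linearity undefined")
    return len(notes) / len(pairs)


def sequence_consistency(
    bouts: list[LabeledBout],
    include_intro: bool = False,
    intro_labels=DEFAULT_INTRO_LABELS,
) -> float:
    """Fraction of transitions that follow their source's typical successor.

    The typical successor of each source label is its modal successor over the
    pooled bouts; ties are broken towards the earliest-observed successor.
    """
    seqs = _sequences(bouts, include_intro, intro_labels)
    counts: Counter = Counter()
    first_seen: dict[tuple[str, str], int] = {}
    total = 0
    for k, pair in enumerate(_transitions(seqs)):
        counts[pair] += 1
        first_seen.setdefault(pair, k)
        total += 1
    if total == 0:
        raise ValueError("no transitions observed; consistency undefined")
    sources = {a for a, _ in counts}
    typical = 0
    for src in sources:
        succ = [(pair, n) for pair, n in counts.items() if pair[0] == src]
        best = max(succ, key=lambda item: (item[1], -first_seen[item[0]]))
        typical += best[1]
    return typical / total


def sequence_stats(
    bouts: list[LabeledBout],
    include_intro: bool = False,
    intro_labels=DEFAULT_INTRO_LABELS,
) -> SequenceStats:
    return SequenceStats(
        sequence_linearity(bouts, include_intro, intro_labels),
        sequence_consistency(bouts, include_intro, intro_labels),
        len(bouts),
    )


def _motif_ends(core_seq: list[str], motif: list[str]) -> list[int]:
    """End indices (inclusive) of non-overlapping completed motifs, greedy
    left-to-right, within the core-only subsequence."""
    ends = []
    L = len(motif)
    k = 0
    while k + L <= len(core_seq):
        if core_seq[k : k + L] == motif:
            ends.append(k + L - 1)
            k += L
        else:
            k += 1
    return ends


def novel_position_histogram(
    bouts: list[LabeledBout],
    novel_labels,
    core_motif,
    intro_labels=DEFAULT_INTRO_LABELS,
) -> PositionHistogram:
    """Histogram of novel-syllable positions relative to motif ends.

    For each novel occurrence, its position is counted in core-syllable steps
    from the end of the nearest preceding (or containing) completed core
    motif: 0 = immediately after the motif's last syllable, positive = further
    along, negative = inserted inside the motif. Occurrences preceding any
    completed motif are skipped (reported in ``n_skipped``).
    """
    novel_labels = set(novel_labels)
    motif = list(core_motif)
    if novel_labels & set(motif):
        raise ValueError("novel labels must be disjoint from the core motif")
    positions: list[int] = []
    n_skipped = 0
    for bout in bouts:
        work = [lab for lab in bout.labels if lab not in intro_labels]
        core_seq = [lab for lab in work if lab not in novel_labels]
        ends = _motif_ends(core_seq, motif)
        if not ends:
            n_novel_here = sum(lab in novel_labels for lab in work)
            if n_novel_here:
                n_skipped += n_novel_here
            continue
        n_core_before = 0
        for lab in work:
            if lab in novel_labels:
                k = n_core_before  # novel sits between core elements k-1 and k
                prior = [e for e in ends if e < k]
                containing = [e for e in ends if e - len(motif) + 1 < k <= e]
                if containing:
                    positions.append(k - containing[0] - 1)
                elif prior:
                    positions.append(k - prior[-1] - 1)
                else:
                    n_skipped += 1
            else:
                n_core_before += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} novel occurrence(s) without a completed core motif skipped")
    if not positions:
        return PositionHistogram(np.array([], dtype=int), np.array([]), 0, n_skipped)
    bins, counts = np.unique(np.asarray(positions), return_counts=True)
    return PositionHistogram(bins, counts / counts.sum(), len(positions), n_skipped)


def bouts_from_table(
    table: pd.DataFrame,
    bout_col: str | None = "bout",
    bout_gap_s: float = 2.0,
    subject: str = "",
    epoch_col: str | None = "epoch",
) -> list[LabeledBout]:
    """Build LabeledBouts from a segment table (onset_s, offset_s, label, ...).

    Uses an explicit bout column when present, otherwise splits at silent
    gaps longer than ``bout_gap_s``.
    """
    df = table.sort_values("onset_s", kind="stable") if bout_col is None else table
    bouts: list[LabeledBout] = []
    if bout_col is not None and bout_col in table.columns:
        for b, sub in table.groupby(bout_col, sort=True):
            epoch = str(sub[epoch_col].iloc[0]) if epoch_col and epoch_col in sub else ""
            bouts.append(LabeledBout(sub["label"].tolist(), sub["onset_s"].tolist(),
                                     subject, epoch))
        return bouts
    gaps = df["onset_s"].values[1:] - df["offset_s"].values[:-1]
    breaks = np.concatenate([[0], np.flatnonzero(gaps > bout_gap_s) + 1, [len(df)]])
    for a, b in zip(breaks, breaks[1:]):
        sub = df.iloc[a:b]
        if len(sub) == 0:
            continue
        epoch = str(sub[epoch_col].iloc[0]) if epoch_col and epoch_col in sub else ""
        bouts.append(LabeledBout(sub["label"].tolist(), sub["onset_s"].tolist(),
                                 subject, epoch))
    return bouts
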