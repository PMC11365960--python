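"""Synthetic zebra-finch song generator with ground-truth annotations.

Adult zebra finch song is organised in bouts: a few short, soft introductory
notes followed by one or more renditions of a stereotyped *motif* of 4-7
syllables separated by ~50 ms silent gaps. This module synthesises WAV-level
corpora of such song, plus a "final" condition in which acoustically novel
syllable types appear (predominantly appended after motif ends) with elevated
rendition-to-rendition variability -- so that every downstream analysis stage
(segmentation, feature extraction, similarity, novelty, sequence statistics)
can be validated against known ground truth.

Syllable renditions are built from simple archetypes (harmonic stacks, chirps,
band-limited noise bursts, introductory up-chirps) with multiplicative
Gaussian jitter on fundamental frequency, duration and amplitude. Noise-burst
carriers are *frozen* per label (seeded from a stable hash of the label) so
that zero-jitter renditions of a type are bit-identical -- a property the test
suite relies on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SyllableArchetype",
    "RenditionJitter",
    "SongGrammar",
    "NoveltySpec",
    "GroundTruth",
    "synth_syllable",
    "generate_bout_labels",
    "synth_corpus",
    "synth_experiment",
    "default_archetypes",
    "default_novelty",
]

DEFAULT_SAMPLE_RATE = 40_000
#: ramp applied to syllable on/offsets, seconds
EDGE_RAMP_S = 0.003
#: background noise level relative to syllable peak, dB
DEFAULT_NOISE_FLOOR_DB = -40.0
#: bouts are peak-normalised to this full-scale value before WAV output
PEAK_NORM = 0.9

KINDS = ("harmonic_stack", "chirp", "noise_burst", "intro_note")


@dataclass(frozen=True)
class SyllableArchetype:
    """Acoustic template for one syllable type."""

    label: str
    kind: str
    f0_start: float = 600.0
    f0_end: float = 600.0
    n_harmonics: int = 1
    noise_band: tuple[float, float] | None = None
    duration_ms: float = 100.0
    amplitude: float = 0.8

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        if self.kind not in KINDS:
            raise ValueError(f"unknown syllable kind {self.kind!r}")
        if self.duration_ms < 5.0:
            raise ValueError(f"{self.label}: duration must be >= 5 ms")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError(f"{self.label}: amplitude must be in (0, 1]")
        if self.kind == "noise_burst":
            if self.noise_band is None:
                raise ValueError(f"{self.label}: noise_burst requires noise_band")
            lo, hi = self.noise_band
            if not (0.0 < lo < hi < nyq):
                raise ValueError(f"{self.label}: noise_band must lie in (0, Nyquist)")
        else:
            if not (0.0 < self.f0_start < nyq and 0.0 < self.f0_end < nyq):
                raise ValueError(
                    f"{self.label}: f0 {self.f0_start}-{self.f0_end} Hz outside (0, {nyq}) Hz"
                )
            if self.kind == "harmonic_stack" and self.n_harmonics < 1:
                raise ValueError(f"{self.label}: harmonic kinds need n_harmonics >= 1")


@dataclass(frozen=True)
class RenditionJitter:
    """Multiplicative rendition-to-rendition variability (fractional CVs)."""

    f0_cv: float = 0.0
    dur_cv: float = 0.0
    amp_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f0_cv", "dur_cv", "amp_cv"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")

    def draw(self, rng: np.random.Generator) -> tuple[float, float, float]:
        """Sample (f0, duration, amplitude) multipliers; clipped away from zero."""
        z = rng.standard_normal(3)
        f0m = max(0.2, 1.0 + self.f0_cv * z[0])
        durm = max(0.2, 1.0 + self.dur_cv * z[1])
        ampm = min(1.25, max(0.2, 1.0 + self.amp_cv * z[2]))
        return f0m, durm, ampm


@dataclass(frozen=True)
class SongGrammar:
    """Bout structure: intro notes, then repeated core motif with optional branching."""

    core_motif: tuple[str, ...]
    intro_label: str = "i"
    intro_count_range: tuple[int, int] = (1, 4)
    motifs_per_bout_range: tuple[int, int] = (2, 4)
    gap_ms: float = 50.0
    branch_prob: float = 0.0

    def __post_init__(self) -> None:
        if len(self.core_motif) == 0:
            raise ValueError("core_motif must be non-empty")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")
        if self.gap_ms <= 0:
            raise ValueError("gap_ms must be > 0")
        for lo, hi in (self.intro_count_range, self.motifs_per_bout_range):
            if lo < 0 or hi < lo:
                raise ValueError("count ranges must satisfy 0 <= min <= max")


@dataclass(frozen=True)
class NoveltySpec:
    """Injection of novel syllable types into the final-epoch song."""

    novel_archetypes: tuple[SyllableArchetype, ...]
    occurrence_prob: float = 0.6
    position_policy: str = "motif_end"
    extra_jitter: RenditionJitter = field(
        default_factory=lambda: RenditionJitter(f0_cv=0.05, dur_cv=0.08, amp_cv=0.08)
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.occurrence_prob <= 1.0):
            raise ValueError("occurrence_prob must be in [0, 1]")
        if self.position_policy not in ("motif_end", "uniform"):
            raise ValueError("position_policy must be 'motif_end' or 'uniform'")

    def validate_against(self, grammar: SongGrammar) -> None:
        novel = {a.label for a in self.novel_archetypes}
        base = set(grammar.core_motif) | {grammar.intro_label}
        overlap = novel & base
        if overlap:
            raise ValueError(f"novel labels overlap grammar labels: {sorted(overlap)}")


@dataclass
class GroundTruth:
    """Per-segment annotations for a synthetic corpus.

    ``table`` columns: bout, onset_s, offset_s, label, archetype, epoch.
    Segments within a bout are non-overlapping with strictly increasing onsets.
    """

    table: pd.DataFrame

    def bout_labels(self, bout: int) -> list[str]:
        sub = self.table[self.table["bout"] == bout]
        return sub["label"].tolist()

    @property
    def n_bouts(self) -> int:
        return int(self.table["bout"].nunique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False,
                          columns=["onset_s", "offset_s", "label", "archetype", "epoch", "bout"])


def _label_seed(label: str) -> int:
    """Stable per-label seed for frozen noise carriers (platform-independent)."""
    return zlib.crc32(label.encode("utf8")) & 0x7FFFFFFF


def _edge_ramp(n: int, sample_rate: float) -> np.ndarray:
    ramp_n = min(int(round(EDGE_RAMP_S * sample_rate)), n // 2)
    env = np.ones(n)
    if ramp_n > 0:
        r = 0.5 - 0.5 * np.cos(np.linspace(0.0, np.pi, ramp_n))
        env[:ramp_n] = r
        env[-ramp_n:] = r[::-1]
    return env


def synth_syllable(
    archetype: SyllableArchetype,
    jitter: RenditionJitter = RenditionJitter(),
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int | np.random.Generator = 0,
    noise_floor_db: float | None = None,
) -> np.ndarray:
    """Synthesise one jittered rendition of ``archetype``.

    Returns a float64 waveform peaking at ``archetype.amplitude`` times the
    drawn amplitude multiplier. If ``noise_floor_db`` is given, white Gaussian
    noise that many dB below the syllable peak is added (corpus synthesis adds
    bout-wide noise instead). Deterministic given ``seed``.
    """
    archetype.validate(sample_rate)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f0m, durm, ampm = jitter.draw(rng)

    dur_s = archetype.duration_ms / 1000.0 * durm
    n = max(int(round(dur_s * sample_rate)), int(round(0.005 * sample_rate)))
    t = np.arange(n) / sample_rate
    nyq = sample_rate / 2.0

    if archetype.kind == "noise_burst":
        lo, hi = archetype.noise_band
        carrier_rng = np.random.default_rng(_label_seed(archetype.label))
        x = carrier_rng.standard_normal(n)
        sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
        x = sps.sosfiltfilt(sos, x)
    else:
        f0a = archetype.f0_start * f0m
        f0b = archetype.f0_end * f0m
        if max(f0a, f0b) >= nyq:
            raise ValueError(
                f"{archetype.label}: jittered f0 {max(f0a, f0b):.0f} Hz reaches Nyquist"
            )
        inst_f = f0a + (f0b - f0a) * (t / max(t[-1], 1e-9))
        phase = 2.0 * np.pi * np.cumsum(inst_f) / sample_rate
        if archetype.kind == "harmonic_stack":
            x = np.zeros(n)
            for h in range(1, archetype.n_harmonics + 1):
                if h * max(f0a, f0b) >= nyq:
                    break  # drop aliased partials
                x += np.sin(h * phase) / h
        else:  # chirp / intro_note
            x = np.sin(phase)

    x = x * _edge_ramp(n, sample_rate)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * min(archetype.amplitude * ampm, 1.0)
    if noise_floor_db is not None:
        sigma = np.max(np.abs(x)) * 10.0 ** (noise_floor_db / 20.0)
        x = x + sigma * rng.standard_normal(n)
    return x


def generate_bout_labels(
    grammar: SongGrammar,
    novelty: NoveltySpec | None,
    rng: np.random.Generator,
) -> list[str]:
    """Draw one bout's label sequence (fast path: no audio).

    Intro notes, then ``motifs_per_bout`` motif renditions. At each within-motif
    transition the scheduled label is replaced with a different random core
    label with probability ``branch_prob``. If ``novelty`` is given, each motif
    rendition is followed (policy ``motif_end``) or interrupted at a uniform
    position (policy ``uniform``) by one novel label with probability
    ``occurrence_prob``.
    """
    labels: list[str] = []
    lo, hi = grammar.intro_count_range
    labels.extend([grammar.intro_label] * int(rng.integers(lo, hi + 1)))
    mlo, mhi = grammar.motifs_per_bout_range
    n_motifs = int(rng.integers(mlo, mhi + 1))
    core = list(grammar.core_motif)
    for _ in range(n_motifs):
        motif = [core[0]]
        for lab in core[1:]:
            if grammar.branch_prob > 0 and rng.random() < grammar.branch_prob:
                alternatives = [c for c in core if c != lab] or core
                lab = alternatives[int(rng.integers(len(alternatives)))]
            motif.append(lab)
        if novelty is not None and novelty.novel_archetypes and rng.random() < novelty.occurrence_prob:
            novel = novelty.novel_archetypes[int(rng.integers(len(novelty.novel_archetypes)))]
            if novelty.position_policy == "motif_end":
                motif.append(novel.label)
            else:
                motif.insert(int(rng.integers(1, len(motif) + 1)), novel.label)
        labels.extend(motif)
    return labels


def _combined_jitter(base: RenditionJitter, extra: RenditionJitter) -> RenditionJitter:
    return RenditionJitter(
        f0_cv=min(0.5, base.f0_cv + extra.f0_cv),
        dur_cv=min(0.5, base.dur_cv + extra.dur_cv),
        amp_cv=min(0.5, base.amp_cv + extra.amp_cv),
    )


def synth_corpus(
    grammar: SongGrammar,
    jitter: RenditionJitter,
    archetypes: dict[str, SyllableArchetype],
    novelty: NoveltySpec | None = None,
    n_bouts: int = 50,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    noise_floor_db: float | None = DEFAULT_NOISE_FLOOR_DB,
    epoch: str = "baseline",
) -> tuple[list[np.ndarray], GroundTruth]:
    """Synthesise ``n_bouts`` song bouts with exact ground-truth annotations.

    Background noise is white Gaussian at ``noise_floor_db`` relative to the
    loudest syllable peak of the bout (None disables it; renditions are then
    bit-identical under zero jitter). Bouts are peak-normalised to 0.9 full
    scale. Deterministic given ``seed``.
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    missing = set(grammar.core_motif) - set(archetypes)
    if missing:
        raise ValueError(f"no archetype for core labels: {sorted(missing)}")
    if grammar.intro_label not in archetypes:
        raise ValueError(f"no archetype for intro label {grammar.intro_label!r}")
    if novelty is not None:
        novelty.validate_against(grammar)
        archetypes = dict(archetypes)
        for a in novelty.novel_archetypes:
            archetypes[a.label] = a
    for a in archetypes.values():
        a.validate(sample_rate)

    rng = np.random.default_rng(seed)
    novel_labels = {a.label for a in novelty.novel_archetypes} if novelty else set()
    waveforms: list[np.ndarray] = []
    rows: list[dict] = []
    lead_s = 0.1  # silence before the first / after the last syllable

    for b in range(n_bouts):
        labels = generate_bout_labels(grammar, novelty, rng)
        pieces: list[np.ndarray] = []
        cursor = lead_s
        bout_rows = []
        for lab in labels:
            jit = jitter
            if lab in novel_labels:
                jit = _combined_jitter(jitter, novelty.extra_jitter)
            w = synth_syllable(archetypes[lab], jit, sample_rate, rng, noise_floor_db=None)
            dur = len(w) / sample_rate
            bout_rows.append(
                dict(bout=b, onset_s=cursor, offset_s=cursor + dur, label=lab,
                     archetype=archetypes[lab].label, epoch=epoch)
            )
            pieces.append(w)
            gap_s = grammar.gap_ms / 1000.0 * max(0.2, 1.0 + jitter.dur_cv * rng.standard_normal())
            cursor += dur + gap_s
        total_n = int(round((bout_rows[-1]["offset_s"] + lead_s) * sample_rate))
        bout = np.zeros(total_n)
        for row, w in zip(bout_rows, pieces):
            i0 = int(round(row["onset_s"] * sample_rate))
            bout[i0:i0 + len(w)] += w
        peak = np.max(np.abs(bout))
        if noise_floor_db is not None and peak > 0:
            bout = bout + peak * 10.0 ** (noise_floor_db / 20.0) * rng.standard_normal(total_n)
        peak = np.max(np.abs(bout))
        if peak > 0:
            bout = bout * (PEAK_NORM / peak)
        waveforms.append(bout)
        rows.extend(bout_rows)

    gt = GroundTruth(pd.DataFrame(rows))
    return waveforms, gt


def synth_experiment(
    grammar: SongGrammar,
    jitter: RenditionJitter,
    archetypes: dict[str, SyllableArchetype],
    novelty: NoveltySpec | None,
    n_bouts_per_epoch: int = 50,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    noise_floor_db: float | None = DEFAULT_NOISE_FLOOR_DB,
) -> dict[str, tuple[list[np.ndarray], GroundTruth]]:
    """Baseline epoch (no novelty) plus final epoch (with novelty, if any)."""
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    baseline = synth_corpus(grammar, jitter, archetypes, None, n_bouts_per_epoch,
                            sample_rate, int(child[0]), noise_floor_db, epoch="baseline")
    final = synth_corpus(grammar, jitter, archetypes, novelty, n_bouts_per_epoch,
                         sample_rate, int(child[1]), noise_floor_db, epoch="final")
    return {"baseline": baseline, "final": final}


def default_archetypes(n_types: int = 5) -> tuple[SongGrammar, dict[str, SyllableArchetype]]:
    """A stereotyped 5-syllable repertoire plus introductory note.

    Harmonic stacks and chirps spanning the zebra-finch range, ~60-160 ms,
    with a 30 ms soft introductory up-chirp.
    """
    templates = [
        SyllableArchetype("A", "harmonic_stack", 620.0, 620.0, n_harmonics=6, duration_ms=120),
        SyllableArchetype("B", "chirp", 2200.0, 4200.0, duration_ms=80),
        SyllableArchetype("C", "harmonic_stack", 950.0, 780.0, n_harmonics=5, duration_ms=150),
        SyllableArchetype("D", "chirp", 5200.0, 3100.0, duration_ms=60),
        SyllableArchetype("E", "harmonic_stack", 1400.0, 1400.0, n_harmonics=4, duration_ms=100),
        SyllableArchetype("F", "chirp", 3000.0, 6500.0, duration_ms=90),
        SyllableArchetype("G", "harmonic_stack", 480.0, 700.0, n_harmonics=7, duration_ms=130),
    ]
    if not (1 <= n_types <= len(templates)):
        raise ValueError(f"n_types must be in 1..{len(templates)}")
    arch = {a.label: a for a in templates[:n_types]}
    intro = SyllableArchetype("i", "intro_note", 500.0, 1500.0, duration_ms=30, amplitude=0.35)
    arch["i"] = intro
    grammar = SongGrammar(core_motif=tuple(a for a in sorted(arch) if a != "i"))
    return grammar, arch


def default_novelty(n_novel: int = 2, occurrence_prob: float = 0.6,
                    position_policy: str = "motif_end") -> NoveltySpec:
    """Novel archetypes of kinds absent from the default baseline repertoire.

    Noise bursts (and, beyond two, widely detuned chirps), so cross-similarity
    to the pre-existing harmonic/chirp types is low by construction.
    """
    templates = [
        SyllableArchetype("X", "noise_burst", noise_band=(2500.0, 7500.0), duration_ms=110),
        SyllableArchetype("Y", "noise_burst", noise_band=(800.0, 2600.0), duration_ms=140),
        SyllableArchetype("Z", "noise_burst", noise_band=(4500.0, 9000.0), duration_ms=70),
        SyllableArchetype("W", "chirp", 7800.0, 7200.0, duration_ms=180),
        SyllableArchetype("V", "noise_burst", noise_band=(300.0, 1200.0), duration_ms=90),
        SyllableArchetype("U", "chirp", 8800.0, 8800.0, duration_ms=50),
        SyllableArchetype("T", "noise_burst", noise_band=(6000.0, 9500.0), duration_ms=160),
    ]
    if not (0 <= n_novel <= len(templates)):
        raise ValueError(f"n_novel must be in 0..{len(templates)}")
    return NoveltySpec(tuple(templates[:n_novel]), occurrence_prob=occurrence_prob,
                       position_policy=position_policy)
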