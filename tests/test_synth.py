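"""Synthetic song generator: determinism, jitter calibration, grammar."""

import numpy as np
import pytest

from finchsong.synth import (
    NoveltySpec,
    RenditionJitter,
    SongGrammar,
    SyllableArchetype,
    default_archetypes,
    default_novelty,
    generate_bout_labels,
    synth_corpus,
    synth_syllable,
)

SR = 40_000


class TestSynthSyllable:
    def test_zero_jitter_harmonic_stack_duration_and_spectrum(self):
        arch = SyllableArchetype("h", "harmonic_stack", 600.0, 600.0, n_harmonics=3,
                                 duration_ms=120)
        w = synth_syllable(arch, RenditionJitter(), SR, seed=1)
        assert len(w) == int(0.120 * SR)
        spec = np.abs(np.fft.rfft(w))
        freqs = np.fft.rfftfreq(len(w), 1 / SR)
        # the three tallest spectral peaks sit at the three harmonics
        order = np.argsort(spec)[::-1]
        top = set()
        for k in order:
            if all(abs(freqs[k] - freqs[j]) > 100 for j in top):
                top.add(k)
            if len(top) == 3:
                break
        found = sorted(freqs[k] for k in top)
        assert np.allclose(found, [600, 1200, 1800], atol=15)

    def test_same_seed_bit_identical(self):
        arch = SyllableArchetype("h", "harmonic_stack", 600.0, 600.0, n_harmonics=3,
                                 duration_ms=120)
        a = synth_syllable(arch, RenditionJitter(0.1, 0.1, 0.1), SR, seed=1)
        b = synth_syllable(arch, RenditionJitter(0.1, 0.1, 0.1), SR, seed=1)
        assert np.array_equal(a, b)

    def test_duration_jitter_calibrated(self):
        """Monte-Carlo: realized duration CV matches the requested dur_cv."""
        arch = SyllableArchetype("c", "chirp", 2000.0, 4000.0, duration_ms=100)
        jit = RenditionJitter(dur_cv=0.1)
        durs = np.array([
            len(synth_syllable(arch, jit, SR, seed=s)) / SR for s in range(200)
        ])
        cv = durs.std() / durs.mean()
        assert abs(cv - 0.1) < 0.03

    def test_f0_above_nyquist_rejected(self):
        arch = SyllableArchetype("bad", "chirp", 2000.0, 30000.0, duration_ms=50)
        with pytest.raises(ValueError):
            synth_syllable(arch, RenditionJitter(), SR, seed=0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="5 ms"):
            SyllableArchetype("s", "chirp", 1000.0, 1000.0, duration_ms=2).validate(SR)


class TestGrammar:
    def test_zero_branching_bouts_follow_core_motif(self):
        grammar, archetypes = default_archetypes(4)
        _, gt = synth_corpus(grammar, RenditionJitter(), archetypes, None,
                             n_bouts=10, seed=5, noise_floor_db=None)
        core = list(grammar.core_motif)
        for b in range(10):
            labels = gt.bout_labels(b)
            body = [l for l in labels if l != "i"]
            assert labels[: len(labels) - len(body)] == ["i"] * (len(labels) - len(body))
            assert len(body) % len(core) == 0
            for k in range(0, len(body), len(core)):
                assert body[k : k + len(core)] == core

    def test_occurrence_prob_one_appends_novel_after_every_motif(self):
        grammar, archetypes = default_archetypes(4)
        novelty = default_novelty(1, occurrence_prob=1.0, position_policy="motif_end")
        _, gt = synth_corpus(grammar, RenditionJitter(), archetypes, novelty,
                             n_bouts=5, seed=2, noise_floor_db=None)
        core_end = grammar.core_motif[-1]
        for b in range(5):
            labels = gt.bout_labels(b)
            for i, lab in enumerate(labels):
                if lab == core_end:
                    assert labels[i + 1] == "X"

    def test_occurrence_prob_binomial(self):
        """~30% of motif renditions carry a novel syllable at p=0.3."""
        grammar, _ = default_archetypes(4)
        novelty = default_novelty(1, occurrence_prob=0.3)
        rng = np.random.default_rng(7)
        n_motifs = 0
        n_novel = 0
        while n_motifs < 500:
            labels = generate_bout_labels(grammar, novelty, rng)
            body = [l for l in labels if l != "i"]
            n_motifs += body.count(grammar.core_motif[0])
            n_novel += body.count("X")
        assert abs(n_novel / n_motifs - 0.3) < 0.05

    def test_empty_grammar_rejected(self):
        with pytest.raises(ValueError):
            SongGrammar(core_motif=())

    def test_novel_labels_must_be_disjoint(self):
        grammar, _ = default_archetypes(4)
        clash = NoveltySpec((SyllableArchetype("A", "noise_burst",
                                               noise_band=(1000.0, 4000.0)),))
        with pytest.raises(ValueError, match="overlap"):
            clash.validate_against(grammar)


class TestCorpusInvariants:
    def test_ground_truth_segments_disjoint_and_sorted(self):
        grammar, archetypes = default_archetypes(5)
        _, gt = synth_corpus(grammar, RenditionJitter(0.05, 0.1, 0.1), archetypes,
                             default_novelty(2), n_bouts=8, seed=3)
        for b in range(8):
            sub = gt.table[gt.table["bout"] == b]
            on = sub["onset_s"].values
            off = sub["offset_s"].values
            assert np.all(np.diff(on) > 0)
            assert np.all(off > on)
            assert np.all(on[1:] >= off[:-1])

    def test_gaps_near_grammar_gap(self):
        grammar, archetypes = default_archetypes(5)
        _, gt = synth_corpus(grammar, RenditionJitter(), archetypes, None,
                             n_bouts=4, seed=9, noise_floor_db=None)
        for b in range(4):
            sub = gt.table[gt.table["bout"] == b]
            gaps = sub["onset_s"].values[1:] - sub["offset_s"].values[:-1]
            assert np.allclose(gaps, grammar.gap_ms / 1000.0, atol=1e-9)

    def test_zero_jitter_renditions_bit_identical(self):
        from dataclasses import replace

        grammar, archetypes = default_archetypes(4)
        novelty = replace(default_novelty(1, occurrence_prob=1.0),
                          extra_jitter=RenditionJitter())
        waves, gt = synth_corpus(grammar, RenditionJitter(), archetypes,
                                 novelty, n_bouts=2, seed=4, noise_floor_db=None)
        for lab in list(grammar.core_motif) + ["X"]:
            chunks = []
            for _, row in gt.table[gt.table["label"] == lab].iterrows():
                w = waves[int(row["bout"])]
                i0 = int(round(row["onset_s"] * SR))
                i1 = int(round(row["offset_s"] * SR))
                chunks.append(w[i0:i1] / np.max(np.abs(w[i0:i1])))
            for c in chunks[1:]:
                assert len(c) == len(chunks[0])
                assert np.allclose(c, chunks[0], atol=1e-12)

    def test_same_seed_regenerates_identical_corpus(self):
        grammar, archetypes = default_archetypes(5)
        a, gta = synth_corpus(grammar, RenditionJitter(0.02, 0.05, 0.05), archetypes,
                              default_novelty(2), n_bouts=3, seed=11)
        b, gtb = synth_corpus(grammar, RenditionJitter(0.02, 0.05, 0.05), archetypes,
                              default_novelty(2), n_bouts=3, seed=11)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert gta.table.equals(gtb.table)

    def test_n_bouts_validated(self):
        grammar, archetypes = default_archetypes(4)
        with pytest.raises(ValueError):
            synth_corpus(grammar, RenditionJitter(), archetypes, None, n_bouts=0, seed=0)
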