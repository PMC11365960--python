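# finchsong

Analysis toolkit for detecting and characterizing **vocal repertoire
expansion** in adult zebra finch song: did a bird, after some manipulation or
experience, start producing syllable types it never sang before — and if so,
how many, how acoustically distinct are they, and where do they sit in the
song's syntax?

The package is aimed at birdsong/bioacoustics researchers who record
baseline and post-manipulation song epochs and want a reproducible,
scriptable version of the classical analysis chain:

1. **Segmentation** — syllables are detected as supra-threshold runs of the
   RMS amplitude envelope (frame 5 ms, hop 1 ms), exploiting the ~50 ms
   silent gaps between zebra-finch syllables; sub-5 ms events are discarded
   and sub-5 ms dips merged.
2. **Spectral features** — per frame (9.27 ms Gaussian window, 1 ms hop):
   pitch and goodness of pitch from the power cepstrum, Wiener entropy
   ln(geometric mean / arithmetic mean of the in-band power spectrum),
   frequency modulation, amplitude modulation, and amplitude.
3. **Percent similarity** — two renditions are linearly time-rescaled to a
   common length; a frame pair is *similar* when its Euclidean distance in
   median/MAD-scaled feature space is below the median background distance
   of the reference corpus; the score is 100 × the similar-frame fraction,
   computed symmetrically across the time course.
4. **Novelty criterion** — for a candidate type `c` and each pre-existing
   type `p` with self-similarity mean μ_p and standard deviation σ_p
   (over pairwise rendition comparisons), `c` is **novel** iff

   cross(c, p) < μ_p − 1.96 σ_p  for *every* pre-existing `p`.

5. **Clustering cross-check** — per-syllable feature summaries (mean and
   std of the six features plus duration) are embedded with UMAP and
   clustered with HDBSCAN; clusters ≥ 95% composed of final-epoch syllables
   count as new.
6. **Sequence statistics** — transition matrices and two stereotypy ratios:

   - sequence linearity = #different notes / #transition types,
   - sequence consistency = Σ typical (modal) transitions / Σ total
     transitions,

   both equal to 1 for a perfectly stereotyped song, plus a
   relative-probability histogram of novel-syllable positions with respect
   to motif ends (bin 0 = immediately after the motif's last syllable).

Because suitable public recordings are scarce, the package ships a
first-class **synthetic song generator** (`finchsong.synth`) producing
WAV-level corpora — introductory notes, a stereotyped 4–7 syllable motif
with rendition jitter, ~50 ms gaps, background noise, and an optional
"final" epoch with injected novel syllable types — together with exact
ground-truth annotations, so every stage is testable end to end.

## Worked example

Run the full baseline-vs-final analysis on a synthetic bird (5 pre-existing
syllable types A–E, 2 injected novel types X/Y appended after motif ends,
50 bouts per epoch, 40 dB SNR):

```bash
finchsong run-all --seed 42 --out demo_run
# novel types (feature route): 2; new clusters: 2; report -> demo_run/report.json
```

`demo_run/report.json` then contains (abridged):

```
self_stats   A: 96.50 ± 2.58   B: 99.85 ± 1.00   C: 93.31 ± 3.67
             D: 99.96 ± 1.00   E: 99.74 ± 1.00        (percent, 45 pairs each)
cross X      A: 0.0  B: 0.0  C: 0.0  D: 0.0  E: 0.0
verdict X    margins all < 0 (e.g. A: -91.44)  ->  is_novel: true
n_novel_feature_route: 2      n_new_clusters: 2
sequence     baseline: linearity 1.000, consistency 1.000
             final:    linearity 0.778, consistency 0.902
position_histogram: all mass in bin 0 (94 occurrences)
```

Reading: the five baseline types are highly self-similar (means 93–100%);
the injected noise-burst type X scores ~0% against every one of them, far
below each type's μ − 1.96σ threshold, so both the feature route and the
UMAP+HDBSCAN route report exactly the 2 injected types. Appending novel
syllables leaves the core motif intact but makes formerly-terminal
transitions variable, so consistency drops while the baseline epoch stays
perfectly stereotyped; every novel occurrence falls immediately after a
motif end (bin 0).

Individual stages are available as `finchsong synth|segment|features|
similarity|sequence` operating on WAV/CSV artifacts, and as plain library
functions.

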