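# Methods

This note documents the models, parameters and numerical choices behind
`finchsong`, and what the synthetic-data experiments do and do not show.

## Synthetic song model

A corpus is a set of *bouts*. Each bout is 1–4 introductory notes followed
by 2–4 renditions of a fixed *core motif* (default: five syllable types
A–E), with 50 ms silent gaps between syllables. Syllable renditions are
rendered from archetypes:

- `harmonic_stack` — harmonics of a (possibly sweeping) f0 with 1/h
  amplitude decay; partials reaching Nyquist are dropped;
- `chirp` — a single linearly swept tone;
- `noise_burst` — Butterworth band-passed Gaussian noise. The noise carrier
  is seeded from a stable hash of the label ("frozen noise"), so renditions
  of a type differ only through jitter; with zero jitter they are
  bit-identical, which the test suite uses as an exactness oracle;
- `intro_note` — a 30 ms, low-amplitude up-chirp.

Rendition-to-rendition variability is multiplicative Gaussian jitter on f0,
duration and amplitude with fractional CVs (defaults 0.02/0.05/0.05;
multipliers are clipped to [0.2, 1.25] so draws stay physical). The paper
trail for real zebra-finch rendition jitter is thin, so these defaults are
free parameters chosen to put zero-jitter self-similarity at exactly 100%
and realistic-jitter self-similarity in the mid-90s; they are exposed in
the config and should not be read as measured biology.

Each syllable has 3 ms raised-cosine on/offset ramps. Bout-wide white
Gaussian background noise sits 40 dB below the loudest syllable peak
(an easy but realistic floor for segmentation), and bouts are
peak-normalised to 0.9 full scale before WAV output (32-bit float mono,
40 kHz default).

The "final" epoch optionally injects novel archetypes of kinds absent from
the baseline repertoire (noise bursts and widely detuned chirps), so
cross-similarity to pre-existing types is low by construction. After each
motif rendition, with probability `occurrence_prob` (default 0.6) one novel
syllable is appended at the motif end (or inserted at a uniform position,
policy `uniform`). Novel types carry extra jitter (default +0.05/+0.08/+0.08
CV) to emulate their elevated variability. The 0.6 default occurrence rate
gives each of two novel types roughly 40+ renditions in a 50-bout epoch —
enough for cluster-level detection at the default minimum cluster size (25)
while keeping novel syllables a minority of the song.

What the generator does **not** emulate: syringeal biomechanics, amplitude
and spectral co-modulation within syllables, calls, cage noise, overlapping
birds, or drift over days. Passing tests on this generator therefore
demonstrate the *computational* correctness and discriminative structure of
the pipeline, not field-readiness for arbitrary recordings.

## Segmentation

RMS envelope per 5 ms frame at 1 ms hop, in dB re full scale, clamped at
−120 dB. The automated threshold tracks the noise floor: envelope's 20th
percentile + 10 dB (mode `percentile`); a `fixed_db` mode (threshold at a
fixed offset above a 5th-percentile floor estimate) is retained for
reproducibility across files. Supra-threshold runs are merged across gaps
shorter than 5 ms (within-syllable amplitude dips must not split
syllables — real inter-syllable gaps are ~50 ms), and runs shorter than the
5 ms minimum syllable length are discarded. Because a 5 ms analysis frame
smears boundaries by up to a frame, each detected run is refined at sample
resolution with a 1 ms sliding window against the same threshold; on
synthetic corpora at 40 dB SNR recovered boundaries sit well within 1 ms of
ground truth, and a 3 ms click is correctly rejected by the duration filter
only because of this refinement. Times are seconds from file start,
half-open [onset, offset).

## Spectral features

Six per-frame features (9.27 ms Gaussian-windowed FFT — 371 samples at
40 kHz — at 1 ms hop, analysis band 300–8000 Hz):

| feature | definition | units |
|---|---|---|
| pitch | quefrency peak of the power cepstrum | Hz |
| goodness | that peak's height / lag-0 power | – (0–1) |
| Wiener entropy | ln(gmean/amean) of in-band power | ≤ 0 |
| FM | arctan(‖∂log S/∂t‖ / ‖∂log S/∂f‖) | rad |
| AM | d(log amplitude)/dt | 1/s |
| amplitude | frame RMS | dB re FS |

Numerical choices worth knowing:

- The single-taper periodogram is lightly smoothed (5-bin moving average)
  before the entropy computation; without it the χ² fluctuations of a raw
  periodogram bias white-noise entropy to −γ ≈ −0.58 rather than ≈ 0.
  This smoothing stands in for multitaper variance reduction.
- Pitch uses the **power** cepstrum (inverse FFT of the power spectrum,
  i.e. the windowed-frame autocorrelation) rather than the log-spectrum
  cepstrum: the latter's quefrency envelope is set by the spectral bump
  width and biases narrowband pitch estimates ~1–2 bins low, while the
  power-cepstrum envelope is window-limited and resolves a 1 kHz tone to
  within one quefrency bin after parabolic interpolation. The search keeps
  to interior local maxima (the decaying envelope otherwise wins at the
  search edge) and applies octave-error suppression: the smallest lag
  within 90% of the strongest peak is taken.
- Unvoiced frames keep their (low-goodness) pitch estimate; no missing
  data ever reaches the distance computation.
- Gain invariance: scaling the waveform leaves pitch, goodness, entropy
  and FM unchanged; amplitude shifts by the gain and is the only feature
  carrying level information.

Absolute numerical parity with SAP2011 is explicitly out of scope; only
relative comparisons between scores are interpreted.

## Percent similarity

For two renditions, both feature tracks are linearly rescaled in time to
K frames (K = rounded mean of the two lengths; time alignment by linear
rescaling, not DTW — the simplest contract that is symmetric across the
time course). Features are scaled by per-feature median/MAD estimated from
a reference corpus (MAD floored at 1e-6), all six features weighted
equally. A frame pair is *similar* when its Euclidean distance is below
the q-quantile (default q = 0.5) of distances between random frame pairs of
the reference corpus; the score is 100 × the similar-frame fraction. The
pairing is identical in both argument orders, so symmetry is exact, and
score(x, x) = 100 identically.

Absolute score levels depend on the reference corpus: with a heterogeneous
multi-type reference the background median is dominated by between-type
distances and within-type scores saturate near 100; resolution *within* a
type requires a same-type (or otherwise homogeneous) reference. q is
exposed in the config for the same reason.

Self-similarity statistics use the first 10 renditions of a type (all 45
pairs; sample std, ddof = 1). ECD curves report the right-continuous ECDF
at the sorted scores with pointwise 2.5/97.5 bootstrap percentile bands
(default 1000 resamples, seeded), clamped to bracket the point curve.

## Novelty

The z-criterion is one-sided below (novelty means *lower* similarity):
candidate c is novel iff cross(c, p) < μ_p − z·σ_p for every pre-existing
type p, with z = 1.96 and σ_p each type's own self-similarity std. A pooled
variant (all pre-existing self scores lumped) is provided for sensitivity
analyses; per-type is the default because the criterion quantifies over
"all other syllables". Raising z strictly tightens the criterion — verdicts
are monotone non-increasing in z.

In the pipeline the self std entering the rule is floored at 1 percentage
point: scores are quantised at ~100/K for K compared frames, so an observed
std of exactly 0 (common for highly stereotyped types) understates the true
dispersion and would declare *any* imperfect match novel, including the
type's own final-epoch renditions.

The cross-check embeds 13-dimensional per-syllable summaries (mean and std
of the six features, plus duration), z-scored, with UMAP (2-D, 15
neighbours, min_dist 0.1, fixed seed) and clusters with HDBSCAN (minimum
cluster size 25). HDBSCAN noise points are excluded; a cluster counts as
new when ≥ 95% of its members are final-epoch (the purity threshold is a
design choice — the qualitative claim "new clusters emerge" needs *some*
cut-off, and 95% tolerates occasional mislabelled baseline stragglers).

Distribution comparisons (Kruskal–Wallis, Wilcoxon signed-rank/rank-sum,
Friedman) delegate to scipy.stats.

## Sequence statistics

Transitions are ordered adjacent label pairs within a bout; never across
bout boundaries (bouts are separated by seconds of silence). Introductory
notes are excluded by default (toggle available), since they are annotated
as a separate category and would otherwise dominate the branching
structure. Both stereotypy ratios are computed pooled over the analysed
bout set ("per song"); a per-bout mode can be had by passing single-bout
lists. The typical transition of a source label is its modal successor,
ties broken towards the earliest-observed successor (the classical
definition leaves ties open; earliest-observed is deterministic and
order-stable).

For the novel-position histogram, completed core motifs are located in the
bout's core-syllable subsequence (greedy non-overlapping left-to-right
match of the configured motif; partial renditions do not count as ends).
Each novel occurrence is assigned the signed offset, in core-syllable
steps, from the end of its containing or nearest-preceding completed
motif: 0 = immediately after the motif's last syllable, negative = inside
the motif. Occurrences preceding any completed motif are skipped and
reported.

## Pipeline

Synthetic mode: baseline epoch (no novelty) and final epoch (with novelty)
are generated, segmented, and detections are labelled by maximal overlap
(> 0.5 of the interval union) with ground truth — this stands in for the
study-style manual labelling; unmatched detections are dropped. The
feature scaling is estimated from the baseline epoch only, candidate types
are all final-epoch types with ≥ 2 renditions, and each is judged against
all baseline types. WAV mode consumes per-file annotation CSVs instead,
splitting bouts at silent gaps > 2 s.

Reports carry a SHA-256 hash of the canonicalised config; every number in
a report is recomputed from the on-disk intermediates written next to it.
With a fixed seed, synthetic-mode runs are bit-reproducible end to end
(the UMAP embedding is seeded and single-threaded).

## Problem sizes and validation scenarios

The validation suite runs at deliberately desk-scale sizes chosen as the
package's own study conditions: 50 bouts per epoch (matching the "first 50
song bouts" convention for sequence analysis), 5 baseline types, 2 injected
novel types, 40 dB SNR, 10 generator seeds for the novelty
recovery/specificity sweep, and 20 seeds for the sequence-structure
comparison. The sequence-structure scenario uses a baseline grammar with
branch probability 0.15: real adult song is not perfectly linear, and on a
perfectly linear baseline (linearity ≡ 1) *any* added syllable type
maximally perturbs the linearity ratio, which would misrepresent the
phenomenon being emulated — rare end-appended novel syllables leaving the
core sequence intact (consistency drops, linearity barely moves).

## Known limitations

- Similarity scores are not SAP2011-calibrated; absolute percentages are
  corpus-dependent (see above) and only contrasts are meaningful.
- The cepstral pitch is undefined-but-finite on noise frames; downstream
  weighting by goodness is left to the user.
- The segmenter assumes a single bird with silent gaps; overlapping
  vocalisations and bout detection across files are out of scope.
- The cluster count depends on min_cluster_size relative to novel-type
  rendition counts; rare novel types (few renditions) are detectable by
  the feature route well before the cluster route.
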