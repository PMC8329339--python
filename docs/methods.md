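# Methods

## Representation and algebra

All information is carried by dense binary hypervectors: 1-D uint8 arrays
of dimension D (default 10,000) with i.i.d. fair-coin components.  At this
dimension the normalized Hamming distance (NHD) between independent
vectors is Binomial(D, ½)/D, i.e. 0.5 with standard deviation
1/(2√D) = 0.005, so unrelated vectors are reliably ~0.5 apart and anything
substantially closer is signal.  The three operations:

- `bind(A, B) = A XOR B`.  Commutative, associative, self-inverse,
  distance-preserving (`nhd(A⊕C, B⊕C) = nhd(A, B)`), and the result is
  quasi-orthogonal to both factors.
- `bundle([V₁…Vₙ])`: componentwise majority.  For three random inputs the
  expected NHD from bundle to each input is exactly ¼ (a bundle bit
  differs from V₁'s only when V₂ and V₃ both disagree with it:
  probability ¼).  With even n, tied components are resolved by
  independent fair coins from an explicit generator.  Implementation
  detail: the tie-break draws one coin per *component* and keeps only the
  tied positions (equivalent to raising the majority threshold by the
  coin); this is distributionally identical to flipping coins only at
  ties and vectorizes without a mask-indexing pass.
- `permute(A, k)`: circular shift; bijective and distance-preserving.

The tie RNG is deliberately a *parameter*, separate from the item-memory
seed: item memories must be reproducible regardless of how many bundling
calls preceded them.  Inside the encoder, window w of a recording uses a
generator seeded from `(tie_seed, w)`, so re-running a detection — or
encoding the same window in isolation — is bit-reproducible.

## Item memory and cleanup

`build_item_memory(L, n_electrodes, D, seed)` draws `2^(L-1)` symbol
vectors then `n_electrodes` electrode vectors from one seeded stream; the
memory is a pure function of those four integers and is serialized as
exactly that 4-tuple.  Cleanup is exact nearest-neighbor search by NHD,
computed through one float32 matrix product (Hamming distance =
|q|₁ + |s|₁ − 2 q·s, exact in float32 for these ranges); distance ties
resolve to the smallest index so classification is deterministic.

Noise tolerance: with a 256-item store at D = 10,000, the distance from a
corrupted vector to its original at flip fraction f is ~f ± 0.005 while
all other items stay at 0.5 ± 0.005, so recovery remains ≥ 99 % well past
30 % flips (the sweep in `scripts/acceptance.py` measures the largest
5-percent level that still recovers at ≥ 99 %, typically 45 %) and falls
to chance (1/256) only at f = 0.5.

## Symbolization

Order relations with "≥" semantics: bit j of a length-L window is 1 iff
x_{j+1} ≥ x_j, read most-significant-bit-first into a symbol index.
Equality counts as ≥, so flat digitized runs map to the all-ones pattern —
the literal rule, adopted because nothing in the method depends on how
equality ties are labeled (all symbol vectors are random anyway; the
bijection only matters for cross-implementation bit-compatibility).
Symbolization is stride-1 (maximal overlap): T samples → T−L+1 symbols.
Default L = 9 (256-symbol alphabet); L = 3 appears in didactic tests.
The symbol sequence is invariant under any positive affine rescaling of
the signal, so no amplitude normalization is needed or performed.

## Encoding and one-shot learning

Spatial composite at one timestep: bind each channel's symbol vector to
its electrode vector, bundle across channels.  Spatiotemporal composite of
a window: bundle the spatial composites of every timestep in the window
(504 of them for 1 s at 512 Hz, L = 9).  Windows are symbolized
independently — patterns do not straddle window boundaries — a choice made
for streaming simplicity; it discards L−1 columns per boundary
(8 of 512, <2 % of the data).

A prototype is the bundle of the ST vectors of a reference period split
into non-overlapping 1 s windows (`window_s`/`stride_s` are configurable;
30 s references give k = 30).  Learning is structurally single-pass, and
classification encodes queries through the same `spatiotemporal_encode`
code path.

The count-accumulation hot loop runs through a numba JIT kernel with a
bit-identical pure-numpy reference implementation kept alongside (a unit
test asserts equality); on one CPU a 60-channel, 1 s, D = 10,000 window
encodes in ~40 ms.

## Detection

Δ = NHD(Q, P_int) − NHD(Q, P_ict) ∈ [−1, 1]; antisymmetric under swapping
the prototypes.  Events: maximal runs of windows with Δ > θ whose span
(first window start to last window end) is at least τ seconds; any
supra-threshold run resuming within ρ seconds of the current event's
offset is merged into it.  Defaults θ = 0 (the sign rule), τ = 5 s,
ρ = 30 s; θ and τ trade sensitivity against false detections and are the
knobs a user would tune per patient.  Event onset is the first
supra-threshold window, not the end of the τ confirmation, so reported
latencies are not inflated by τ.

A caveat worth knowing: the event *count* is monotone non-increasing in τ
for any trace, but monotone in θ only for typical Δ traces (flat noisy
baseline plus smooth seizure excursions).  An adversarial trace whose
long supra-threshold run splits, at a higher θ, into two qualifying runs
separated by more than ρ gains an event; with ρ covering the trace the
count is 0/1 and provably monotone.  The test suite checks both regimes.

Evaluation uses standard interval-overlap matching: a label is detected if
any event overlaps it, an event overlapping no label is false (normalized
per hour), latency = matched onset − label onset.

## Synthetic data

The generator produces the study conditions end to end: 60 channels at
512 Hz.  Background is per-channel AR(2) noise,
x_t = 1.5 x_{t−1} − 0.55 x_{t−2} + ε_t (poles 0.86 and 0.64): low-pass,
EEG-like 1/f-ish spectrum, and — the reason it is not white noise — a
non-uniform interictal symbol distribution, so the classifier has to
separate two structured regimes rather than structure from uniformity.
During a labeled seizure the onset-zone channels (default: the first
quarter of the grid, a focal pattern) add a sinusoid whose instantaneous
frequency wanders inside 4–12 Hz (theta/alpha-band rhythmic ictal
activity), with RMS 3× the channel's background RMS and a 2 s linear
ramp-in at onset.  All defaults were fixed when the generator was
designed.

What it emulates: channel-count/rate of a clinical grid, colored
background, focal rhythmic ictal activity with gradual onset, regime
labels.  What it does not: spike-wave morphology, artifacts
(movement/muscle), inter-channel correlation of background activity,
non-stationary interictal states (sleep stages), electrode drift.
Passing tests therefore demonstrate that the encoder/classifier recovers
a rhythmic regime change from colored noise at realistic scale — not
clinical performance on human iEEG.

The separability premise is asserted directly on the symbols: the
total-variation distance between ictal and interictal symbol histograms on
the onset-zone channels is > 0.1 (measured ≈ 0.37 at defaults).  Pooled
over the full grid the distance dilutes toward ≈ 0.09 because only a
quarter of the channels carry the rhythm; the onset-zone statement is the
one the spatial encoding actually consumes.

## Problem sizes and numerical choices

- Concentration experiment: default 2,000 repetitions per dimension
  (clinical-scale 50,000 is available via `--reps`); medians at D = 10,000
  are stable to ±0.002 at 2,000 reps.
- End-to-end recovery test: 50 seeds, each with a 75 s training recording
  (seizure 40–70 s; references 5–35 s interictal, 40–70 s ictal) and a
  60 s held-out recording (seizure 20–40 s), full-scale settings
  (D = 10,000, L = 9, 60 channels, 512 Hz).  Recording durations are the
  package's own desk-scale choice; nothing else is scaled down.
- Cleanup sweeps batch all queries into one matrix product.
- Degenerate inputs are rejected loudly: empty bundles, D mismatches,
  L < 2, windows shorter than L, references outside the recording, NaNs
  in recordings, ragged or header-less recording files.

## Known limitations

Binary components only (no bipolar/real/complex variants); two states
(interictal/ictal) with no online prototype updating; no patient-specific
threshold optimization; the synthetic generator's realism limits above;
EDF reading requires the optional `mne` dependency and EDF writing is not
provided.
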