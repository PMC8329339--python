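# hdseizure

Hyperdimensional computing (HDC) for seizure detection in multichannel
intracranial EEG (iEEG).  The package is aimed at researchers in clinical
electrophysiology and neuromorphic/in-memory computing who want a complete,
reproducible reference pipeline: from raw multichannel signals to binary
hypervectors to detected seizure events, with a seeded synthetic-iEEG
generator so everything runs and is testable without any external data.

## The method

Everything is built from dense binary hypervectors of dimension
*D* = 10,000.  Independently drawn hypervectors are quasi-orthogonal — their
normalized Hamming distance (NHD) concentrates around 0.5 — which makes
them behave like robust symbols.  Three operations manipulate them:

- **binding** `A ⊕ B` (componentwise XOR): combines two vectors into one
  quasi-orthogonal to both; self-inverse, so binding also unbinds;
- **bundling** `[A + B + C]` (componentwise majority, random tie-break):
  produces a vector *similar* to every input (NHD ≈ 0.25 for three random
  inputs) — the set/prototype memory;
- **permutation** (circular shift): a distance-preserving rotation for
  sequence positions (provided as a core operation; the default encoder
  does not use it).

The pipeline:

1. **Symbolization.** Each channel is reduced to order relations: for
   *L* = 9 consecutive samples, the 8 bits "is *x*ₜ₊₁ ≥ *x*ₜ?" form one of
   2⁸ = 256 symbols, computed at every sample (maximal overlap).
   Amplitudes are discarded entirely.
2. **Item memory.** One fixed random hypervector per symbol (*C₁…C₂₅₆*)
   and per electrode (*E₁…E₆₀*) — 316 vectors at the clinical-scale setting —
   immutable during learning and classification.
3. **Spatial encoding.** At one timestep,
   `S = [C_s(1) ⊕ E₁ + … + C_s(n) ⊕ Eₙ]` records *which* pattern occurred
   *where*.  Binding `E_i` back onto `S` and cleaning up against the item
   memory recovers channel *i*'s symbol.
4. **Spatiotemporal encoding.** The `S_t` of a window (504 of them for 1 s
   at 512 Hz with L = 9) are bundled into one composite `ST`.
5. **One-shot learning.** A brain-state prototype is the bundle of the ST
   vectors from a 30 s reference period: `P_ict = [ST₁ + … + ST₃₀]`, and
   likewise `P_int`.  One pass, no iteration, no gradients.
6. **Detection.** Each query window is encoded through the *same* path and
   scored with `Δ = NHD(Q, P_int) − NHD(Q, P_ict)`; Δ > 0 means
   "closer to ictal".  Events are maximal runs with Δ > θ lasting ≥ τ
   seconds, merged across a refractory period ρ.

## Worked example

Train on one synthetic seizure, detect a held-out one (different noise
seed, same regime), all from the shell:

```sh
hdseizure simulate --duration 75 --seizure 40:70 --seed 11 \
    --out train.txt --labels train.json
hdseizure simulate --duration 60 --seizure 20:40 --seed 22 \
    --out test.txt --labels test.json
hdseizure train  --recording train.txt --labels train.json \
    --out-int p_int.hdp --out-ict p_ict.hdp
hdseizure detect --recording test.txt --proto-int p_int.hdp \
    --proto-ict p_ict.hdp --events events.tsv --delta delta.tsv
hdseizure evaluate --events events.tsv --labels test.json --duration 60
```

which prints

```
wrote 60x38400 recording to train.txt
wrote 60x30720 recording to test.txt
learned prototypes from k=30 windows each
1 event(s) over 60 s
{
  "n_labels": 1,
  "n_events": 1,
  "sensitivity": 1.0,
  "false_detections": 0,
  "latencies_s": [1.0],
  "mean_latency_s": 1.0,
  "false_per_hour": 0.0
}
```

The held-out seizure (labeled 20–40 s) is detected as one event from 21 s
to 40 s (`events.tsv`: peak Δ = 0.1515) — a 1 s onset latency, explained by
the generator's 2 s amplitude ramp-in — with no false detections anywhere
in the recording.

The concentration-of-measure experiment behind all of this:

```sh
hdseizure figure1 --reps 2000 --dims 100,1000,10000 --seed 0 --out fig1.csv
```

| D | random-pair median NHD | 1–99% range | bundle-to-input median NHD | 1–99% range |
|---|---|---|---|---|
| 100 | 0.50 | 0.23 | 0.25 | 0.20 |
| 1,000 | 0.50 | 0.073 | 0.25 | 0.063 |
| 10,000 | 0.5001 | 0.024 | 0.25 | 0.020 |

Random pairs sit at NHD 0.5, bundles at 0.25 from each input, and both
distributions tighten as D grows — the robustness budget the classifier
spends.

The same pipeline is available as a library (`hdseizure.generate`,
`build_item_memory`, `learn_prototypes_from_intervals`, `run_detection`,
…); see `docs/methods.md` for the model details and design choices.

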