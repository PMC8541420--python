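# Methods

This document records the modeling assumptions, parameter choices and
numerical conventions behind `cogload`. The package classifies cognitive
workload levels (three classes: low / medium / high) from EEG functional
connectivity: each recording session is reduced to a 16×16 connectivity
matrix over a fixed electrode montage, and a deep classifier assigns the
matrix to a workload class. Because no EEG recordings ship with the
package, a coupled-oscillator simulator generates studies with known,
planted connectivity structure; every quantitative claim in the test
suite is made against that known structure or against closed-form /
brute-force oracles.

## 1. Synthetic EEG generator

### Signal model

Each channel `j` is a sinusoid with slowly drifting phase plus additive
noise:

```
s_j(t) = sin(2π f_j t + φ_j(t)) + ε_j(t)
```

- `f_j`: per-channel base frequency, default `linspace(8, 12, n)` Hz
  (alpha band, where instantaneous phase is well defined).
- `φ_j(t)`: a Gaussian random walk, step SD `phase_jitter_sd = 0.05`
  rad/sample. The jitter decorrelates channels over seconds so that
  independent channels genuinely read as null connectivity.
- `ε_j(t)`: white (default) or 1/f "pink" Gaussian noise with SD
  `noise_sd`.

### Coupling

Coupling is declared per directed pair `(i → j)` with a strength
`c ∈ [0, 1]` and an integer sample lag.

- **Undirected (zero-lag) coupling** mixes source `i` into target `j`
  with weight `c`, and the target keeps weight `max(0, 1 − Σ incoming)`
  of its own source. At `c = 1` the two channels share one underlying
  oscillation, so PLV → 1 exactly (a test anchor).
- **Directed (lagged) coupling** inserts a delayed copy of the source.
  The declared strength `c` maps to mixing weight `c/2`. Rationale: a
  pilot study showed detectability by phase transfer entropy is an
  inverted-U in the raw mixing weight — past weight ≈ 0.5 the channels
  synchronize and the directional signature collapses (and a purely
  additive variant even flips the recovered direction, because
  independent target noise makes the target a cleaner "second view" of
  the source). Halving keeps the full strength range on the rising,
  monotone branch: direction recovery is ~100% at `c = 0.9` and mean
  dPTE is strictly increasing in `c` (Spearman 1.0 in two independent
  50-seed pilot blocks). These pilots were run before the test bounds
  were frozen.

### Study layout

A study is a balanced set of sessions, default 113 per class (339
total), 18 s at 256 Hz, one seeded `CouplingSpec` per class. The three
default class topologies use disjoint channel pairs (channels 0–5,
6–9, 10–15 respectively) so the planted structure is separable by
construction. Session order is shuffled with the study seed; per-session
seeds come from `numpy.random.SeedSequence.spawn`, so any session is
reproducible in isolation. An optional `drop_first_k` switch discards
the first *k* sessions per class (practice-session convention).

### Realism limits

The generator is a calibration instrument, not a brain model: no
volume conduction, no non-stationarity beyond phase drift, no artifacts
(ocular, muscle, line noise), and narrowband oscillations only. Results
on synthetic studies are engineering acceptance of the pipeline, not
claims about real EEG.

## 2. Preprocessing

- **DC removal**: per-channel mean subtraction.
- **Band-pass 0.1–45 Hz**: 4th-order Butterworth applied forward and
  backward (`sosfiltfilt`), i.e. zero-phase, 8th-order magnitude.
  Zero-phase filtering matters because the connectivity metrics are
  phase-based. Note the 0.1 Hz edge implies ~10 s edge transients;
  amplitude checks in the tests therefore measure at exact Fourier bins
  and idempotence is assessed on the interior of long recordings.
- **Downsampling to 256 Hz**: polyphase resampling (`resample_poly`)
  with the rational ratio from `fractions.Fraction`; output trimmed to
  `floor(n · target/fs)` samples.
- **Channel selection**: the canonical 16-electrode montage
  Fp1, Fp2, F7, F3, F4, F8, T7, C3, C4, T8, P7, P3, P4, P8, O1, O2
  (10–20 system), each mapped to a Brodmann area. Selection is a pure
  row projection in canonical order; missing electrodes raise an error
  naming them.
- **EDF interop**: a minimal plain-EDF writer (ASCII header, int16,
  1-second records) for export; reading goes through `mne` when
  available. The round-trip is tested against `mne`'s reader with a
  16-bit quantization error bound.

## 3. Connectivity metrics

All metrics are computed pairwise over the 16 channels of one session.
Instantaneous phase/amplitude come from the analytic signal
(`scipy.signal.hilbert`), phase wrapped to (−π, π].

- **Mutual information (MI)** on the raw (cleaned) signals: joint
  histogram with uniform-width bins over each series' observed range,
  natural log (nats). Default bin count `max(2, ⌈√(N/5)⌉)` (≈ 5 samples
  per marginal bin). Symmetric; diagonal set to 0. Tiny negative
  rounding is clamped to 0.
- **Phase locking value (PLV)**: `|mean exp(j(φ_x − φ_y))|` in [0, 1].
  Symmetric; diagonal 1.
- **Phase transfer entropy (PTE)**:
  `PTE_{x→y} = H(y_t, y_t′) + H(y_t′, x_t′) − H(y_t′) − H(y_t, y_t′, x_t′)`
  with past states at lag θ (`y_t′ = y_{t−θ}`), estimated from
  uniform-width phase histograms. Data-driven parameters:
  θ = `round(L·CH / N±)` floored at 1, where N± counts wrapped-phase
  sign changes across time and channels (a zero sample takes the
  following sample's sign); bins = `round(exp(0.626 + 0.4 ln(L − θ − 1)))`
  floored at 2.
- **dPTE** = `PTE_xy / (PTE_xy + PTE_yx)` ∈ [0, 1]; 0.5 means no
  preferential flow, > 0.5 net flow x → y. The matrix is
  complementary (`d_ij + d_ji = 1` off-diagonal), diagonal 0. If both
  directed estimates are exactly zero the pair carries no directional
  evidence and 0.5 is returned with a warning.

Band-limited connectivity and surrogate-based significance testing are
out of scope.

## 4. Classifier architectures

Nine variants in three families, all ending in the shared tail
`Flatten → Dense(64, ReLU) → Dropout(0.25) → Dense(16, ReLU) → Dense(3, softmax)`:

| Variant | Body |
|---|---|
| C-A | Conv32(5×5) → Conv64(3×3) → MaxPool2 → Conv128(5×5) |
| C-B | Conv32(5×5) → Conv64(3×3) → MaxPool2 → Conv128(5×5) → Conv128(5×5) |
| C-C | Conv32(5×5) → Conv64(5×5) → MaxPool2 → Conv128(3×3) |
| L-A | LSTM32 → LSTM16 → LSTM8 |
| L-B | LSTM64 → LSTM32 → LSTM16 → LSTM8 |
| L-C | LSTM64 → LSTM32 → LSTM16 → LSTM16 |
| CL-A | Conv32(3×3)×2 → MaxPool2 → Conv64(3×3)×2 → Reshape(256,16) → LSTM32 → LSTM16 |
| CL-B | Conv16(3×3)×2 → MaxPool2 → Conv64(3×3)×2 → Reshape(256,16) → LSTM64 → LSTM16 |
| CL-C | Conv32(3×3)×2 → MaxPool2 → Conv64(3×3)×2 → Reshape(256,16) → LSTM64 → LSTM32 → LSTM16 |

Conventions and their reasons:

- CNN input is the 16×16 matrix as a one-channel image; convolutions
  are stride 1 with 'same' padding, ReLU.
- LSTM input is the row-major flattening of the matrix to a (256, 1)
  sequence.
- **Conv-LSTM reshape is (256, 16)**, not (256, 1): the conv stack
  emits an 8×8×64 tensor (4096 elements), which cannot reshape to 256
  scalars; 256 steps × 16 features preserves the element count.
- **Intermediate LSTM layers return full sequences; the last returns
  its final hidden state** — the standard convention for stacked
  recurrent layers feeding a dense head, and the only one that makes
  the stacks well-formed.
- LSTM gates use sigmoid activations; candidate and cell-output
  activations are ReLU.
- Parameter-count oracle: C-A has exactly 749,699 trainable parameters
  (verified by hand in the tests).

### Numpy backend

No deep-learning framework is assumed; the layers (Conv2D via im2col,
MaxPool2D, LSTM with full BPTT, Dense, Dropout) and Adam are
implemented in `cogload/nn.py` in float32 (float64 available for
gradient checking). Weight initialization is seeded Glorot-uniform;
dropout uses a separate RNG stream spawned from the same seed so weight
init is independent of training. Every layer's analytic gradient is
checked against central finite differences in float64.

## 5. Training and evaluation protocol

- **Split**: stratified seeded 70/15/15. Train gets `floor(0.70 n)`;
  validation and test split the remainder, validation taking the extra
  item when odd. For the canonical 339-session study this gives
  237/51/51. Items of each class are shuffled into pools and
  interleaved round-robin, so strata stay balanced; the split is a
  disjoint exhaustive partition (property-tested).
- **Feature scaling**: MI matrices are divided by the training-set
  maximum (computed on the training split only, applied to all splits);
  PLV and dPTE are already in [0, 1].
- **Optimization**: categorical cross-entropy (forced by the 3-unit
  softmax head), Adam at 1e-3, batch size 64, up to 1000 epochs.
- **Early stopping**: patience 50 on validation loss with best-weights
  restore; learning rate halves after each 20 consecutive
  non-improving epochs. All configurable.
- **Evaluation**: accuracy = 100 · trace(confusion)/n, per-class
  precision/recall/F1 (percent), 3×3 confusion matrix (rows = true),
  one-vs-rest ROC AUC per class (NaN for a class absent from the test
  set). Cross-subject aggregation reports the arithmetic mean and
  *sample* SD (ddof = 1; defined as 0 for a single subject).

The canonical problem sizes (339 sessions, 18 s at 256 Hz, 16
channels, batch 64) are this package's own defaults for its synthetic
studies, chosen to make one full subject trainable on one CPU in a few
minutes.

## 6. Limitations

- Synthetic-only validation: accuracy on simulated studies says the
  pipeline recovers structure it planted, nothing more.
- MI and PTE histogram estimators are biased at small sample sizes
  (positive bias for MI on independent data is bounded in the tests,
  not removed).
- The numpy backend is CPU-only and unoptimized relative to a real
  framework; it targets correctness, determinism and testability.
- No artifact handling (ICA/EOG), no re-referencing, no band-limited
  connectivity, no surrogate significance testing, no cross-subject
  (subject-independent) training.
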