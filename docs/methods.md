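# Methods

## Problem and model

The package classifies 30-second epochs of multivariate polysomnography
(PSG) into five sleep stages (Wake, REM, S1, S2, S3 with slow-wave
sleep merged into S3). PSG channels are heterogeneous — different
sample rates, amplitudes, and rhythms — so the model learns two
complementary views of every epoch and lets an attention mechanism
decide how to combine them.

**Multi-view convolutional representation.** Each channel c owns an
independent 1-D CNN encoder producing a channel-view vector
d_c ∈ R^p; a single 2-D CNN over the aligned C × L channel matrix
produces a global-view vector s ∈ R^p. Stage 1 of both encoders runs
four parallel kernels of 8/16/32/64 samples so that waveform patterns
at different frequency scales are captured; channel encoders use max
pooling (salient per-channel features), the global encoder average
pooling (general cross-channel structure), and its final pool spans
the channel axis (height C), collapsing it to 1.

**Channel-wise attention.** For each channel, a fusional rate
r_c = σ(W_rg·s + W_rc·d_c + b_rc) gates how much the channel view
contributes against the global view. The energy
e_c = W_ec·((1−r_c)⊙s + r_c⊙d_c) + b_ec is softmax-normalised into
weights α, and the fused epoch vector is x̃ = s ⊕ Σ_c α_c d_c ∈ R^2p.

**Time-wise attention.** The fused sequence runs through a 2-layer
bidirectional GRU with per-direction width q; h_t ∈ R^2q concatenates
the two directions. For query t and every key i the same rate/energy
construction over (h_t, h_i) yields weights β_t, and the context is
c_t = Σ_i β_{t,i} h_i. The alternative reading that weights the query
state itself (Σ_i β_{t,i} h_t) is degenerate — it equals h_t for any
normalised β because the weights sum to one — so the sum-over-keys
form is the implemented one; the degenerate form is retained as
`time_context_literal` purely as a tested negative oracle.

**Classifier and cost.** ĥ_t = tanh(W_h[c_t ⊕ h_t] + b_h) ∈ R^r feeds
a softmax layer over the five stages. The cost is the two-term
(Bernoulli-style) cross-entropy applied to the softmax output,
averaged per record and then across records, with probabilities
clipped to [1e-7, 1−1e-7]; it upper-bounds the categorical
cross-entropy, which is available via `loss_mode="categorical"`. The
tanh head activation is a design choice (bounded, conventional); ReLU
is available by config.

A structural note: the shared energy biases b_ec and b_et are provably
gradient-free — they shift all softmax inputs equally and feed nothing
else — so they stay at their initial value during training. They are
kept as declared parameters for fidelity to the formulation.

## Numerical core

No deep-learning framework is used; the package carries a small
reverse-mode autodiff engine over float64 numpy arrays
(`hybridatt.autodiff`) implementing dense algebra, 1-D/2-D
cross-correlation, max/average pooling (average pooling counts zero
padding in the divisor), the standard nonlinearities, and a
max-subtracted softmax. Every operation is gradient-checked against
central finite differences in the test suite. Glorot-uniform
initialisation is drawn from a single numpy Generator per model, so a
model is a pure function of its seed.

## Reference configuration

- Feature dimensions p = q = r = 128; five stages; 14 channels.
- Channel encoder (1-D): stage 1 kernels 8/16/32/64 (8 filters each,
  stride 2), max-pool 6/4/1; stages 2–3 kernels 3 and 5 (16 filters,
  stride 1), max-pool 3/2/1. The configured paddings for the 32- and
  64-sample branches are (K−2)/2 = 15 and 31 so that all four parallel
  branches emit equal lengths and can concatenate; the alternative
  paddings 3 and 7 would make stage 1 uncomposable without cropping.
- Global encoder (2-D): 1×K analogues of stage 1, average pooling, and
  a final C×3 pool that collapses the channel axis.
- The stacks end in 32 feature maps; a learned linear projection with
  ReLU maps the flattened output to p. This is the minimal addition
  consistent with d_c, s ∈ R^p.
- Aligned epoch length L: the highest channel rate × 30 s (3,840 at
  128 Hz). Upsampling by linear interpolation preserves information;
  downsampling would discard it. A 14-channel epoch then carries
  14 × 3,840 = 53,760 time-domain values.
- Frequency domain: per aligned channel, a magnitude spectrogram with
  a periodic Hann window of 128 samples, hop 128 (non-overlapping),
  one-sided (65 bins), no boundary padding → 65 × 30 values per
  channel, 27,300 per 14-channel epoch. This is the unique simple STFT
  setting producing that count; whether magnitudes, powers, or
  log-powers were intended is not determinable from the count alone,
  so magnitude is the default and log-magnitude a config flag.
- Optimiser: adadelta with decay ρ = 0.95 and ε = 1e-6 ("0.95
  momentum" is read as the adadelta decay, since adadelta has no
  separate classical momentum term), L2 penalty 0.001 added to the
  cost, dropout 0.5 applied to the fused vectors x̃_t before the GRU
  and to ĥ_t before the softmax layer (placement is a design choice).
- Training defaults: 50 epochs, 8 windows per update, early stop after
  a 10-epoch validation-accuracy plateau, best checkpoint selected by
  validation accuracy.
- Time-wise attention is O(T²); sequences are processed in windows of
  `window` epochs (default 25, non-overlapping), and T in β_t is the
  window length.

## Synthetic cohorts

The generator emulates the structure the model assumes, not the
physiology of real sleep:

- A montage of C channels with heterogeneous integer rates. The
  default 14-channel montage (6 EEG + 2 EOG + 1 ECG at 128 Hz, 1 EMG +
  4 auxiliary at 64 Hz) is a stand-in with the documented rate
  heterogeneity; it is not a claim about any real recording montage.
- A first-order Markov hypnogram with a sticky, physiologically
  plausible transition matrix; the empirical stage distribution of a
  long simulated hypnogram converges to the chain's stationary
  distribution (tested at total variation < 0.05 over 10,000 epochs).
- Per 30-s slot, each channel is a sum of band-limited sinusoids
  (3 per band) over the conventional delta/theta/alpha/beta bands,
  with log-amplitudes drawn around a per-(stage, channel-kind) mean
  (delta-dominant S3, alpha-dominant wake, EMG tone suppressed in
  REM), plus white Gaussian noise (default SD 0.5, amplitude jitter
  0.3 in log units). Bands at or above a channel's Nyquist rate are
  skipped.
- Subject streams are derived by SeedSequence hashing of
  (seed, subject_index), so cohorts are order-independent and each
  record individually reproducible.

Not modelled: apneas, arousals, movement artifacts, electrode noise,
inter-scorer label noise, stage-transition spectral dynamics within an
epoch. Passing learning tests on these cohorts therefore demonstrates
that the architecture, gradients, and training protocol work end to
end on data with the assumed band-power class structure — not
clinical-grade performance on real PSG.

## Toy study conditions

CPU-scale learning checks use a two-channel cohort (EEG 32 Hz, EMG
16 Hz, aligned length 960), p = q = r = 16, a reduced two-stage
encoder, window 8, one window per update, and well-separated
band-power signatures in which each stage owns a distinct (EEG band,
EMG tone) pair; a periodogram-plus-logistic-regression oracle verifies
the cohort is separable (accuracy > 0.9) before any network is
trained, so the learning targets are achievable by construction.
Memorization uses 2 subjects × 40 epochs and 30 training epochs;
cross-validation uses 10 subjects × 40 epochs, 5 folds, up to 30
epochs with patience 8. These sizes were chosen as the smallest
configuration at which the separable cohort is learned reliably.

## Degenerate inputs and tie-breaks

- argmax label ties break to the lowest class index (Wake < REM < S1 <
  S2 < S3).
- Single-class test sets leave one-vs-rest AUCs undefined; they are
  reported as NaN with a warning, and macro AUCs average only over
  classes present in the truth.
- Macro-F1 averages over all five classes; absent classes contribute 0.
- Validation-set rounding: floor(0.1 × n) subjects to validation,
  remainder to train, after a seeded shuffle; the k test sets
  partition the cohort (k = 1 degenerates to a single 0.7/0.1/0.2
  split).
- Channels whose length already equals the alignment target pass
  through untouched; z-scoring uses per-record, per-channel moments
  with zero-variance channels left unscaled.

## Known limitations

- O(T²) time attention limits window sizes; the default window of 25
  epochs (12.5 min of recording) bounds cost but cannot attend across
  window boundaries.
- The numpy engine is single-threaded per operation and processes
  epochs sequentially; it is meant for correctness and desk-scale
  experiments, not overnight-cohort training.
- The full-size (p = 128, 14-channel) model is exercised for forward
  geometry and gradient checks, not trained to convergence here.
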