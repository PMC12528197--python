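# Methods

This note records what the package computes, the assumptions behind it,
and the choices made where the design was genuinely open.

## Signal model and synthetic data

The generator emulates a 64-channel, 256 Hz acquisition over the 10-20
electrode layout.  Each class is a relative band-power signature over
the five canonical bands (delta 0.5–4, theta 4–8, alpha 8–12, beta
12–30, gamma 30–50 Hz).  One band-limited Gaussian source per band
(4th-order Butterworth-filtered white noise, unit SD, amplitude √weight)
plus low-amplitude broadband fillers form a square source matrix,
mixed by a random full-rank matrix whose band-source columns are drawn
from ±U(0.5, 1.5) so every channel carries every active band.  On top of
the clean mixture:

- **Eye-blink proxies** — 0.4 s Hann-windowed transients at ~8× channel
  SD on frontal (Fp*/AF*) channels, Poisson arrivals (default 12/min, a
  typical spontaneous blink rate).  Poisson was chosen as the simplest
  memoryless, fully seedable event model.
- **Mains contamination** — a sustained 50 Hz (configurable 60 Hz)
  sinusoid at 0.2× channel SD by default.
- **Sensor noise** — "X% Gaussian noise" is defined throughout the
  package as additive zero-mean noise with SD equal to X/100 of the
  clean signal's per-channel SD (per epoch-channel when applied to
  epoched data).  Under this definition 10% noise is a 20 dB SNR.

What the generator does **not** model: biophysical volume conduction
(mixing is random, not a forward head model), non-stationarity across a
recording, realistic artifact waveform libraries, inter-subject
variability.  Passing tests therefore demonstrate correctness of the
pipeline's machinery and learnability of band-power-separable classes —
not clinical-grade performance on real corpora, which have unknown
class geometry and far lower SNR between classes.

Classes default to an alpha-dominant vs theta-dominant pair, which makes
the classification task solvable by exactly the feature family the
pipeline extracts (band powers), so end-to-end learning tests probe the
model rather than the task definition.

## Preprocessing

- **Filtering** precedes ICA and segmentation (filter → ICA → segment;
  the order is configurable).  The band-pass is a zero-phase
  (forward-backward) Butterworth, default 0.5–50 Hz.  The default order
  is 6: the double-pass magnitude response of an order-4 design leaves
  ~11% of a 60 Hz mains tone at 256 Hz (18.5% by the continuous-time
  response), whereas order 6 meets the intended <10% rejection (analytic
  9.7%, digital 4.4%) while keeping passband ripple nil.  Zero-phase
  application preserves epoch alignment; the price is non-causality,
  acceptable for offline analysis.
- **ICA** is FastICA (fixed-point non-Gaussianity maximization with
  whitening), deterministic given its seed.  Components are flagged as
  artifacts when excess kurtosis exceeds 5.0 (spiky transients) or more
  than 60% of their power lies below 4 Hz (ocular drift).  These rules
  need no EOG reference channel; the low-frequency rule will also flag
  genuine delta-dominant components, so delta-heavy protocols should
  raise the threshold.  Flagging every component is refused.
- **Segmentation** uses half-open windows [t₀, t₀+T) so boundary samples
  are not double-counted; the trailing partial window is dropped.
  Default 2-s windows, non-overlapping; overlap is exposed for
  sliding-window inference.

## Features and tokenization

Band powers are trapezoidal integrals of a Welch PSD (segment length
min(L, 256), 50% overlap) between band edges; on 2-s epochs the delta
band has coarse frequency resolution and its estimate should be read
accordingly.  For the model input, each epoch-channel is tiled into
P = 16 contiguous frames (32 samples each at 512-sample epochs): raw
sample vectors by default (`raw_frames`), or per-frame log-compressed
5-band powers (`band_frames`) for interpretability-oriented runs.  Raw
frames keep the temporal attention matrices small (16×16) while leaving
frequency extraction to the learned embedding; the end-to-end tests
confirm this is sufficient for the synthetic task.

## Model

Defaults mirror the full-scale configuration (6 layers, 8 heads,
d = 256, FFN width 4d); the ablation grid covers heads ∈ {4, 8, 12} and
depth ∈ {3, 6}.  The small configuration used in tests and the
acceptance script (2 layers, 4 heads, d = 64, 8 channels) exists purely
to keep runs desk-scale; problem sizes in all shipped runs are 400
epochs × 8 channels.

Open design points, resolved as follows:

- **Token granularity**: frames within an epoch, per channel; channels
  share the embedding by default (parameter economy and channel-
  permutation equivariance; a per-channel option exists).
- **Temporal/spatial composition**: the temporal encoder stack runs per
  channel first; one spatial-attention block then pools the mean-pooled
  channel summaries.
- **Masked attention**: the elementwise product A ∘ M is row-
  renormalized so downstream mixing stays a convex combination.  It is
  computed as (exp(scores) ∘ M) / row-sum, which makes M ≡ 1 reproduce
  the unmasked weights bit-for-bit; a fully-masked row (possible only
  with an explicit override, since σ > 0) falls back to uniform with a
  warning.
- **Mask parameterization**: one σ(logits) matrix per layer, shared
  across heads (config-switchable), initialized at logits = 2
  (σ ≈ 0.88, nearly open).  The retention penalty Σ(1−M)∘A alone is
  minimized by M ≡ 1, so a sparsity regularizer λ_s·mean(M) is added;
  defaults λ_mask = 0.1, λ_s = 0.01 keep both terms an order below the
  cross-entropy at initialization.
- **Residual connections and pre-norm layer normalization** are used
  around both sublayers — a 6-layer stack does not train reliably
  without them.
- **Pooling**: mean over positions (tokens → channel summary) and mean
  over query channels (spatial block → pooled vector).

The forward and backward passes are hand-written NumPy in float64.
Correctness of every gradient block (embedding, attention, mask logits,
FFN, layer norms, spatial attention, classifier) is established by
central-difference checks at h = 1e-6 with relative tolerance 1e-4; an
absolute floor of 1e-7 on the numeric-analytic difference absorbs
cancellation noise for parameters whose true gradient is ~0 (notably the
key-projection bias, which shifts every attention score in a row equally
and is therefore softmax-invariant).

## Training and evaluation

Adam (lr 0.001 by default; the explored range is 0.0001–0.005), batch
size 32, up to 100 epochs with early stopping on validation loss
(patience 10); shipped runs use 15 epochs / patience 5, which the
separable task saturates.  Splits are epoch-level, stratified per class,
60/20/20 by default; for real multi-recording corpora a recording-level
split should be preferred to avoid leakage (synthetic epochs are
exchangeable, so epoch-level splitting is sound there).

Metrics: accuracy, precision, recall, specificity (TN/(TN+FP)), F1 and
AUC; binary by default, macro one-vs-rest for K > 2.  AUC is the
rank-based Mann-Whitney estimator with midranked ties.  Metrics that are
undefined on the given data (absent class, zero denominators, degenerate
scores) are reported as NaN and named in `report.undefined`, never
silently zeroed.

Numerical conventions: attention rows are stochastic to 1e-6;
layer-norm epsilon 1e-6; cross-entropy clamps log(0) with a 1e-300
floor; training aborts with a diagnostic on non-finite loss.
Determinism: with dropout 0 (the default), generation, initialization,
batching and noise injection all derive from explicit integer seeds, so
identical config + seed reproduces serialized fixtures byte-for-byte
and trained weights exactly.

## Known limitations

- The pure-NumPy implementation is single-threaded per matmul and
  intended for desk-scale experiments, not large-corpus training.
- Mask matrices are position-indexed, so a trained model is tied to its
  sequence length; changing P requires retraining.
- Sparse attention, quantization and pruning are out of scope, as is
  any claim about performance on clinical corpora: the synthetic task's
  ceiling accuracy reflects its constructed separability.
- EDF support covers 16-bit EDF with per-channel physical ranges;
  EDF+ annotations beyond channel labels are not written.
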