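# Methods

## Problem and pipeline

`somno` detects apnea and hypopnea events in full-night ambient audio
and derives patient-level clinical indices. The pipeline is

1. resample to 16 kHz, window 60 s / stride 30 s;
2. per window: 128-band log-mel matrix (10 ms frames) and across-band
   energy curve, each z-normalized;
3. dual-stream CRNN → per-80 ms-frame class probabilities
   (normal / hypopnea / apnea);
4. temporal averaging of overlapping windows on the night timeline;
5. clinically constrained event post-processing;
6. frame-, event- and patient-level evaluation.

## Front end

STFT framing is centered (reflect padding) and the frame count is
trimmed to `len/hop`, so frame *i* represents `[10i, 10(i+1))` ms and a
60 s window is exactly 128 × 6000. The mel filterbank is Slaney-style
(linear below 1 kHz, logarithmic above, area-normalized triangles) over
0 Hz–Nyquist. "Log" is read as decibels: `10·log10(power + 1e-10)`;
the floor keeps silence finite at −100 dB.

Two points the design leaves open are resolved as documented switches:

- **Spectrogram normalization scope** — global per segment (default)
  rather than per mel-bin (`FeatureConfig.norm = "global"|"per_bin"`).
  Global scaling preserves the relative intensity of frequency bands
  within a window, which is the cue the energy stream formalizes.
- **Energy computation point** — the energy curve is the across-band
  mean of the *raw* log-mel matrix, before z-normalization, then
  normalized independently. Computing it after normalization would
  erase the absolute-intensity information the stream exists to carry.

SpecAugment masks are filled with 0 — the per-segment mean in
normalized units — with widths drawn uniformly from `{0..max}` and one
mask per axis; the gain perturbation multiplies both streams by the
same draw from U(0.8, 1.2) after masking, preserving cross-modal
consistency.

## Architecture

Conv channels (32, 64, 128, 256), a bias-free SE gate, an energy MLP
1→64→64 with layer-norm, fusion 2112→256 with layer-norm, and a 2-layer
BiLSTM with 128 hidden units per direction and two bias vectors per
layer/direction are the unique widths that simultaneously satisfy the
2048-dim flatten, the 64-dim energy feature, d_model = 256, r = 16 and
a total of 1,734,147 trainable parameters; the implementation treats
that count as an architectural invariant (asserted in tests). Pool
tuples are (frequency, time); input layout is channel × frequency ×
time; the 6000→750 energy alignment averages disjoint groups of eight
samples. Batch-norm uses affine terms (counted as parameters) and
running statistics (not counted).

## Numerical kernel

The network runs on a small numpy kernel with hand-written
backpropagation (im2col GEMM convolutions, explicit BPTT for the
BiLSTM), written for a single CPU:

- float32 arithmetic throughout; batch-norm moments accumulated in
  float64/pairwise summation;
- large activations and scratch arrays are persistent per-layer
  buffers — on a memory-bound CPU, page faults from reallocating
  ~100 MB arrays every step otherwise dominate;
- max-pool backward routes gradient through every element equal to the
  window maximum. This is a valid subgradient; exact ties at positive
  activations have measure zero, and tied zeros are blocked by the
  preceding ReLU's gradient mask;
- LSTM forget-gate biases are initialized to 1 (all other recurrent
  parameters uniform in ±1/√H): keeping the cell path open at
  initialization is the standard remedy for slow early LSTM training
  and helps gradients reach the convolutional stack;
- every backward pass is verified against central finite differences
  in the test suite, and the full model against directional
  derivatives.

## Loss and optimization

`L = L_focal + λ·L_dice` with γ = 2, α = (1, 4, 2) for
(normal, hypopnea, apnea) and λ = 0.5. Dice is computed on soft
probabilities against one-hot labels with Laplace smoothing ε = 1,
which keeps gradients finite when a class is absent from a batch;
probabilities are clamped at 10⁻⁸ before the log. AdamW uses lr
5·10⁻⁴ and decoupled weight decay 5·10⁻² (applied to all parameters);
gradients are clipped to global norm 1.0 every step; the LR halves
after two consecutive epochs without validation macro-F1 improvement;
early stopping waits five epochs. Batch size 32, 100 epoch budget and
patience 5 are desk-scale defaults, all configurable — quick profiles
in the tests use batch 2 and a raised LR (4·10⁻³) because they take
only ~10²  optimizer steps.

## Labels and events

Events are half-open `[onset, offset)` intervals; a frame belongs to an
event iff its center lies inside; apnea overrides hypopnea on overlap
(severity-first). Labels are generated directly at the 80 ms model
resolution. These conventions make rasterize→extract a near-inverse
pair: every event ≥ 10 s round-trips with ≤ 0.08 s boundary error,
which the tests assert.

Post-processing order is fixed: argmax (ties → lowest class, i.e.
normal — conservative), median filter (k = 5, edge replication, median
of the numeric labels), run extraction, merging of same-class gaps
strictly below 3 s iterated to fixpoint (so transitive chains merge),
then removal of events shorter than 10 s. Merging precedes duration
filtering; a dedicated test verifies that two 8 s fragments 2 s apart
survive as one 18 s event.

## Evaluation

Event matching is greedy on descending IoU (ties: earlier reference
onset, then earlier predicted onset), one-to-one, threshold 0.1, and
class-agnostic — class agreement is assessed afterwards by the error
taxonomy, which needs cross-class pairs. Frame metrics with zero
denominators are reported as missing (None) and excluded from macro
averages instead of being silently counted as zero. Bland–Altman
differences are oriented audio − PSG with sample SD (n−1). AUC is the
normalized Mann–Whitney U with half-credit ties (identical to the
trapezoidal ROC area on finite samples; cross-checked against
scikit-learn). Bootstrap CIs resample subjects with replacement
(percentile method, 1000 draws); proportions at 0% or 100% get exact
Clopper–Pearson intervals (beta quantiles via statsmodels). Frame
metrics can be computed per window or on the aggregated night timeline;
the night timeline is the default.

## Synthetic nights

The generator emulates what the detector actually keys on: a periodic
breathing/snoring baseline (band-passed 100–2000 Hz noise bursts,
amplitude-modulated at a 4 s breath period, over a −45 dB noise floor),
with planted events that attenuate burst amplitude — U(0.3, 0.7) for
hypopneas, 0.02 for apneas — with 100 ms cosine ramps, peak-normalized
to 0.9. Event durations follow truncated normals (hypopnea
16.58 ± 6.68 s, apnea 23.39 ± 10.10 s) cut at the 10 s clinical
minimum so every planted event is clinically valid and the round-trip
property stays exact. Events are separated by ≥ 20 s so default
post-processing never fuses distinct planted events. Hypopneas are
rendered as amplitude attenuation only (no spectral change), which
mirrors their clinical definition (≥ 30% flow reduction, not silence)
and makes the energy stream's contribution testable.

What the generator does **not** model: real snore timbre, bed-partner
or environmental interference, microphone variation, sleep/wake
structure, or the acoustic ambiguity between mild hypopneas and heavy
breathing. Passing the end-to-end test therefore demonstrates that the
pipeline is mechanically correct and that the model can learn
amplitude-coded events — not that clinical-grade accuracy transfers to
real recordings.

## End-to-end experiment scale

The recovery experiment (`somno.experiments.run_e2e`, also the basis of
the CLI `e2e` subcommand and the heaviest acceptance test) trains the
full-size network on 40 stratified 60 s windows cut from event-dense
4-minute synthetic nights (target AHI 25–50), for up to seven epochs at
batch 2 and lr 4·10⁻³, then detects on a 12-night cohort balanced
across the four severity bands (nights of 12 minutes). Validation
windows come from held-out nights so best-epoch selection measures
generalization; on validation-F1 ties the later (longer-trained) model
is kept, because with tens of steps per epoch the eval-mode argmax can
plateau while the loss still falls.

Training windows are sampled **stratified by content** — 45%
containing an apnea, 35% a hypopnea (only), 20% pure background. The
apnea share is the quantity that controls early optimization (the
near-silent class is the separable one); leaving it to the binomial
luck of a handful of planted events per night makes the short training
run's behavior strongly seed-dependent, which the stratification
removes. These sizes are the package's chosen desk-scale operating
point for a single CPU. At this scale the model reliably learns apneas
(recall near 1 with sub-second boundaries) while hypopneas — a
deliberately subtler, amplitude-only cue — are only partially
retrieved; the AHI correlation target is still met because the apnea
count carries the between-subject severity signal.

## Known limitations

- No denoising, voice-activity or snore-specific detection; apnea
  subtypes (obstructive/central/mixed) are aggregated by design.
- The numpy kernel is single-threaded BLAS-bound; it is meant for
  experimentation and testing, not large-scale training.
- Checkpoints store weights as `.npz` plus a YAML config sidecar with a
  hash; loading refuses a mismatched configuration rather than
  attempting migration.
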