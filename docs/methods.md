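# Methods

`beatbp` estimates beat-to-beat systolic blood pressure (SBP) trends from
single-channel photoplethysmography (PPG). Rather than mapping a signal
window to one SBP value, the task is posed as sequence regression: the input
is a block of *contextual cycles* — n consecutive, non-overlapping,
length-normalised PPG cardiac-cycle slices C = [c_1, …, c_n] — and the
output is the n-value SBP sequence S = [SBP_1, …, SBP_n] read, during
training, from the peaks of a simultaneously recorded arterial blood
pressure (ABP) waveform. This note documents the model, the data pipeline,
the synthetic data generator, and the numerical and design choices made
where the design was genuinely open.

## Model

**Stage 1 — intra-cycle feature extraction.** Each cycle slice (125 samples,
right zero-padded to l0 = 128 at model input) passes through a shared ResU
block, a 1-D U-shaped convolutional encoder/decoder wrapped in residual
structure:

    f_j = f_cir( f_up^d ( f_res^r ( f_down^d ( f_cir(c_j) ) ) ) ) + c_j

where f_cir is convolution → instance norm → ReLU, d = 2 down/up steps and
r = 8 residual blocks at the bottleneck (defaults). Channels start at 16 and
double at each strided-convolution down-step (16 → 32 → 64 over lengths
128 → 64 → 32); residual blocks are standard 1-D basic blocks
(conv-IN-ReLU, conv-IN, + identity, post-ReLU); up-steps are linear-
interpolation upsampling followed by f_cir with additive encoder skips at
matching scales; a final f_cir returns to 1 × 128 before the outer residual
addition of the raw slice. The interior wiring of the U (additive skips,
channel doubling) is a design choice: only the outer composition above is
fixed by the method. With every weight at zero the block is exactly the
identity, which the tests assert.

**Stage 2 — context-sensitive interaction.** The n feature vectors are
stacked chronologically into tokens F ∈ R^{n×l} (l = 128) and processed by
L = 3 pre-norm Transformer layers,

    F̂ = MSA(LN(F)) + F,    F' = MLP(LN(F̂)) + F̂,

with 8 attention heads, GELU MLP of expansion 4, and dropout 0.1 (train
only). Self-attention carries a signed sinusoidal relative-position bias.
With 1-based cycle positions and D = l,

    PE_{2x}(j) = sin(j / 10000^{2x/D}),  PE_{2x+1}(j) = cos(j / 10000^{2x/D}),
    p_{a,b} = sign(a − b) · PE(|a − b|),
    Attention = Softmax( QK^T / √d_k + W_p^T p ) V,

where W_p is one learnable length-D vector per head per layer — the smallest
parameterisation producing the required n × n scalar bias per head. The bias
depends only on the offset a − b (translation invariance), vanishes on the
diagonal and is antisymmetric; all three properties are asserted at n = 60.
`pe_mode` switches to absolute sinusoidal encodings (`ape`: added to the
tokens once before layer 1, no score bias) or to no encoding (`none`) for
ablations. A per-token projection head (affine l → l/2, ReLU, affine
l/2 → 1) emits the SBP sequence.

**Autodiff engine.** The network is built on a small tape-based
reverse-mode automatic differentiation engine over numpy arrays
(`beatbp.autodiff`): a deliberately minimal primitive set (broadcast
arithmetic, matmul, shape ops, reductions, a strided window gather for
convolution) from which normalisation layers, softmax attention and GELU are
composed. Every primitive's vector-Jacobian product is verified against
central finite differences in the test suite. Computation is float64
throughout.

**Target standardisation.** The model carries an affine output transform
(offset, scale), set once from the training targets (mean and SD, stored in
the checkpoint), so the network regresses standardised values while
predictions and losses remain in mmHg. Without it, Adam at small learning
rates spends most of its budget moving the output level toward ~120 mmHg
before it can learn any structure; with it, desk-scale runs converge in tens
of epochs. All reported metrics are unaffected in meaning.

## Training

Adam (β = 0.9/0.999), initial learning rate 1e-4, batch size 16, 500 epochs,
mean-absolute-error loss L(θ) = ||S − S̃||_1 — these defaults mirror the
published full-scale setting. Batches are reshuffled each epoch from a
seeded generator; the incomplete final batch is kept; model selection takes
the epoch with the lowest validation MAE (the validation split has no other
role); optional gradient clipping (global norm) is off by default. Runs are
bit-reproducible given the seed. No learning-rate schedule or weight decay
is used.

## Data pipeline

1. **Screening.** Records shorter than 8 min are rejected. A per-sample
   quality mask flags non-finite samples, ABP outside 30–250 mmHg, and
   flatlined PPG (2 s windows, half-window hop, SD below 1e-6 of the signal
   scale). The per-beat pulse-pressure screen (< 10 mmHg → drop beat) is
   applied at slicing time, once beat boundaries exist.
2. **Filtering.** Zero-phase (forward–backward) 4th-order Chebyshev II
   band-pass, 0.5–10 Hz, 20 dB minimum stopband attenuation. The band
   brackets resting cardiac content while preserving the dicrotic wave; the
   published method fixes the filter family but not the band.
3. **Onset detection.** A slope-sum-function detector: windowed sum
   (128 ms) of positive first differences, adaptive threshold at 0.6 of a
   running maximum decaying with a 3 s time constant, 300 ms refractory
   period, refinement to the waveform foot by local minimum followed by a
   walk-back to the earliest sample of the non-increasing run (the
   zero-phase filter flattens the foot into a shallow valley whose centre
   sits a few samples late).
4. **Slicing and labelling.** Cycles are cut at consecutive onsets
   (half-open, 0-based). Slices shorter than 125 samples are right
   zero-padded; longer ones are uniformly resampled by linear
   interpolation. The label is the ABP maximum over the same interval (the
   minimum in DBP mode). Beats outside 0.3–1.5 s, touching masked samples,
   or with pulse pressure under 10 mmHg are dropped.
5. **Assembly.** Greedy non-overlapping windows of n = 60 consecutive
   slices; runs broken by dropped beats are never bridged; no beat appears
   in two samples; remainders under n are discarded.
6. **Inclusion.** A subject is kept iff at least one of its sequences spans
   strictly more than 10 mmHg (max − min).
7. **Split.** Per subject, chronologically: first ⌊0.7k⌋ samples to train,
   next ⌊0.1k⌋ to validation, remainder to test, so training data always
   precedes test data in time. Subjects with k < 3 go entirely to train.

## Evaluation

MAE over all beats; Rseq, the mean within-sequence Pearson correlation
(zero-variance sequences are excluded with a logged count); VE, the mean
absolute difference between the first-order difference sequences with
1/(n−1) per-sequence normalisation — the average-real-variability-based
trend error, invariant to level shifts of the prediction. Signed errors use
the pred − gt convention with a population-denominator SD. Beat-averaged
variants use non-overlapping 10-beat means (capped at n/2 beats per window
for short sequences). A sequence is *unsteady* when its span strictly
exceeds 10 mmHg; unsteady — the clinically alarming class — is the positive
class in the ACC/precision/recall/F1 report. AAMI: pass iff |ME| ≤ 5 mmHg,
SD ≤ 8 mmHg and ≥ 85 subjects. BHS: cumulative percentages of absolute
errors within 5/10/15 mmHg; a grade requires all three thresholds with
inclusive boundaries (A: 60/85/95, B: 50/75/90, C: 40/65/85, else D).
Bland–Altman: mean difference, ±1.96·SD limits, percentage within.

## Synthetic data generator

The simulator emits paired PPG/ABP at 125 Hz with known per-beat truth:

* **SBP trajectory** = per-subject base + bounded random walk
  (`steady_sigma`, default 0.6 mmHg/beat, clipped to 60–220 mmHg) +
  hill-shaped surges: raised-cosine bumps of 10–30 mmHg over 40 beats at
  0.5 events/min (deterministic count ≥ 1 whenever the rate is positive, so
  an 8-minute record always contains an unsteady window).
* **ABP**: each beat is a unit pulse (fast systolic upstroke, slower decay
  with a dicrotic shoulder) rescaled per beat so its grid maximum equals the
  beat's SBP exactly and its minimum the DBP; pulse pressure tracks SBP with
  a 12 mmHg floor. Labels recovered from ABP peaks at true onsets are
  therefore exact by construction.
* **PPG**: two Gaussians per beat (systolic wave + dicrotic wave at 65 % of
  the cycle), amplitude linear in absolute SBP (+2 %/mmHg around a 120 mmHg
  reference, the same coupling for every subject so SBP level is decodable
  from morphology) and systolic-peak latency shrinking with SBP, plus
  two-tone baseline wander (0.05–0.35 Hz) and white noise. Cycle lengths
  vary around 60/HR with fractional jitter. Cohorts draw per-subject resting
  SBP ~ N(base, 8 mmHg) and heart rate ~ N(75, 6 bpm).

The generator stores K+1 onsets for K labelled beats (the last onset marks
the trailing partial beat kept in the signal), so K inter-onset intervals
align exactly with the K labels.

What the simulator does **not** emulate: Windkessel/transfer-function
hemodynamics, pulse-wave-velocity effects, arrhythmia, motion artifacts,
sensor saturation, or the noise statistics of ICU monitoring data. Passing
tests on this generator demonstrate that the pipeline, model and metrics are
implemented correctly and that the architecture can learn a morphology→SBP
mapping of realistic geometry; they say nothing quantitative about
performance on real recordings.

## Desk-scale study sizes

Full-scale training (60-cycle contexts, hundreds of subjects, 500 epochs) is
a GPU workload. The packaged studies exercise the identical code at sizes a
single CPU handles in minutes, fixed once as the package's study conditions:
60 subjects × 120 s, n = 15 cycles per sample, reduced model (8 base
channels, 1 Trans-RPE layer, r = 2), 30 epochs at lr 1e-3 (learning rate
raised for the shortened schedule; 1e-4 remains the default), 5-beat
averaging windows; and a memorisation check on 5 samples for 200 epochs.
The record-length screen scales to 100 s for these short records.

## Numerical choices and edge cases

* Instance/layer norm use ε = 1e-5; softmax subtracts a detached maximum.
* Sequence boundaries: ΔSBP of exactly 10 mmHg is *steady* (strict "over"),
  and the same strict rule governs subject inclusion.
* Zero-variance sequences: excluded from Rseq (undefined correlation) with
  a warning; an all-flat evaluation raises rather than returning NaN.
* Fewer than 2 onsets, or fewer than n usable slices, yield empty outputs
  with warnings rather than errors.
* Non-finite training loss aborts with a diagnostic rather than continuing.
* HDF5 is the container for records and datasets (CSV/JSON sidecars for
  two-column export); checkpoints are a single `.npz` with the model config
  and output transform embedded.

## Known limitations

The simulator's morphology–SBP coupling is idealised and noise-stationary;
onset-detection accuracy (≈98 % within ±3 samples at low noise) degrades on
heavily corrupted signals, and no signal-quality index beyond the stated
screens is computed. The optional MAT reader covers the common cell-array
layout of the public ICU waveform subset but is untested against every
export variant. DBP estimation is supported as a labelling mode, not a
jointly trained second output.
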