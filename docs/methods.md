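# Methods

`ppgvitals` estimates arterial systolic blood pressure (ASBP), arterial
diastolic blood pressure (ADBP), and peripheral oxygen saturation (SpO₂)
from the photoplethysmogram (PPG) alone, using an encoder-only time-series
transformer that is pretrained by masked reconstruction and then fine-tuned
per patient.  This note documents the model, the processing pipeline, the
synthetic cohorts the package is validated on, and the numerical choices
made where the design was genuinely open.

## Signal model and preprocessing

Input records are multichannel ICU-style waveforms sampled at a known rate
(canonically 125 Hz) containing at least a PPG channel (`PLETH`) and an
invasive arterial pressure channel (`ABP`); an SpO₂ numeric channel is
optional.  Record-level inclusion requires at least 10 minutes of signal,
both required channels (channel-name matching is case-insensitive with an
extensible alias table, since header dialects vary), and a file payload of
at least 17 KiB.

Cleaning proceeds in a fixed order:

1. **Flat-part handling.**  A "flat" part is a run of ≥ 3 consecutive equal
   samples (equality with tolerance `eps`, default 0, appropriate for
   quantized signals; for `eps > 0` a run is grown while its max−min stays
   within `eps`).  If more than 5% of either the PPG or the ABP channel is
   flat the record is discarded; otherwise the flat samples (union over the
   two channels) are removed from *all* channels and the remainder is
   concatenated ("sutured").  Whether the 5% rule is per channel or joint
   was an open choice; the per-channel maximum is used as the stricter
   reading.
2. **Band-pass filtering of the PPG.**  A 4th-order Butterworth band-pass,
   0.5–8 Hz, applied forward–backward (`sosfiltfilt`).  Zero-phase
   application preserves beat timing relative to the ABP channel; the
   effective magnitude response is the square of the 4th-order design, so
   the stated stop-band attenuations are conservative.
3. **Cycle detection.**  Candidate systolic peaks are local maxima at least
   `60/200 s` apart (the fastest physiological rate considered) whose
   prominence is at least 0.3 of the local amplitude range (max−min over a
   rolling 5-s window); valleys are the minima between consecutive peaks
   plus the boundary minima.  The detector is deterministic and
   parameter-light; a flat line yields an empty cycle index.
4. **Hampel despiking of beat-wise ABP extrema.**  The per-beat peak and
   valley value series are filtered with a centered sliding window of 100
   values; a value is replaced by its window median when it deviates by
   more than 3 robust sigmas (σ = 1.4826 · MAD, the standard Hampel
   identifier).  Windows are truncated at the series edges.  The filter is
   applied to beat-wise extrema, not raw samples, because the spikes it
   must remove are per-beat label outliers.
5. **Segmentation.**  Consecutive, non-overlapping 20-s windows
   (2,500 samples at 125 Hz), starting at the onset of the first cardiac
   cycle; a trailing partial window is dropped.  If the first detected
   valley lies within half a beat period of sample 0 the segmentation
   starts at 0 — the displacement is then the band-pass filter's edge
   transient, not a real onset.  Indices are 0-based with half-open
   windows.
6. **Quality gating.**  A cycle is anomalous when its valley-to-valley
   length is outside [60/200, 60/20] s or its peak-to-valley amplitude
   deviates from the window median by more than 3 robust sigmas.  The MAD
   threshold is floored at 5% of the median amplitude: a robust scale
   estimated from ~20 nearly identical beats collapses toward zero, where
   the unfloored rule would flag float-level jitter.  A window qualifies iff
   at most 3 cycles are anomalous in *both* channels.
7. **Labels.**  ASBP = mean of the (despiked) ABP peak values in the
   window; ADBP = mean of the valley values; SpO₂ = mean of the SpO₂
   channel over the window when present (the simplest consistent choice —
   how per-slice SpO₂ ground truth should be aligned is not otherwise
   specified).  A slice must satisfy ASBP > ADBP with finite labels or it
   is rejected.

## EMD channelization

Each qualified PPG slice is decomposed by empirical mode decomposition:
cubic-spline envelopes through the local maxima/minima, envelope-mean
subtraction, per-mode stop on Huang's SD criterion ≤ 0.2 or 50 sifting
iterations, extraction stop when the remainder is monotone.  Boundary
swings are suppressed by mirroring the outermost extrema about the first
and last extremum positions, which continues a periodic signal exactly.
The residue is maintained as a running remainder, so IMFs + residue
reconstruct the input to float precision.

The model input is a 4×2,500 matrix: channels 1–3 are IMF1–IMF3 (zero
vectors when fewer modes exist) and channel 4 is the remainder
(input − channels 1–3).  Which EMD outputs form the channels was an open
choice; this scheme is lossless by construction — the channel sum equals
the raw slice exactly — so the encoder always sees complete information
while the leading channels isolate the fast components.

## Transformer encoder

Per time step t the w-channel sample x_t is projected as
z_t = W_p·x_t + b_p into D dimensions; a **learnable** positional encoding
W_pos (one D-vector per position, up to the configured maximum length) is
added; and the sequence passes through N post-norm encoder blocks:
multi-head scaled dot-product self-attention followed by layer
normalization, then a ReLU feed-forward sublayer followed by layer
normalization.  Shorter inputs are zero-padded; the padding mask sends
attention logits at padded key positions to −∞ before the softmax and
excludes padded positions from pooling, so predictions are provably
invariant to padding (asserted to 1e-5 in the tests).

Two heads share the encoder.  The regression head mean-pools the encoded
sequence over non-padded positions, applies a hidden layer of width 128
with ReLU, and maps linearly to one scalar per configured target.  Pooling
is the reduction of choice because Eq.-style per-position readouts are
ambiguous for a scalar target and mean-pooling is padding-consistent.  The
masked-reconstruction head is a per-position linear map back to the w
input channels.  Both objectives are mean squared error; the
reconstruction loss is restricted to masked positions.

Defaults (full scale): 3 layers, D = 128, 8 heads, feed-forward width 256,
dropout 0.1, attention scaled by √d_k.  Scaling by the sequence length √l
is also implemented (`attn_scale="sqrt_len"`) for fidelity to the printed
formula, but √d_k is the default since the length-scaled variant collapses
the logit range for long sequences.  Head count, feed-forward width,
dropout, and the masking ratio/span are package choices, not reported
values.

Per-sample, per-channel standardization (subtract mean, divide by SD over
non-padded positions) precedes the encoder; channels with zero spread pass
through centered.  Masking for pretraining zeroes contiguous spans
(geometric lengths, mean 3 samples) covering 15% of the non-padded
positions, drawn until the target count is covered and trimmed, so the
masked fraction is exact.  Masked positions additionally receive a
learnable **mask-token embedding**: a zeroed signal value alone is
ambiguous, because a standardized waveform crosses zero constantly, so
without the token the encoder cannot tell where reconstruction is required
and collapses to copying its input (measured directly during development —
the reconstruction loss pins at the signal variance).  Two further
initialization choices aid the reconstruction objective: the learnable
positional encodings start from the sinusoidal table (neighboring
positions begin correlated), and each layer's query and key matrices share
their initialization, so attention starts as a positive-semidefinite
similarity kernel with a built-in locality bias that training refines.

The network, its manual backward pass, and the Adam optimizer are
implemented directly in NumPy; the backward pass is verified against
central-difference numerical gradients in the test suite.  Attention is
evaluated one sample at a time so the (heads × l × l) score block stays
cache-resident, and the training studies run in float32 (float64 is the
default elsewhere; gradient checks use it).

## Training protocol

Splitting is patient-level (70/10/20 by count, seeded): no patient
contributes slices to more than one of the train/validation/test sets, and
patients with fewer than 10 qualified slices (< 200 s of usable signal)
are excluded with a logged reason.  Pretraining minimizes the masked
reconstruction MSE on the training patients' slices.  It can run either as
shuffled passes over the full-length slices or under a **crop
curriculum**: each optimization step draws a crop length from a configured
mixture (the study default is 60% quarter-length, 25% half-length, 15%
full-length crops at matched batch sizes) and trains on random crops.
With absolute positional encodings every position's attention pattern is
learned separately, so full-length-only training at a few hundred steps
never escapes mean prediction; short crops form the interpolation circuit
cheaply and the full-length fraction adapts the whole positional table —
held-out full-length reconstruction then reaches roughly the
linear-interpolation floor.  The pretraining learning rate and schedule
are otherwise the same as fine-tuning (the protocol names a learning rate
only for fine-tuning).

Personalization fine-tunes a copy of the pretrained encoder per test
patient: the patient's slices are ordered chronologically, the earliest
⌊0.2·n⌋ (minimum 1) form the fine-tuning set and the rest the evaluation
set, so later data never informs earlier predictions.  Within the
fine-tuning portion the last 20% (minimum 1 slice) is held out as the
early-stopping validation set — the evaluation slices are never touched
during training; the protocol leaves the fine-tuning validation set
underdetermined, so this chronology-preserving construction is the
package's choice.  Optimization uses Adam (standard moments — only the learning rate
is prescribed), learning rate 3e-3, multiplicative decay of 0.98/epoch
after epoch 50 (the decay coefficient's value being another open choice),
up to 200 epochs with patience 20, restoring the best-validation
checkpoint.

Regression targets are z-scored during optimization: the pooled model uses
the training cohort's label moments; a personalized model uses the
patient's own fine-tune-train moments (falling back to pooled SDs when
degenerate).  With only a handful of fine-tuning slices — a few gradient
steps at learning rate 3e-3 — per-patient label normalization is the
mechanism by which fine-tuning reaches a patient's operating point; at
full scale (dozens to hundreds of fine-tuning slices) the weights
themselves can travel the same distance.  Predictions are always returned
in physical units.

## Evaluation and standards

Errors are summarized by MAE, RMSE, the signed mean error (ME) and its
sample (n−1) SD, and the squared Pearson correlation r² (computed at slice
level).  Bland–Altman data are per-pair means and differences with limits
of agreement bias ± 1.96·SD.  The AAMI criterion passes iff the cohort has
more than 85 subjects, |ME| < 5 mmHg, and SD < 8 mmHg (strict
inequalities).  BHS grading computes the cumulative percentages of
absolute errors within 5/10/15 mmHg and assigns A/B/C/fail at the
60/85/95, 50/75/90, 40/65/85 thresholds; comparisons are inclusive (≤),
matching the standard's tabulated "≤ K mmHg" columns, with a strict-mode
flag.  Subgroup reports compute the same metrics per attribute group,
flagging (never dropping) groups below a minimum pair count.

## Synthetic cohorts

The generator emulates exactly the waveform features the pipeline
exercises.  One cardiac cycle is an asymmetric Gaussian systolic upstroke
(rise σ 0.08 cycles, fall σ 0.18) peaking at 0.3 of the cycle plus a
dicrotic bump (ratio 0.25, σ 0.07) 0.4 of a cycle later, evaluated with
wrapped phase so beats join smoothly, normalized to [0, 1] with the valley
at the cycle boundary.  The ABP channel is this shape rescaled per beat so
its peaks and valleys trace the ASBP/ADBP trajectories; the PPG channel is
the shape times the patient's pulse amplitude plus baseline and white
noise.

Ground truth is an explicit linear map: ASBP = 90 + 25·amplitude +
0.25·heart-rate + offset + ε, ADBP = 50 + 10·amplitude + 0.10·heart-rate +
0.5·offset + ε′, SpO₂ = 97.5 + (amplitude−1) − 0.01·(HR−80) + 0.05·offset
+ ε″ (clipped to ≤ 100%).  The label-noise processes ε are zero-mean
Gaussians held constant over 20-s blocks with SDs of 2 / 1.5 / 0.3
(mmHg, mmHg, %), so the slice-level label noise is directly the stated σ.
Cohorts draw heart rate ~ N(80, 15) bpm clipped to [45, 140], pulse
amplitude ~ N(1, 0.15), per-patient offsets ~ N(0, 10) mmHg, and PPG noise
SD 0.01.  Artifacts are injectable per plan: `flat_line` (constant hold on
both channels), `flat_peak` (clipping at 70% of pulse height), and
`motion_spike` (large transient bumps on the PPG).

What the generator does **not** emulate: real PPG morphology variation
(stiffness, reflection waves), baseline wander, heart-rate variability,
measurement drift between ABP and PPG, or any physiologic coupling beyond
the linear map.  Passing tests therefore demonstrate that the pipeline's
machinery — QC rules, decomposition, model, protocol, standards logic —
behaves as specified and can recover known structure; they say nothing
about accuracy on real ICU waveforms.

## Study scale

The training-based validation studies run at a deliberately desk-scale
size chosen once: 25 Hz sampling (a 20-s slice is 500 samples), a
30-patient cohort with 500-s records (~25 slices each), a 3-layer encoder
with D = 32, 2 heads, feed-forward width 64, no dropout, ~500 pretraining
slices for 8 epochs, pooled regression for up to 15 epochs (patience 5),
and per-patient fine-tuning under the full 200-epoch/patience-20 protocol.
The scientific structure — pipeline order, split protocol, losses, early
stopping — is identical to the full-scale configuration; only problem size
is reduced.  At this scale a fine-tuning set is ~5 slices, which is why
per-patient label statistics (above) carry the personalization.

## Known limitations

* EMD is the classical algorithm; mode mixing under intermittent noise is
  not addressed (no ensemble/CEEMDAN variants).
* The WFDB reader covers the single-segment, format-16 subset only.
* The cycle detector assumes a dominant periodicity; severe arrhythmia
  would be flagged as anomalous rather than tracked.
* r² is computed over slices, not per-patient means; with strong
  between-patient spread the slice-level value runs higher.
* The pure-NumPy trainer is single-threaded and cache-blocked for small
  models; it is not intended for full-scale (D = 128, l = 2,500, 10⁵+
  slices) training.
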