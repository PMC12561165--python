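# Methods

## Problem and scope

The package classifies single-lead ECG heartbeats into 12 classes — 11
anatomical myocardial-infarction locations (AMI, ALMI, ASMI, ASLMI, IMI,
ILMI, IPMI, IPLMI, LMI, PMI, PLMI) and healthy control (HC) — and localizes
the decision evidence on the time–frequency plane. It is built to run
end-to-end at desk scale on synthetic data with known ground truth; applying
it to real WFDB databases is supported through the record reader but large-
scale training results on such data are outside what the desk-scale tests
establish.

## Preprocessing

**Baseline removal.** Two cascaded median filters (200 ms, then 600 ms; both
configurable) estimate the baseline, which is subtracted. The short window
flattens QRS complexes so they do not leak into the baseline estimate; the
long window tracks sub-hertz drift. On a 0.3 Hz, 0.5 mV drift the residual
in-band power is below 1% of the injected power.

**Wavelet shrinkage.** Five-level db6 decomposition; each detail level b
(b = 1 finest) is soft-thresholded at

    TE_b = sigma_b * sqrt(2 ln N_b) / ln(b + 1),

where N_b is the coefficient count at level b and
sigma_b = median(|d_b|) / 0.6745 is the robust MAD noise estimate (0.6745 is
the 0.75 quantile of the standard normal). This is the universal threshold
scaled down at coarser levels, where cardiac energy dominates and noise
contributes less; natural logarithms are used (`threshold_log_base` config
key). The shrinkage operator kills |d| ≤ TE_b and shrinks the remainder
toward zero with the sign preserved. The level count is a config key; the
default is five levels.

**QRS detection.** Classic Pan–Tompkins: 5–15 Hz band-pass (2nd-order
Butterworth, zero-phase), derivative, squaring, 150 ms moving-window
integration, adaptive signal/noise thresholds with 0.125/0.875 exponential
updates, a 200 ms refractory period, and refinement of each detection to the
local maximum of the band-passed signal. The adaptive thresholds make
detections invariant to overall amplitude scaling. A flat signal returns an
empty list rather than an error.

**Segmentation.** Each beat is the inclusive window [R−250, R+400]
(651 samples at 1000 Hz, R at index 250). Peaks too close to a record
boundary are dropped and counted in the log.

## S-transform

The discrete Stockwell transform is computed in the frequency domain: for
each analysis frequency f, the signal spectrum is shifted by f, multiplied by
the voice Gaussian exp(−2π²ν²/f²), and inverse-transformed. The equivalent
time-domain window is a Gaussian of standard deviation 1/|f|, giving the
frequency-adaptive resolution that distinguishes the S-transform from a
fixed-window STFT while preserving absolute phase in the complex
intermediate. The zero-frequency row is defined as the signal mean (the |f|
prefactor vanishes at f = 0).

Rows sit on an exact integer grid (1 Hz by default) by zero-padding the
analysis FFT to a multiple of fs/Δf samples; the time axis is truncated back
to the input length. Padding introduces mild edge effects for signals much
shorter than the grid; segmented beats taper toward their window edges, which
keeps this small. The default band is 0–50 Hz (the clinically informative ECG
band plus powerline margin), so a beat maps to a ≤51-row image. Magnitude
(not log-magnitude) feeds the network by default; `log1p` is a toggle. The
FFT formulation is verified in the tests against a literal direct-sum
evaluation with a periodized time-domain Gaussian, to 1e-6 on signals up to
256 samples.

Model inputs are produced by corner-aligned bilinear resizing to side×side,
per-image min–max normalization to [0, 1] (a constant image maps to zeros),
and replication to 3 channels. STFT (Hann window) and Morlet-CWT images are
provided on the same container for the ablation switch.

## Diffusion-based rebalancing

The forward process is the variance-preserving chain
q(x_t|x_{t−1}) = N(√(1−β_t)x_{t−1}, β_t I) with strictly increasing
β_1 < … < β_T; its closed-form marginal √(ᾱ_t)x_0 + √(1−ᾱ_t)ε is used for
training draws and is Monte-Carlo-verified against the iterated chain. The
default schedule is linear β ∈ [1e-4, 0.02] with T = 1000 (the canonical
values); desk-scale runs and tests use T = 50 with β up to 0.05 so that
ᾱ_T ≈ 0.28 — small enough to scramble the signal at this horizon while
keeping sampling cheap. The reverse step uses
μ = (x_t − β_t/√(1−ᾱ_t)·ε_θ)/√(α_t) with σ_t² = β_t by default; the posterior
variance β_t(1−ᾱ_{t−1})/(1−ᾱ_t) is available as a config switch.

The noise predictor is a three-layer 1-D convolutional network whose input
stacks the noisy beat with fixed sinusoidal *position* channels and a
broadcast sinusoidal embedding of the timestep. The position channels matter:
a purely translation-invariant convolution cannot represent the
position-dependent mean of beat morphology, while with them the ε target —
affine in x_t with position- and time-dependent coefficients — is well within
the network's capacity. Training minimizes the simplified ε-prediction MSE
with Adam (the reverse-mean parameterization presupposes exactly this
objective). Beats are z-standardized per dataset before diffusion and
de-standardized after sampling.

Balancing trains one unconditional model per minority class (the simplest
reading of per-class generation; a class-conditional model is a possible
alternative, not implemented). Majority classes are downsampled by seeded
uniform choice without replacement; minority classes keep all real beats and
are topped up with synthetic ones flagged `source="synthetic"`. The
near-balance helper targets the median class count; exact targets can be
given in the plan. Synthetic beats are pinned to the training partition by
the splitter.

## The cascade

The backbone is a five-stage ResNet-50: 7×7/64 stem (stride 2), 3×3 max-pool
(stride 2), bottleneck stacks (1×1 → 3×3 → 1×1) repeated 3/4/6/3 with widths
64/128/256/512 (×4 expansion), batch normalization and ReLU throughout, and
stride-2 1×1 convolutions on the first block of each downsampling stage and
its projection shortcut. Counting the stem, the 48 bottleneck convolutions
and the classification head gives 50 trainable weight layers; a 3×224×224
input yields a 7×7×2048 feature map.

A 1×1 convolution compresses channels to d = 512 (presets 128–1536 mirror the
compression-dimension ablation), the map is flattened row-major into 49
tokens, a learnable per-position embedding (49 × d, Gaussian init std 0.02)
is added, a learnable class token is prepended, and dropout (0.1) is applied
to the sequence. Three post-norm Transformer encoder layers (8 heads,
feed-forward 4d, ReLU) model global context; per-layer attention maps are
retained for explainability. The class-token state feeds a fully connected
12-way head; softmax probabilities sum to one by construction. Convolutions
use He fan-out initialization; no pretrained weights anywhere — the model is
trained from scratch.

`width_divisor` scales every channel width jointly and `input_side` the
spatial budget, preserving the architecture while making CPU-scale training
tractable (the tests train a ÷8-width model on 64×64 inputs). Ablation
variants share the config surface: `variant="resnet"` replaces the encoder
with global average pooling + fc; `variant="vit"` patchifies the input
directly (linear patch embedding, same encoder).

**Training.** Cross-entropy with SGD (lr 0.001, momentum 0.9), batch 64,
60 epochs by default; desk-scale configs override these (the shipped smoke
config uses lr 0.01, batch 16, 6–10 epochs, matching what a ÷8-width model
needs on tens of images). A 10% stratified validation holdout supplies the
accuracy/loss curves. After each epoch the BatchNorm running statistics are
replaced by exact dataset statistics via a chunked forward sweep — with few
optimizer steps the default momentum-0.1 running estimates lag far behind the
trained weights, and inference-mode behaviour would otherwise misrepresent
the model.

## Splits and metrics

The inter-patient split deduplicates patients, partitions the patient set
≈8:2 (at least one patient on each side), and lets beats follow their
patients; disjointness is asserted on every split. The intra-patient split is
a beat-level stratified random split. Synthetic beats always go to train.

Metrics derive from the 12×12 confusion matrix by one-vs-rest reduction:
Acc = (TP+TN)/N, Sen = TP/(TP+FN), Pre = TP/(TP+FP), Spe = TN/(TN+FP),
F1 = 2·Sen·Pre/(Sen+Pre), all in percent, with unweighted (macro) averages
across classes — per-class accuracy is read as the one-vs-rest accuracy of
that class's binary reduction, the only reading that yields a per-class
accuracy column at all. Overall AccT is trace/total. Cells with zero
denominators are reported as NaN and excluded from macro averages with a log
note.

## Explainability

Grad-CAM: the gradient of the target-class logit w.r.t. a registered layer's
activations is spatially averaged into channel weights; the rectified
weighted activation sum is bilinearly upsampled to the input size and
max-normalized. Registered layers are the last backbone stage and the last
encoder layer's token grid (49 token relevances reshaped to 7×7). The map is
invariant to constant logit shifts and identically zero for a zero-weight
head. A band-energy helper reports the heatmap mass inside a frequency band
(e.g. 5–15 Hz, the QRS-energy band). Attribution through the S-transform back
to the raw 1-D waveform is not attempted: the transform is a fixed
preprocessing step with no learnable path to attribute through.

## Generation quality

FID fits Gaussians to feature sets of real and synthetic beats and evaluates
‖μ_r−μ_g‖² + Tr(Σ_r+Σ_g−2(Σ_rΣ_g)^{1/2}) with a symmetrized matrix square
root and diagonal jitter for near-singular covariances. The default feature
extractor is plain decimation (cheap and oracle-friendly); a trained-backbone
extractor (truncated at global pooling) is available. CRPS uses the exact
discrete identity E|X−y| − ½E|X−X′| per time point, averaged over time and
test beats, with a synthetic ensemble per real beat (50 members by default).
DTW uses absolute local cost with match/insert/delete steps; pairing is
seeded random within class ("counterpart" pairing is otherwise undefined),
with an optional Sakoe–Chiba band (default 50 in the report) for speed and a
bootstrap std over resampled pairings. Identical real/synthetic sets score
FID ≈ 0 and DTW ≈ 0; added noise strictly increases DTW.

## Synthetic data: what it does and does not emulate

Beats are sums of five Gaussian waves (P, Q, R, S, T) with defaults of
roughly physiological amplitude and timing at lead II; class morphology is
deliberately minimal — an ST-segment offset (smooth plateau over
60–140 ms post-R) and a Q-wave amplitude per class, anterior-type classes
shifting ST up, inferior/posterior-type classes deepening Q or depressing ST.
Noise comprises a 0.3 Hz sinusoidal baseline (0.15 mV), 50 Hz powerline
(0.05 mV) and white noise (0.02 mV), all configurable; R-R intervals carry
3% Gaussian jitter by default. Identical spec + seed reproduces the signal
bit-for-bit.

This makes the 12-class problem well-posed and every stage testable against
ground truth, but it does not reproduce inter-patient morphology variability,
real MI waveform diversity, electrode artefacts or arrhythmia. Passing tests
therefore demonstrate the correctness and trainability of the pipeline, not
clinical performance; accuracy numbers on this generator say nothing
quantitative about real ECG databases.

## Numerical choices and degenerate inputs

- Soft thresholding with TE = 0 is the identity; wavelet reconstruction error
  is below 1e-8 relative.
- Constant-range time–frequency images normalize to all-zero model inputs.
- A flat ECG yields no QRS detections (empty list, not an error); empty beat
  lists, empty coefficient vectors, single-patient inter-patient splits,
  out-of-range diffusion steps and mismatched feature dimensions raise
  validation errors.
- All internal indices are 0-based; WFDB sample numbering is preserved at the
  I/O boundary.
- Desk-scale problem sizes in the tests and acceptance script: 10 s records,
  ≤56 records per run, T = 50 diffusion steps with 150–400 training steps,
  ÷8-width cascade on 64×64 inputs for 6–10 epochs; the full-width cascade is
  exercised forward-only. These sizes were chosen so every check completes on
  one CPU in minutes while still exercising the genuine code paths.

## Known limitations

- The inter-patient accuracy of a scaled-down cascade on synthetic data is
  noisy across seeds; it is reported, not asserted against a fixed value.
- Per-class diffusion models (rather than one conditional model) multiply
  training cost by the number of minority classes.
- The WFDB reader covers the header + single-file format-16 layout only.
- DTW is exact dynamic programming (O(nm)); the optional band approximates it
  for long beats.
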