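# Methods

## Problem setting

Scalp EEG is recorded in fixed 2 s windows at 256 Hz (512 samples per
segment).  Physiological artifacts — ocular (EOG) and muscular (EMG)
activity — contaminate the recording additively and overlap the EEG rhythm
bands, so they cannot be removed by filtering alone.  The package trains a
dual-pathway autoencoder (DPAE) to map a contaminated segment back to its
clean counterpart and evaluates the result with the standard benchmark
metrics for this task.

## Contamination model

A contaminated segment is constructed linearly,

```
contaminated = clean + λ · artifact,
SNR = 10 · log10( RMS(clean) / RMS(λ · artifact) )   [dB],
RMS(x) = sqrt( (1/N) Σ x_i² ).
```

The artifact coefficient is solved from the target SNR,
`λ = (RMS(clean)/RMS(artifact)) · 10^(−SNR/10)`; smaller λ means larger SNR.
Note the SNR here is defined on the RMS *amplitude* ratio (the convention of
the benchmark datasets for this task), not on a power ratio.  Two direct
consequences used throughout the tests: the solved λ reproduces the
requested SNR to machine precision, and the untouched mixture has temporal
RRMSE exactly `10^(−SNR/10)` against its clean reference — at −7 dB the
mixture is wrong by a factor ≈ 5.01 in RMS.

Datasets are SNR-stratified over the ten integer levels −7 … 2 dB (the
benchmark's stated interval; integer steps).  Within each level artifact
segments are drawn without replacement; clean segments cycle through a
seeded permutation.  Global no-replacement across levels is not enforced —
at realistic counts it is infeasible, and the benchmark itself reuses
artifacts across levels.

## Surrogate sources

The package generates its own band-limited surrogates rather than
redistributing benchmark recordings:

- **clean EEG** — 1/f-weighted Gaussian noise plus one alpha-band
  (8–13 Hz) oscillation of random frequency/phase/amplitude, band-passed
  1–80 Hz;
- **EOG** — 1/f noise plus 0–3 blink-like Gaussian transients
  (50–200 ms wide, predominantly one-signed), band-passed 0.3–10 Hz;
- **EMG** — Gaussian noise amplitude-modulated by a random burst envelope,
  band-passed 1–120 Hz.

All band-passes are zero-phase forward–backward Butterworth filters (order
4; order 2 for the 0.3 Hz edge); edge transients are tolerated because
segments are isolated windows.  Every segment is normalized to unit RMS, so
λ depends only on the requested SNR.  What the surrogates reproduce is the
*band structure* of the benchmark sources, not their physiology: no
channel covariance, no non-stationarity beyond the burst envelope, no
line noise.  Passing tests therefore demonstrate that the architecture,
training loop and metrics behave as specified on signals with the stated
spectral structure — they do not certify performance on clinical
recordings.

A consequence worth stating: flat-spectrum EMG band-limited to 1–120 Hz
leaves ≈ 24% of artifact power inside 1–30 Hz where 1/f EEG concentrates.
An oracle per-frequency Wiener filter on these surrogates achieves a
temporal RRMSE of about 0.90 at −7 dB — there is very little headroom below
1.0 at the harshest levels, and the desk-scale trained model does not reach
it there (see Limitations).

## Architecture

The canonical 512-input fully connected DPAE (`canonical_mlp_table1`) is
hard-coded to the published reference widths:

- pathway 1 (shrinkage ratio 0.45): 230 → 103 → 46;
- pathway 2 (ratio 0.75, expand first): 680 → 511 → 383;
- concatenation (429) → batch norm → symmetric fusion block
  193 → 86 → 39 → 86 → 193;
- per-pathway projections back to 46 and 383, each summed with its
  pathway's pre-fusion output (residual connections), then 46 → 20 and
  383 → 287;
- concatenation (20 + 287 = 307) → batch norm → decoder 256 → linear
  output 512.

That is 16 trainable hidden layers.  All hidden layers use SeLU; the output
layer is linear, since a bounded or centred output activation would prevent
amplitude recovery in a regression.  Two printed widths are not reproducible
from the ratio rule (680 where 512/0.75 = 682.67 floors to 682, and 39 where
the floor chain gives 38); the canonical spec preserves the printed values,
while `derive_path_widths` implements the formula faithfully (and therefore
returns 682/38).  The reference table's second concatenation is wired from
the 20- and 287-wide layers — the only combination consistent with its
printed width 307.

Ablation variants: `no_fusion` removes the five fusion-block layers and
projects the normalized concatenation directly onto the two decoder
branches; `no_residual` removes the two elementwise additions.  All other
widths are unchanged.

Backbone variants share the dense fusion/residual/decoder tail:

- **cnn** — pathway 1 convolves with kernel 3 / stride 2, pathway 2 with
  kernel 5 / stride 4, three stages of (16, 32, 64) channels (configurable;
  the paper does not state channel counts), flattened before the fusion
  block.  With these defaults the flattened pathway widths (4096 and 512 at
  input 512) make the fusion projections dominate the parameter count.
- **rnn** — GRU pathways whose hidden-unit counts follow the same floor
  chains as the MLP widths (230/103/46 and 682/511/383).  The 512-sample
  window is presented as 64 time steps × 8 samples; the last hidden state
  of each pathway feeds the fusion block.  The step/feature split is a
  package choice — the source protocol does not state one — made so the
  recurrent depth stays tractable while the unit chains match the MLP.

`count_params` and `count_flops` use standard conventions: dense
`in·out + out` parameters and `2·in·out` FLOPs (2·MAC), batch norm `2·width`
for both, conv `c_out·c_in·k + c_out` and `2·c_in·k·c_out·l_out`, GRU
`3·(in·h + h² + h)` and `6·(in·h + h²)` per step.  Under these conventions
the canonical MLP has 1.57 M parameters and 3.13 M forward FLOPs.  The FLOP
convention of the published scale table is unstated, so these counts are
reported but not treated as a reproduction target.

## Training

Supervised pairs (contaminated input, clean target) are fit by minimizing
MSE with Adam.  Defaults follow the reference protocol: batch 128, learning
rate 1e-3, 200 epochs, per-epoch reshuffling from the config seed, no early
stopping (validation loss is recorded but unused).  Inputs and targets stay
in raw mixture/clean units; a config switch enables per-segment RMS scaling
for experimentation (it was not better on these surrogates).  Batch
normalization uses batch statistics in training and running statistics
(momentum 0.1) at inference, so inference is deterministic and
batching-independent; multichannel trials are denoised channel by channel,
which is bit-identical to single-segment inference.

The network stack is a small reverse-mode automatic-differentiation core
over numpy (`dpae.nn`): broadcast-aware elementwise ops, 2-D matmul,
concatenation/slicing, SeLU/sigmoid/tanh, a fused batch-norm op and a fused
im2col 1-D convolution, with LeCun-normal initialization (the
self-normalizing regime for SeLU) and Adam.  Every layer's gradient is
checked against central finite differences in the test suite.  Arithmetic is
float32; with fixed seeds, runs are bit-reproducible on a given BLAS.

## Evaluation metrics

For denoised output `y` and clean reference `x`:

```
RRMSE_temporal = RMS(y − x) / RMS(x)
RRMSE_spectral = RMS(PSD(y) − PSD(x)) / RMS(PSD(x))
CC             = cov(y, x) / (σ_y σ_x)
```

PSDs are Welch estimates — Hann taper, 256-sample windows, 50% overlap —
the estimator parameters are not fixed by the source protocol, so they are
fixed here and recorded in every result file.  Band powers integrate the
density over delta 1–4, theta 4–8, alpha 8–13, beta 13–30 and gamma
30–80 Hz by the trapezoidal rule.  Curves report the per-SNR-level mean
over test pairs with across-pair standard deviation (the error-bar
definition is a package choice); the untouched mixture is always evaluated
alongside as the no-denoising reference.

For presentation-normalization the package implements both the literal
benchmark phrasing ("subtract the standard deviation, divide by the max
absolute value", method `paper`) and the conventional zero-mean variant
(`zscore_max`); the phrase "subtracting the standard deviation" is most
likely a misstatement of "subtracting the mean", so both are kept and
neither is applied to training data.

## Experiment designs and problem sizes

Desk-scale defaults, chosen so each experiment runs in minutes on one CPU:

- **end-to-end run** — 2,000 training pairs (200 per level), 40 test pairs
  per level, 50 epochs;
- **ablation** — 1,000 training pairs (100 per level), the reference
  hyperparameters (batch 128, lr 1e-3, 200 epochs), one seed shared across
  the three variants with identical data order;
- **benchmark** — any subset of {mlp, cnn, rnn} plus an optional plain
  fully connected baseline (four equal-width SeLU hidden layers, default
  width 1024), all trained on the same dataset and tabulated with params
  and FLOPs;
- **multichannel** — 22-channel trials contaminated per level with EMG and
  denoised channel by channel.

Source pools are sized so nearly every pair uses a distinct clean and
artifact segment: surrogates are free, and small pools (hundreds of
segments behind thousands of pairs) measurably let the model memorize
sources instead of learning the mapping.  The paper-scale counts (4,478 or
2,720 pairs per level, 200 epochs) remain reachable through the config.

## Numerical choices and degenerate inputs

- Zero-power artifacts, zero-variance correlation inputs, all-equal
  normalization inputs and empty segments raise argument errors rather than
  propagating NaNs.
- `split_train_test` sizes the training side as `round(n · fraction)`
  (4,514 segments at 0.8 → 3,611/903).
- Non-finite training loss raises a divergence error carrying the epoch.
- Spec graphs are validated before building: concatenation widths must sum,
  addition widths must match, the output width must equal the input length;
  violations name the offending layer.

## Known limitations

- At the harshest SNR levels (−7, −6 dB) the desk-scale end-to-end run
  does not push temporal RRMSE below 1.0 (≈ 1.1 across seeds): the Wiener
  bound on these deliberately overlap-heavy surrogates is ≈ 0.90 there, and
  a 1.5 M-parameter model estimated from 2,000 pairs does not close that
  gap — held-out error at low SNR rises while training loss still falls.
  It does beat the raw-mixture reference at every level.
- On these surrogates the fusion block's 39-unit joint feature is a binding
  information bottleneck: removing the residual bypasses degrades the final
  loss far more than removing the fusion block, so the two ablations order
  differently than on the real benchmark (where the fusion block matters
  more).  The full model is best in both settings.
- The CNN variant's parameter count is dominated by the flatten-width
  fusion projections and far exceeds the published scale for that variant;
  channel counts are configurable.
- Surrogate realism limits are listed above; nothing here validates
  performance on real multichannel recordings.
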