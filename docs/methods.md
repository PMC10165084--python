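# Methods

## Problem

A motor-imagery BCI montage measures scalp potentials on a regular grid of
22 electrodes (2.5 cm pitch, Cz at the centre, 250 Hz sampling). When an
electrode is absent or damaged, its signal must be synthesized from the
channels that were measured. `eegcomplete` trains a small sparse-attention
encoder–decoder that maps four measured channels to one *complementary*
(virtual) channel, and provides the evaluation and correction toolkit around
it: MSE and Pearson ρ, baseline and amplitude corrections, an
inverse-distance interpolation baseline, bad-channel flagging, and a
cross-subject transfer harness.

## Montage geometry

The grid is planar: rows Fz / FC3–FC4 / C5–C6 / CP3–CP4 / P1–Pz–P2 / POz
with 2.5 cm spacing on both axes and Cz = channel 10 at the origin. Scalp
curvature is not modelled; all "average distance" conditions are Euclidean
distances on this plane. The standard input conditions this geometry
produces: {1, 8, 12, 20}→Cz averages 5.0 cm; {2, 6, 14, 18}→Cz averages
5.5902 cm (5.59 at two decimals); {4, 9, 11, 16}→Cz averages 2.5 cm; the
maximal-distance set {1, 7, 13, 22}→Cz averages 6.875 cm. The last value is
sometimes quoted as 6.8 cm; we report the computed 6.875.

## Preprocessing

Bandpass 2–40 Hz (4th-order Butterworth, zero-phase forward–backward —
zero phase so filtering never shifts channels relative to each other), then
per-channel z-score followed by min–max rescaling to [0, 1]. Both steps are
invertible; `NormalizationParams` stores mean, SD and post-z-score min/max
per channel. Statistics are fitted on the training split only and applied
to held-out data (`apply_normalization`, which clips to [0, 1] because a
test session can slightly exceed the training range). The choice to fit on
the training split is ours: fitting on test data would leak its statistics
into the evaluation.

## Model

Windows of `L = 48` samples of the `d_x = 4` input channels are embedded
per time step by a linear map into `d_model` dimensions after an affine
shift of the [0, 1] amplitudes to [−1, 1]; the shift centres the value
embedding on the same scale as the positional encoding, which measurably
speeds optimisation. Positions are encoded sinusoidally with base `2·L`
(components `sin/cos(pos / (2L)^(2j/d_model))`) — positions never exceed
the window, so a short base spreads phases over it. Pair indices `j` count
from 0.

The encoder stacks two layers of multi-head ProbSparse self-attention with
a distilling step after each layer. ProbSparse attention ranks queries by
the sparsity measure `M(q, K) = LSE_j(q·k_j/√d) − mean_j(q·k_j/√d)`
(`M ≥ ln L_K`, equality iff all scores are equal), gives the top
`u = ⌈5·ln L_Q⌉` queries full softmax attention over all keys, and fills
every other output row with the mean of the value rows (the "lazy"
average-distribution fallback). The sparsity scores are estimated from
`min(L_K, ⌈L_K·ln L_Q⌉)` sampled keys; at the window lengths used here that
cap always selects *all* keys, so inference is deterministic without any
sampling RNG. Distilling is a kernel-3 zero-padded 1-D convolution, ELU,
then max pooling with kernel 3 / stride 2 / pad 1, halving the length:
48 → 24 → 12 tokens through the stack, so layer 2 attends over 24 tokens
and the decoder memory holds 12.

The one-layer decoder takes the `L′ = 24`-sample *label window* — the
slice of the same four input channels starting at offset `t_s` inside the
encoder window (constraints `t_s ≥ 0`, `t_s + L′ − 1 ≤ L − 1`; default
`t_s = L − L′`, the trailing half). It applies causal masked self-attention,
dense cross-attention to the encoder memory, and a linear head that emits
all 24 output samples in one pass (generative-style, no autoregression). No
placeholder token is needed: this is completion, not forecasting, and the
target channel is simply absent from the decoder input. Global timestamp
embeddings (hour/day/week) are deliberately omitted — EEG is non-stationary
and such covariates carry no useful signal at window scale.

Residual blocks are pre-norm (LayerNorm on the sublayer input, residual on
the raw stream). With post-norm the final LayerNorm erases per-token
amplitude before the linear head and the network must reconstruct scale
indirectly; in our experiments that capped the recoverable correlation on
the identity sanity task. Feed-forward blocks are two linear maps with
ReLU, width `d_ff` (default `4·d_model`). Weights are Glorot-uniform except
the output projection, which is zero-initialized: the network starts at the
constant-zero map and grows its readout from data. (With a Glorot head,
constant-learning-rate Adam never shrinks the readout — its per-coordinate
normalization random-walks small weights — and trivially representable
constant targets stall several orders of magnitude above the achievable
loss.) Dropout (default 0.05) applies after each sublayer during training
only.

Reference hyperparameters: `d_model = 128`, 16 heads, 2 encoder layers,
1 decoder layer, window 48, label 24, dropout 0.05, Adam at 0.001, batch
128, 3 epochs (a 15-epoch "thorough" preset is also exposed; both counts
are in circulation for this architecture and neither is silently
preferred). One undocumented setting named "Bias" with value 4 appears in
the reference table; it has no definition and is not implemented.

## Training and completion

Training minimizes the MSE between the predicted and true label windows,
averaged over the full window. Everything is seeded: weight init from
`ModelConfig.seed`, shuffling/dropout from `TrainingRun.seed`; identical
settings reproduce the loss history bit for bit. Training windows tile the
recording at a configurable stride (default `L′`, i.e. non-overlapping
labels).

`complete_channel` synthesizes a full-length signal: windows slide at
stride `L′/2`, overlapping label predictions are averaged per time point,
and the recording is reflect-padded at both ends so the head (before the
first label offset) and tail receive genuine model predictions rather than
constant fill — constant fill of even 24 samples measurably depresses ρ.
Output is clipped to [0, 1] (the normalized amplitude range).

## Evaluation and corrections

* `E` (MSE): mean over the window of squared differences. The defining
  formula is written with a `1/N` prefactor and a sum to `L` with `N`
  undefined; we take `N = L`. All reported MSEs are on the normalized
  [0, 1] scale unless the caller denormalizes first.
* `ρ`: Pearson product-moment correlation; errors on constant signals.
* Baseline correction: subtract the mean (ρ-preserving by construction).
* Amplitude correction: `α = Σ|P_l| / Σ|P̂_l|`; `α·P̂` has the same total
  absolute amplitude as the reference. Useful for edge electrodes, whose
  synthesized amplitude is systematically low.
* Interpolation baseline: `C_p = Σ η_i C_i`, `η_i ∝ 1/d_i`, weights
  normalized to sum to 1 — the classical spatial baseline.
* Bad-channel rule: flag when ρ(measured, complementary) falls below a
  threshold (default 0.5, exposed) or when the baseline-corrected MSE
  exceeds a configurable multiple of a historical reference value. The
  underlying idea — a damaged channel "lacks correlation" with its
  synthesized counterpart — fixes no numbers, so the defaults are ours.
* Transfer harness: a model trained on one subject completes the same
  channel on other subjects' recordings without retraining; results are
  reported as a per-subject table of E and ρ.

## Synthetic data

The generator emulates the *regime* of grid-montage motor-imagery
recordings — 22 channels, 250 Hz, 2–40 Hz content, strong short-range
spatial correlation — with known ground truth. Latent sources sit on grid
nodes; each is a band-limited stochastic oscillation (4th-order Butterworth
filtered white noise in a theta/alpha/beta band) plus a 30 % 1/f pink
background, band-limited to 2–40 Hz. Electrodes observe Gaussian
distance-attenuated mixtures (`exp(−d²/2σ²)`, σ = `spatial_decay`, default
4 cm — neighbours on a 2.5 cm grid stay strongly correlated), optionally
squashed by a mild tanh nonlinearity, plus independent sensor noise
(default SD 0.02 of the unit-scale mixture), scaled to tens of microvolts.
The mild nonlinearity exists so a learned model has something to beat
linear inverse-distance interpolation with; with a purely linear forward
model the interpolation baseline is near-optimal and the comparison is
vacuous. `generate_subject_pair` emulates two acquisition sessions: shared
mixing, fresh source/noise draws, and electrode positions displaced by
`jitter·2.5 cm` in the test session (cap placement shift).

Not emulated: head-model volume conduction, event-related motor-imagery
dynamics, ocular/muscle artifacts, electrode drift. Passing tests on this
generator demonstrate that the pipeline learns cross-channel spatial
structure under realistic spectra and noise — not that it reaches any
particular accuracy on real recordings.

## Scaled-down experiment protocol

The in-repository experiments (test suite and worked examples) use a
reduced configuration chosen to keep a full train/evaluate cycle under a
minute of CPU: `d_model = 16`, 4 heads, `d_ff = 32`, dropout 0.05, windows
48/24 at stride 12, Adam at 0.002, batch 8, 12 epochs, on 96 s of
synthetic signal split 70/30 train/test. At this scale the qualitative
results are stable across seeds: identity-task recovery reaches ρ ≈ 0.999,
the trained model beats inverse-distance interpolation on nonlinear
mixtures by several-fold in baseline-corrected MSE with ρ ≈ 0.99, and
completion quality decreases monotonically with input-to-target distance.

## Numerical notes

* The autodiff engine is float64 throughout; max pooling pads with
  `min(x) − 1` rather than a huge negative sentinel, which would suffer
  catastrophic cancellation inside `a + relu(b − a)`.
* ProbSparse top-`u` selection uses a stable argsort; ties break toward the
  earlier query. Gradients flow through the gathered rows only (the
  selection itself is treated as constant, as usual for top-k routing).
* The causal mask adds −10⁹ to masked scores before the softmax.
* `normalize` rejects zero-variance channels; `pearson_rho` rejects
  constant signals; `bandpass_filter` validates band edges against Nyquist.
* EDF/GDF files are read through `mne` (optional extra). EDF writing is not
  supported; the interchange format is delimited text (header of channel
  ids, one sample per row, `# rate_hz=... units_state=...` comment line).

## Known limitations

* One model per target channel (`d_y = 1`); completing many channels means
  training many models.
* The numpy training loop is single-core and suits the small reference
  architecture; it is not a GPU replacement.
* Amplitude correction needs a reference signal, so it applies to repair
  and diagnostics, not to channels that were never measured.
* Real-EEG performance claims are out of scope here; the synthetic
  generator cannot stand in for subject variability or artifacts.
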