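# eegcomplete

Synthesize **virtual EEG acquisition channels**: given a handful of measured
electrodes, reconstruct the signal of an unmeasured or damaged channel.

Motor-imagery BCIs face a trade-off: more electrodes capture more cortical
information, but long setup times, cap-placement drift and broken channels
make dense montages impractical. `eegcomplete` addresses this with a small
sparse-attention encoder–decoder that learns, from a short recording, the
mapping from four measured channels to one *complementary* channel — a
channel that can then be fed to downstream pipelines as if it had been
measured, used to repair a damaged electrode, or compared against a
suspect electrode to flag it as bad.

## The model

Windows of `L = 48` samples of the `d_x = 4` input channels (22-electrode
grid montage, 2.5 cm pitch, 250 Hz, bandpassed to 2–40 Hz and normalized to
[0, 1] per channel) pass through:

* sinusoidal positional encoding with base `2L`:
  `PE(pos, 2j) = sin(pos / (2L)^(2j/d_model))`, cosine on odd components;
* a 2-layer encoder of multi-head **ProbSparse self-attention**: queries are
  ranked by the sparsity measure
  `M(q, K) = ln Σ_j exp(q·k_j/√d) − (1/L_K) Σ_j q·k_j/√d`,
  the top `u = ⌈5 ln L_Q⌉` queries receive full softmax attention
  `softmax(Q̄Kᵀ/√d)V`, and the remaining output rows take the mean of the
  value rows;
* **self-attention distilling** between layers — conv1d, ELU, stride-2 max
  pooling — halving the sequence: 48 → 24 → 12 tokens;
* a 1-layer generative decoder over the label window (the trailing
  `L′ = 24` samples of the input window): causal self-attention, cross
  attention to the encoder memory, and a linear head that emits all 24
  samples in one pass.

Training minimizes window MSE (`E = (1/L) Σ_l (P_l − P̂_l)²`) with Adam.
Reconstructions are scored by `E` and Pearson `ρ` after optional *baseline
correction* (mean removal) and *amplitude correction*
(`α = Σ|P_l| / Σ|P̂_l|`), and compared against inverse-distance
interpolation `C_p = Σ_i η_i C_i`, `η_i ∝ 1/d_i` — the classical spatial
baseline. A synthetic-data generator (band-limited sources on the grid,
Gaussian distance attenuation, optional mild nonlinearity) makes the whole
pipeline runnable and testable without any recordings.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

Complete the central Cz electrode (channel 10) from the four electrodes
5 cm away (channels 1, 8, 12, 20) on a synthetic subject:

```python
import numpy as np
from eegcomplete import (
    ModelConfig, SyntheticConfig, TrainingRun, WindowSpec, Recording,
    apply_normalization, bandpass_filter, build_2a_layout, complete_channel,
    evaluate_completion, generate_recording, interpolate_channel,
    make_windows, normalize, train_model, mean_input_distance,
)

layout = build_2a_layout()
print("mean distance {1,8,12,20} -> Cz:",
      mean_input_distance(layout, [1, 8, 12, 20], 10), "cm")

raw, _ = generate_recording(
    layout, SyntheticConfig(duration_s=96, nonlinearity="mild", seed=11))
filt = bandpass_filter(raw)                      # 2-40 Hz, zero phase
cut = int(filt.n_samples * 0.7)
train_raw = Recording(filt.data[:, :cut], filt.rate, filt.channel_ids, "filtered")
test_raw = Recording(filt.data[:, cut:], filt.rate, filt.channel_ids, "filtered")
train, params = normalize(train_raw)             # stats from the training split only
test = apply_normalization(test_raw, params)

inputs, target = [1, 8, 12, 20], 10
samples = make_windows(train, inputs, target, WindowSpec(48, 24, stride=12))
config = ModelConfig(d_model=16, n_heads=4, d_ff=32, seed=0)   # desk-scale network
model, run = train_model(samples, config,
                         TrainingRun(epochs=12, batch_size=8,
                                     learning_rate=2e-3, seed=0))

completed = complete_channel(model, test, inputs)
m = evaluate_completion(test.channel(target), completed.data[0], baseline=True)
interp, _ = interpolate_channel(test, layout, inputs, target)
mi = evaluate_completion(test.channel(target), interp, baseline=True)
print(f"model:         MSE = {m.mse:.2e}, rho = {m.rho:.4f}")
print(f"interpolation: MSE = {mi.mse:.2e}, rho = {mi.rho:.4f}")
```

Output:

```
mean distance {1,8,12,20} -> Cz: 5.0 cm
model:         MSE = 1.90e-03, rho = 0.9898
interpolation: MSE = 1.19e-02, rho = 0.9498
```

The learned completion tracks the held-out Cz signal with ρ ≈ 0.99 on the
normalized scale and roughly a sixth of the interpolation baseline's
baseline-corrected MSE — the nonlinear spatial mixing is exactly what a
fixed inverse-distance weighting cannot capture.

The same flow is available from the shell:

```bash
eegcomplete simulate --seed 7 --duration 60 --out data/
eegcomplete train data/recording.tsv --inputs 1,8,12,20 --target 10 \
    --config config.yaml --seed 1 --checkpoint model.npz
eegcomplete complete data/recording.tsv --checkpoint model.npz --out completed.tsv
eegcomplete evaluate data/recording.tsv completed.tsv --target 10 \
    --interpolate-inputs 1,8,12,20
eegcomplete flag-bad data/recording.tsv completed.tsv --channel 10
```

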