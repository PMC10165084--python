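"""Windowed datasets, MSE training, and full-length channel completion.

A training sample is one encoder window of the input channels (length ``L``),
the decoder label window (length ``L'``, a slice of the same input channels
starting at offset ``t_s`` inside the window), and the target channel over
that label window.  The label window lies entirely inside the input window
(``t_s >= 0`` and ``t_s + L' - 1 <= L - 1``): the synthesized stretch is
conditioned on input context both before and after it, which is what
distinguishes completion from forecasting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Adam, Tensor
from .model import CompletionInformer, ModelConfig
from .signal_io import Recording

__all__ = [
    "WindowSpec",
    "WindowedSample",
    "TrainingRun",
    "make_windows",
    "train_model",
    "complete_channel",
]


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the sliding windows.

    ``t_s`` defaults to ``L - L'`` (the label is the trailing half of the
    window).  ``stride`` is the hop between consecutive windows.
    """

    L: int = 48
    label_len: int = 24
    t_s: int | None = None
    stride: int = 24

    def __post_init__(self) -> None:
        if self.t_s is None:
            object.__setattr__(self, "t_s", self.L - self.label_len)
        if self.L <= 0 or self.label_len <= 0 or self.stride <= 0:
            raise ValueError("window lengths and stride must be positive")
        if not (0 <= self.t_s and self.t_s + self.label_len - 1 <= self.L - 1):
            raise ValueError(
                f"label window [t_s={self.t_s}, t_s+L'-1={self.t_s + self.label_len - 1}] "
                f"must lie inside the input window [0, {self.L - 1}]"
            )


@dataclass(frozen=True)
class WindowedSample:
    """One training/inference sample cut from a recording."""

    enc_in: np.ndarray  # (L, n_inputs)
    dec_in: np.ndarray  # (L', n_inputs)
    label: np.ndarray | None  # (L', 1) target slice; None at pure inference
    enc_pos: np.ndarray  # (L,) relative positions 0..L-1
    dec_pos: np.ndarray  # (L',) relative positions t_s..t_s+L'-1
    start: int  # sample index of the window start in the recording


@dataclass
class TrainingRun:
    """Optimization settings plus the per-epoch loss history."""

    epochs: int = 3
    batch_size: int = 128
    learning_rate: float = 0.001
    seed: int = 0
    loss_history: list[float] = field(default_factory=list)


#: Named epoch presets; "standard" is the default, "thorough" the longer
#: schedule for difficult targets.
EPOCH_PRESETS = {"standard": 3, "thorough": 15}


def make_windows(
    rec: Recording,
    inputs,
    target: int | None,
    spec: WindowSpec,
) -> list[WindowedSample]:
    """Tile a recording into windowed samples.

    ``target`` may be None when the channel is genuinely absent (inference on
    a device without that electrode); labels are then None.  Trailing partial
    windows are dropped.
    """
    if rec.units_state != "normalized":
        raise ValueError("recording must be normalized before windowing")
    inputs = [int(c) for c in inputs]
    if target is not None and target in inputs:
        raise ValueError("target channel must not be an input channel")
    if rec.n_samples < spec.L:
        raise ValueError(
            f"recording has {rec.n_samples} samples; need at least L = {spec.L}"
        )
    X = rec.select(inputs).T  # (n_samples, n_inputs)
    y = rec.channel(target) if target is not None else None
    enc_pos = np.arange(spec.L)
    dec_pos = np.arange(spec.t_s, spec.t_s + spec.label_len)
    samples = []
    for start in range(0, rec.n_samples - spec.L + 1, spec.stride):
        lo = start + spec.t_s
        hi = lo + spec.label_len
        samples.append(
            WindowedSample(
                enc_in=X[start : start + spec.L],
                dec_in=X[lo:hi],
                label=None if y is None else y[lo:hi, None],
                enc_pos=enc_pos,
                dec_pos=dec_pos,
                start=start,
            )
        )
    return samples


def train_model(
    samples: list[WindowedSample],
    config: ModelConfig,
    run: TrainingRun | None = None,
    model: CompletionInformer | None = None,
) -> tuple[CompletionInformer, TrainingRun]:
    """Train a completion network by minimizing window-averaged MSE.

    Fully seeded: weight init comes from ``config.seed``, and shuffling /
    dropout / key sampling from ``run.seed``, so two runs with identical
    settings produce identical loss histories.
    """
    run = replace(run) if run is not None else TrainingRun()
    run.loss_history = []
    if not samples:
        raise ValueError("no training samples")
    if any(s.label is None for s in samples):
        raise ValueError("all training samples need labels")
    if model is None:
        model = CompletionInformer(config)
    enc = np.stack([s.enc_in for s in samples])
    dec = np.stack([s.dec_in for s in samples])
    lab = np.stack([s.label for s in samples])
    enc_pos, dec_pos = samples[0].enc_pos, samples[0].dec_pos

    rng = np.random.default_rng(run.seed)
    opt = Adam(model.parameters(), lr=run.learning_rate)
    n = len(samples)
    for epoch in range(run.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, run.batch_size):
            idx = order[lo : lo + run.batch_size]
            opt.zero_grad()
            pred = model._forward_t(enc[idx], dec[idx], enc_pos, dec_pos, rng)
            diff = pred - Tensor(lab[idx])
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // run.batch_size}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        run.loss_history.append(float(np.mean(epoch_losses)))
    return model, run


def complete_channel(
    model: CompletionInformer,
    rec: Recording,
    inputs,
    spec: WindowSpec | None = None,
) -> Recording:
    """Synthesize the complementary channel over a whole recording.

    Windows slide at ``spec.stride`` (default ``L'/2`` for smooth
    stitching); overlapping label predictions are averaged per time point.
    Samples never covered by any label window (a head shorter than ``t_s``
    and a tail shorter than ``L - t_s - L'``) take the value of the nearest
    predicted sample.
    """
    cfg = model.config
    if spec is None:
        spec = WindowSpec(cfg.seq_len, cfg.label_len, stride=max(1, cfg.label_len // 2))
    if spec.L != cfg.seq_len or spec.label_len != cfg.label_len:
        raise ValueError("window spec does not match the model configuration")
    if rec.n_samples < spec.L:
        raise ValueError("recording shorter than one window")

    # reflect-pad so label windows cover the whole recording, including the
    # head (before the first label offset t_s) and tail
    pad_head = spec.t_s
    pad_tail = spec.L - spec.t_s - spec.label_len
    padded = np.pad(rec.data, ((0, 0), (pad_head, pad_tail)), mode="reflect")
    prec = Recording(padded, rec.rate, rec.channel_ids, rec.units_state)
    samples = make_windows(prec, inputs, None, spec)
    last_start = prec.n_samples - spec.L
    if samples[-1].start != last_start:
        tail_rec = Recording(
            padded[:, last_start:], rec.rate, rec.channel_ids, rec.units_state
        )
        extra = make_windows(tail_rec, inputs, None, replace(spec, stride=spec.L))[0]
        samples.append(replace_start(extra, last_start))

    acc = np.zeros(prec.n_samples)
    cover = np.zeros(prec.n_samples)
    batch = 256
    for lo in range(0, len(samples), batch):
        chunk = samples[lo : lo + batch]
        enc = np.stack([s.enc_in for s in chunk])
        dec = np.stack([s.dec_in for s in chunk])
        pred = model.forward(enc, dec, chunk[0].enc_pos, chunk[0].dec_pos)
        for s, p in zip(chunk, pred):
            a = s.start + spec.t_s
            acc[a : a + spec.label_len] += p[:, 0]
            cover[a : a + spec.label_len] += 1
    covered = cover > 0
    acc[covered] /= cover[covered]
    if not covered.all():  # possible when stride > label_len
        idx = np.flatnonzero(covered)
        missing = np.flatnonzero(~covered)
        nearest = idx[np.abs(missing[:, None] - idx[None, :]).argmin(axis=1)]
        acc[missing] = acc[nearest]
    out = acc[pad_head : pad_head + rec.n_samples]
    data = np.clip(out, 0.0, 1.0)[None, :]
    return Recording(data, rec.rate, (-1,), "normalized")


def replace_start(sample: WindowedSample, start: int) -> WindowedSample:
    return WindowedSample(
        sample.enc_in, sample.dec_in, sample.label, sample.enc_pos, sample.dec_pos, start
    )
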