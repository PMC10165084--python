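"""Shared fixtures.

The two heavy fixtures (``identity_experiment`` and ``mixture_experiment``)
each train one scaled-down completion network once per session; several
tests then interrogate the same trained model from different angles.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.signal import butter, sosfiltfilt

from eegcomplete.evaluation import evaluate_completion, interpolate_channel
from eegcomplete.model import ModelConfig
from eegcomplete.montage import build_2a_layout
from eegcomplete.signal_io import Recording, apply_normalization, bandpass_filter, normalize
from eegcomplete.synthetic import SyntheticConfig, generate_recording
from eegcomplete.training import TrainingRun, WindowSpec, complete_channel, make_windows, train_model

# scaled-down network + optimization settings used by all in-suite trainings
TEST_MODEL = dict(d_model=16, n_heads=4, d_ff=32, dropout=0.05)
TEST_RUN = dict(epochs=12, batch_size=8, learning_rate=2e-3)
TEST_STRIDE = 12


@pytest.fixture(scope="session")
def layout():
    return build_2a_layout()


def bandlimited_recording(seed: int, n_samples: int, n_channels: int = 4) -> Recording:
    """A normalized recording of independent 2-40 Hz channels plus a copy of
    channel 1 appended as channel ``n_channels + 1`` (the identity target)."""
    sos = butter(4, [2, 40], btype="bandpass", fs=250, output="sos")
    x = sosfiltfilt(sos, np.random.default_rng(seed).standard_normal((n_channels, n_samples)))
    x = (x - x.min(axis=1, keepdims=True)) / np.ptp(x, axis=1)[:, None]
    data = np.vstack([x, x[0:1]])
    ids = tuple(range(1, n_channels + 2))
    return Recording(data, 250.0, ids, "normalized")


@pytest.fixture(scope="session")
def identity_experiment():
    """Train on the sanity task where the target channel *is* input channel 1."""
    train = bandlimited_recording(seed=7, n_samples=24000)
    test = bandlimited_recording(seed=8, n_samples=6000)
    inputs, target = [1, 2, 3, 4], 5
    samples = make_windows(train, inputs, target, WindowSpec(48, 24, stride=TEST_STRIDE))
    model, run = train_model(
        samples, ModelConfig(seed=0, **TEST_MODEL), TrainingRun(seed=0, **TEST_RUN)
    )
    completed = complete_channel(model, test, inputs)
    return {
        "model": model,
        "run": run,
        "test": test,
        "inputs": inputs,
        "target": target,
        "completed": completed.data[0],
        "truth": test.channel(target),
    }


def train_completion_on_synthetic(layout, inputs, target, seed,
                                  nonlinearity="mild", duration_s=96.0):
    """Full pipeline on synthetic data: generate, filter, normalize (training
    split only), train, complete the held-out split.  Returns a result dict."""
    cfg = SyntheticConfig(duration_s=duration_s, nonlinearity=nonlinearity, seed=seed)
    raw, truth = generate_recording(layout, cfg)
    filt = bandpass_filter(raw)
    cut = int(filt.n_samples * 0.7)
    train_raw = Recording(filt.data[:, :cut], filt.rate, filt.channel_ids, "filtered")
    test_raw = Recording(filt.data[:, cut:], filt.rate, filt.channel_ids, "filtered")
    train, params = normalize(train_raw)
    test = apply_normalization(test_raw, params)
    samples = make_windows(train, inputs, target, WindowSpec(48, 24, stride=TEST_STRIDE))
    model, run = train_model(
        samples, ModelConfig(seed=seed, **TEST_MODEL), TrainingRun(seed=seed, **TEST_RUN)
    )
    completed = complete_channel(model, test, inputs)
    return {
        "model": model,
        "run": run,
        "train": train,
        "test": test,
        "params": params,
        "completed": completed.data[0],
        "truth": test.channel(target),
        "inputs": inputs,
        "target": target,
        "mixing": truth,
    }


@pytest.fixture(scope="session")
def mixture_experiment(layout):
    """Completion of Cz from the 5-cm input ring on mildly nonlinear data."""
    return train_completion_on_synthetic(layout, [1, 8, 12, 20], 10, seed=11)


@pytest.fixture(scope="session")
def mixture_baseline(layout, mixture_experiment):
    """Inverse-distance interpolation of the same held-out target."""
    exp = mixture_experiment
    interp, weights = interpolate_channel(
        exp["test"], layout, exp["inputs"], exp["target"]
    )
    metrics = evaluate_completion(exp["truth"], interp, baseline=True)
    return {"signal": interp, "weights": weights, "metrics": metrics}
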