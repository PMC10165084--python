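"""Completion metrics, signal corrections, the interpolation baseline,
bad-channel flagging and the cross-subject transfer harness.

Metrics are reported on the normalized [0, 1] amplitude scale unless the
caller denormalizes first.  Two light-weight corrections mirror common BCI
preprocessing: *baseline correction* (mean removal, so measured and
synthesized channels share a zero reference) and *amplitude correction*
(rescaling by the ratio of total absolute amplitudes, Pearson-correlation
preserving).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montage import ElectrodeLayout, pairwise_distance

__all__ = [
    "CompletionMetrics",
    "InterpolationWeights",
    "mse",
    "pearson_rho",
    "baseline_correct",
    "amplitude_correct",
    "interpolate_channel",
    "flag_bad_channel",
    "evaluate_completion",
    "transfer_evaluation",
]


@dataclass(frozen=True)
class CompletionMetrics:
    """Quality of one synthesized channel against its measured reference."""

    mse: float
    rho: float
    alpha: float | None = None
    baseline_corrected: bool = False
    amplitude_corrected: bool = False

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("MSE must be non-negative")
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho must lie in [-1, 1]")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be positive when defined")


@dataclass(frozen=True)
class InterpolationWeights:
    """Inverse-distance weights eta_i and the distances d_i they came from."""

    weights: np.ndarray
    distances_cm: np.ndarray
    channel_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.distances_cm, dtype=float)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("interpolation weights must sum to 1")
        if np.any(w <= 0):
            raise ValueError("interpolation weights must be positive")
        order_w = np.argsort(-w, kind="stable")
        order_d = np.argsort(d, kind="stable")
        if not np.allclose(w[order_w], w[order_d]):
            raise ValueError("weights must be inversely ordered with distance")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "distances_cm", d)


def _as_signal(x, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise ValueError(f"signal must have at least {min_len} samples")
    return x


def mse(P, P_hat) -> float:
    """Mean squared error between a reference signal and its reconstruction."""
    P, P_hat = _as_signal(P), _as_signal(P_hat)
    if P.shape != P_hat.shape:
        raise ValueError(f"length mismatch: {P.size} vs {P_hat.size}")
    return float(np.mean((P - P_hat) ** 2))


def pearson_rho(P, P_hat) -> float:
    """Pearson product-moment correlation; 1 means fully correlated signals."""
    P, P_hat = _as_signal(P, 2), _as_signal(P_hat, 2)
    if P.shape != P_hat.shape:
        raise ValueError(f"length mismatch: {P.size} vs {P_hat.size}")
    if np.ptp(P) == 0 or np.ptp(P_hat) == 0:
        raise ValueError("correlation is undefined for a constant signal")
    return float(stats.pearsonr(P, P_hat).statistic)


def baseline_correct(sig) -> np.ndarray:
    """Remove the mean so the signal is referenced to zero."""
    sig = _as_signal(sig)
    return sig - sig.mean()


def amplitude_correct(P, P_hat) -> tuple[float, np.ndarray]:
    """Rescale ``P_hat`` so its total absolute amplitude matches ``P``.

    Returns ``(alpha, alpha * P_hat)`` with
    ``alpha = sum |P_l| / sum |P_hat_l|``.
    """
    P, P_hat = _as_signal(P), _as_signal(P_hat)
    denom = np.abs(P_hat).sum()
    if denom == 0:
        raise ValueError("cannot amplitude-correct an all-zero signal")
    alpha = float(np.abs(P).sum() / denom)
    return alpha, alpha * P_hat


def interpolate_channel(
    rec, layout: ElectrodeLayout, inputs, target: int
) -> tuple[np.ndarray, InterpolationWeights]:
    """Inverse-distance-weighted interpolation of the target channel.

    ``C_p = sum_i eta_i C_i`` with ``eta_i = (1/d_i) / sum_l (1/d_l)``,
    where ``d_i`` is the electrode distance from input ``i`` to the target.
    The classical spatial baseline the learned model is compared against.
    """
    inputs = [int(c) for c in inputs]
    if target in inputs:
        raise ValueError("target channel must not be an input channel")
    d = np.array([pairwise_distance(layout, c, target) for c in inputs])
    if np.any(d == 0):
        raise ValueError("an input electrode is coincident with the target")
    inv = 1.0 / d
    eta = inv / inv.sum()
    signal = eta @ rec.select(inputs)
    return signal, InterpolationWeights(eta, d, tuple(inputs))


def flag_bad_channel(
    measured,
    complementary,
    rho_threshold: float = 0.5,
    mse_reference: float | None = None,
    mse_multiple: float = 3.0,
) -> tuple[bool, dict]:
    """Decide whether a measured channel is damaged or heavily disturbed.

    The channel is flagged when its correlation with the model's
    complementary signal falls below ``rho_threshold``, or — when a
    historical baseline-corrected MSE ``mse_reference`` is supplied — when
    the current baseline-corrected MSE exceeds ``mse_multiple`` times it.
    Returns ``(flag, diagnostics)``.
    """
    if not 0.0 < rho_threshold < 1.0:
        raise ValueError("rho_threshold must lie in (0, 1)")
    rho = pearson_rho(measured, complementary)
    err = mse(baseline_correct(measured), baseline_correct(complementary))
    flag = rho < rho_threshold
    if mse_reference is not None and err > mse_multiple * mse_reference:
        flag = True
    return flag, {"rho": rho, "mse_baseline_corrected": err,
                  "rho_threshold": rho_threshold}


def evaluate_completion(
    true_target,
    complementary,
    baseline: bool = False,
    amplitude: bool = False,
) -> CompletionMetrics:
    """Apply the requested corrections, then report MSE, rho and alpha."""
    P = _as_signal(true_target, 2)
    P_hat = _as_signal(complementary, 2)
    if P.shape != P_hat.shape:
        raise ValueError(f"length mismatch: {P.size} vs {P_hat.size}")
    alpha = None
    if amplitude:
        alpha, P_hat = amplitude_correct(P, P_hat)
    if baseline:
        P = baseline_correct(P)
        P_hat = baseline_correct(P_hat)
    return CompletionMetrics(
        mse=mse(P, P_hat),
        rho=pearson_rho(P, P_hat),
        alpha=alpha,
        baseline_corrected=baseline,
        amplitude_corrected=amplitude,
    )


def transfer_evaluation(
    model,
    subjects: dict[str, tuple],
    inputs,
    target: int,
    spec=None,
    baseline: bool = True,
) -> pd.DataFrame:
    """Evaluate one trained model across several subjects' recordings.

    ``subjects`` maps a subject label to ``(normalized recording, true
    target signal)``.  The model is *not* retrained: this is the transfer
    setting, where a network fitted on one person's data completes the same
    channel for everyone else.  Returns a table with columns
    ``subject, target_channel, mse, rho``.
    """
    from .training import complete_channel

    rows = []
    for name, (rec, truth) in subjects.items():
        completed = complete_channel(model, rec, inputs, spec)
        m = evaluate_completion(truth, completed.data[0], baseline=baseline)
        rows.append({"subject": name, "target_channel": target,
                     "mse": m.mse, "rho": m.rho})
    return pd.DataFrame(rows)
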