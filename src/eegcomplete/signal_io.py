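"""Recording container, file I/O and preprocessing.

Preprocessing follows the usual motor-imagery pipeline: bandpass to the
2-40 Hz EEG band, then per-channel standardization (z-score) followed by
min-max rescaling so every channel lies in [0, 1].  Both transforms are
invertible; :class:`NormalizationParams` stores what is needed to map model
output back to filtered units.

The interchange format is delimited text: a header row of channel ids, one
sample per line, one column per channel.  EDF and GDF files are read through
:mod:`mne` when it is installed (``pip install eegcomplete[edf]``).  EDF
writing is not supported; use the delimited format.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "Recording",
    "NormalizationParams",
    "read_recording",
    "write_recording",
    "bandpass_filter",
    "normalize",
    "denormalize",
]

UnitsState = Literal["raw", "filtered", "normalized"]


@dataclass(frozen=True)
class Recording:
    """A multichannel potential matrix with sampling rate and channel ids.

    ``data`` is channels x samples.  ``units_state`` tracks where the
    recording sits in the preprocessing pipeline: ``raw`` (as read),
    ``filtered`` (bandpassed) or ``normalized`` (each channel in [0, 1]).
    """

    data: np.ndarray
    rate: float
    channel_ids: tuple[int, ...]
    units_state: UnitsState = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"data has {data.shape[0]} rows but {len(self.channel_ids)} channel ids"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite values")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.units_state == "normalized":
            if data.min() < -1e-9 or data.max() > 1 + 1e-9:
                raise ValueError("normalized recording must lie in [0, 1]")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_ids", tuple(int(c) for c in self.channel_ids))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, channel_id: int) -> np.ndarray:
        """The 1-D signal of one channel, by id."""
        try:
            row = self.channel_ids.index(int(channel_id))
        except ValueError:
            raise KeyError(f"unknown channel id: {channel_id!r}") from None
        return self.data[row]

    def select(self, channel_ids) -> np.ndarray:
        """Stack several channels into a (len(ids), n_samples) array."""
        return np.stack([self.channel(c) for c in channel_ids])


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel affine parameters of the standardize + min-max transform."""

    mean: np.ndarray
    std: np.ndarray
    post_min: np.ndarray
    post_max: np.ndarray
    channel_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        for name in ("mean", "std", "post_min", "post_max"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.channel_ids)
        if not all(
            getattr(self, name).shape == (n,)
            for name in ("mean", "std", "post_min", "post_max")
        ):
            raise ValueError("parameter arrays must be aligned with channel_ids")
        if np.any(self.std <= 0):
            raise ValueError("standard deviation must be positive per channel")
        if np.any(self.post_max <= self.post_min):
            raise ValueError("post-standardization max must exceed min per channel")


def write_recording(rec: Recording, path) -> None:
    """Write a recording as delimited text (header of channel ids).

    The sampling rate is stored in a ``# rate_hz=...`` comment on the first
    line so the file round-trips through :func:`read_recording`.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# rate_hz={rec.rate} units_state={rec.units_state}\n")
        df = pd.DataFrame(rec.data.T, columns=[str(c) for c in rec.channel_ids])
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def _read_delimited(path: Path) -> Recording:
    rate = 250.0
    units_state: UnitsState = "raw"
    with path.open() as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        for token in first[1:].split():
            key, _, value = token.partition("=")
            if key == "rate_hz":
                rate = float(value)
            elif key == "units_state":
                units_state = value  # type: ignore[assignment]
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if df.empty:
        raise ValueError(f"no samples in {path}")
    if df.isna().any().any():
        raise ValueError(f"malformed delimited recording (missing values): {path}")
    ids = tuple(int(c) for c in df.columns)
    return Recording(df.to_numpy(dtype=float).T, rate, ids, units_state)


def _read_mne(path: Path, fmt: str) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF/GDF requires mne; install the 'edf' extra"
        ) from exc
    reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_gdf
    raw = reader(str(path), preload=True, verbose="error")
    data = raw.get_data()
    return Recording(data, float(raw.info["sfreq"]), tuple(range(1, data.shape[0] + 1)))


def read_recording(
    path, format: Literal["edf", "gdf", "delimited"] = "delimited"
) -> Recording:
    """Read a multichannel recording in ``raw`` units state.

    Channel order is preserved from the file; EDF/GDF channels are assigned
    ids 1..n in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_delimited(path)
    if format in ("edf", "gdf"):
        return _read_mne(path, format)
    raise ValueError(f"unknown format: {format!r}")


def bandpass_filter(rec: Recording, low: float = 2.0, high: float = 40.0) -> Recording:
    """Zero-phase bandpass (4th-order Butterworth, forward-backward).

    The 2-40 Hz default keeps the physiological EEG band and rejects drift
    and power-line interference.  Zero-phase filtering avoids group-delay
    shifts that would misalign channels.
    """
    nyquist = rec.rate / 2.0
    if not (0 < low < high < nyquist):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyquist} Hz); "
            f"got low={low}, high={high}"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered, units_state="filtered")


def normalize(rec: Recording) -> tuple[Recording, NormalizationParams]:
    """Standardize then min-max rescale each channel to [0, 1].

    Returns the normalized recording plus the parameters needed by
    :func:`denormalize`.  Statistics are computed on ``rec`` itself; to avoid
    leakage, fit on the training split and apply to test data with
    :func:`apply_normalization`.
    """
    mean = rec.data.mean(axis=1)
    std = rec.data.std(axis=1)
    if np.any(std == 0):
        bad = [rec.channel_ids[i] for i in np.flatnonzero(std == 0)]
        raise ValueError(f"constant channel(s) (zero variance): {bad}")
    z = (rec.data - mean[:, None]) / std[:, None]
    post_min = z.min(axis=1)
    post_max = z.max(axis=1)
    params = NormalizationParams(mean, std, post_min, post_max, rec.channel_ids)
    return apply_normalization(rec, params), params


def apply_normalization(rec: Recording, params: NormalizationParams) -> Recording:
    """Apply previously fitted normalization parameters to a recording.

    Values are clipped to [0, 1]: a test session can slightly exceed the
    training session's range.
    """
    _check_params(rec, params)
    z = (rec.data - params.mean[:, None]) / params.std[:, None]
    span = (params.post_max - params.post_min)[:, None]
    scaled = (z - params.post_min[:, None]) / span
    return replace(rec, data=np.clip(scaled, 0.0, 1.0), units_state="normalized")


def denormalize(rec: Recording, params: NormalizationParams) -> Recording:
    """Invert :func:`normalize`, mapping [0, 1] back to filtered units."""
    _check_params(rec, params)
    span = (params.post_max - params.post_min)[:, None]
    z = rec.data * span + params.post_min[:, None]
    data = z * params.std[:, None] + params.mean[:, None]
    return replace(rec, data=data, units_state="filtered")


def denormalize_channel(
    x: np.ndarray, params: NormalizationParams, channel_id: int
) -> np.ndarray:
    """Invert the normalization of a single channel given by id."""
    try:
        i = params.channel_ids.index(int(channel_id))
    except ValueError:
        raise KeyError(f"channel {channel_id} not in normalization params") from None
    z = x * (params.post_max[i] - params.post_min[i]) + params.post_min[i]
    return z * params.std[i] + params.mean[i]


def _check_params(rec: Recording, params: NormalizationParams) -> None:
    if rec.channel_ids != params.channel_ids:
        raise ValueError(
            "normalization params were fitted for different channels: "
            f"{params.channel_ids} vs {rec.channel_ids}"
        )
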