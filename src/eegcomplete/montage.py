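"""Electrode montage geometry for the 22-channel motor-imagery grid.

The montage is a regular planar grid with 2.5 cm pitch centred on Cz
(channel 10).  Scalp curvature is deliberately not modelled: all distance
conditions used to select input channels ("5 cm ring", "average distance
5.59 cm", ...) are defined on this flat grid.  Channel ids are 1-based,
matching the usual "1st ... 22nd channel" numbering of the layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeLayout",
    "build_2a_layout",
    "pairwise_distance",
    "mean_input_distance",
    "load_layout",
    "save_layout",
]

# Rows of the grid, anterior (frontal) at +y, left at -x.  Each entry is
# (channel id, 10-20 name, x_cm, y_cm).  Pitch is 2.5 cm on both axes and
# Cz (channel 10) sits at the origin.
_PITCH_CM = 2.5
_GRID_ROWS: list[tuple[tuple[int, str], ...]] = [
    ((1, "Fz"),),
    ((2, "FC3"), (3, "FC1"), (4, "FCz"), (5, "FC2"), (6, "FC4")),
    ((7, "C5"), (8, "C3"), (9, "C1"), (10, "Cz"), (11, "C2"), (12, "C4"), (13, "C6")),
    ((14, "CP3"), (15, "CP1"), (16, "CPz"), (17, "CP2"), (18, "CP4")),
    ((19, "P1"), (20, "Pz"), (21, "P2")),
    ((22, "POz"),),
]
_ROW_Y_CM = (5.0, 2.5, 0.0, -2.5, -5.0, -7.5)


@dataclass(frozen=True)
class ElectrodeLayout:
    """2-D electrode coordinates (cm) for an EEG montage.

    Attributes
    ----------
    channel_ids : tuple of int
        Ordered 1-based channel ids.
    positions : ndarray, shape (n_channels, 2)
        (x, y) coordinates in centimetres.
    names : tuple of str
        Standard 10-20 labels, aligned with ``channel_ids``.
    """

    channel_ids: tuple[int, ...]
    positions: np.ndarray
    names: tuple[str, ...]
    _index: Mapping[int, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n_channels, 2)")
        if pos.shape[0] != len(self.channel_ids) or len(self.names) != len(self.channel_ids):
            raise ValueError("channel_ids, positions and names must be aligned")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(
            self, "_index", {cid: i for i, cid in enumerate(self.channel_ids)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def position_of(self, channel_id: int) -> np.ndarray:
        try:
            return self.positions[self._index[channel_id]]
        except KeyError:
            raise KeyError(f"unknown channel id: {channel_id!r}") from None

    def name_of(self, channel_id: int) -> str:
        return self.names[self._index[channel_id]]

    def id_of(self, name: str) -> int:
        for cid, nm in zip(self.channel_ids, self.names):
            if nm == name:
                return cid
        raise KeyError(f"unknown channel name: {name!r}")

    def translated(self, dx: float, dy: float) -> "ElectrodeLayout":
        return ElectrodeLayout(
            self.channel_ids, self.positions + np.array([dx, dy]), self.names
        )


def build_2a_layout() -> ElectrodeLayout:
    """Construct the fixed 22-electrode grid (2.5 cm pitch, Cz at the origin).

    Rows, anterior to posterior: Fz / FC3-FC4 / C5-C6 / CP3-CP4 / P1-Pz-P2 /
    POz.  Channel 10 is Cz.
    """
    ids: list[int] = []
    names: list[str] = []
    xy: list[tuple[float, float]] = []
    for row, y in zip(_GRID_ROWS, _ROW_Y_CM):
        half = (len(row) - 1) / 2.0
        for k, (cid, name) in enumerate(row):
            ids.append(cid)
            names.append(name)
            xy.append(((k - half) * _PITCH_CM, y))
    return ElectrodeLayout(tuple(ids), np.array(xy), tuple(names))


def pairwise_distance(layout: ElectrodeLayout, a: int, b: int) -> float:
    """Euclidean distance in cm between electrodes ``a`` and ``b``."""
    return float(np.linalg.norm(layout.position_of(a) - layout.position_of(b)))


def mean_input_distance(
    layout: ElectrodeLayout, inputs: Iterable[int], target: int
) -> float:
    """Arithmetic mean of the input-to-target electrode distances in cm.

    This is the "average distance" used to characterise how far a set of
    measured channels sits from the channel being synthesised.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("inputs must be non-empty")
    if target in inputs:
        raise ValueError(f"target channel {target} must not be an input channel")
    return float(np.mean([pairwise_distance(layout, i, target) for i in inputs]))


def save_layout(layout: ElectrodeLayout, path) -> None:
    """Write a layout as a tab-separated table (id, name, x_cm, y_cm)."""
    df = pd.DataFrame(
        {
            "id": layout.channel_ids,
            "name": layout.names,
            "x_cm": layout.positions[:, 0],
            "y_cm": layout.positions[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_layout(path) -> ElectrodeLayout:
    """Read a layout table written by :func:`save_layout`."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "name", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"layout table must have columns {sorted(required)}")
    return ElectrodeLayout(
        tuple(int(i) for i in df["id"]),
        df[["x_cm", "y_cm"]].to_numpy(dtype=float),
        tuple(str(n) for n in df["name"]),
    )


def bundled_2a_table() -> str:
    """The bundled grid layout as TSV text (id, name, x_cm, y_cm)."""
    buf = io.StringIO()
    save_layout(build_2a_layout(), buf)
    return buf.getvalue()


def _write_bundled() -> None:  # pragma: no cover - packaging helper
    with resources.files("eegcomplete").joinpath("data/layout_2a.tsv").open("w") as fh:
        fh.write(bundled_2a_table())
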