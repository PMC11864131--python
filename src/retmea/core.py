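"""Core data model for retinal multi-electrode-array (MEA) recordings.

Everything downstream — the synthetic generator, the PSTH classifier, the
Naka-Rushton fitter, the flicker statistics and the graft-area labeler —
operates on the containers defined here.

Units are fixed package-wide and never mixed: time in seconds, rates in Hz,
distances in µm, voltages in µV, light intensity in photoisomerizations per
rod per second (R*/rod/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ElectrodeGrid",
    "SpikeTrain",
    "FieldTrace",
    "Epoch",
    "StimulusProtocol",
    "MaskImage",
    "Recording",
    "default_mea60",
    "ProtocolError",
]

#: default analog sampling rate, Hz ("digitized at 20 kHz")
DEFAULT_SAMPLING_RATE = 20_000.0


class ProtocolError(ValueError):
    """Raised for ill-formed stimulus protocols (overlap, bad intensity...)."""


@dataclass(frozen=True)
class ElectrodeGrid:
    """Planar MEA electrode layout.

    Attributes
    ----------
    ids : tuple of int
        Unique electrode identifiers.
    positions_um : (n, 2) ndarray
        Electrode center coordinates, µm.
    pitch_um : float
        Inter-electrode distance, µm.
    electrode_size_um : float
        Side length of the (square) electrode, µm.
    """

    ids: tuple[int, ...]
    positions_um: np.ndarray
    pitch_um: float = 200.0
    electrode_size_um: float = 30.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions_um must be an (n, 2) array")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("electrode ids must be unique")
        if pos.shape[0] != len(self.ids):
            raise ValueError("positions/ids length mismatch")
        object.__setattr__(self, "positions_um", pos)

    def __len__(self) -> int:
        return len(self.ids)

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions_um[self.ids.index(electrode_id)]


def default_mea60(pitch_um: float = 200.0, electrode_size_um: float = 30.0) -> ElectrodeGrid:
    """The standard 60-electrode layout: 8x8 grid minus the four corners.

    Coordinates are centered on the array so the grid centroid is (0, 0).
    """
    ids, pos = [], []
    next_id = 1
    for row in range(8):
        for col in range(8):
            if (row, col) in {(0, 0), (0, 7), (7, 0), (7, 7)}:
                continue
            ids.append(next_id)
            pos.append(((col - 3.5) * pitch_um, (row - 3.5) * pitch_um))
            next_id += 1
    return ElectrodeGrid(tuple(ids), np.array(pos), pitch_um, electrode_size_um)


@dataclass(frozen=True)
class SpikeTrain:
    """A spike-sorted unit: strictly increasing spike times on one electrode."""

    unit_id: str
    electrode_id: int
    times: np.ndarray  # seconds

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FieldTrace:
    """Per-electrode local field potential (micro-ERG source signal)."""

    electrode_id: int
    samples_uv: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        s = np.asarray(self.samples_uv)
        if not np.issubdtype(s.dtype, np.floating):
            s = s.astype(np.float64)  # keep float32 traces as-is to bound memory
        object.__setattr__(self, "samples_uv", s)

    @property
    def duration(self) -> float:
        return self.samples_uv.size / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples_uv.size) / self.sampling_rate


@dataclass(frozen=True)
class Epoch:
    """One stimulus epoch on the absolute recording time axis.

    ``kind`` is "flash" or "flicker".  ``frequency_hz`` is only meaningful
    for flicker epochs.  Intensities are in R*/rod/s.
    """

    kind: str
    onset: float
    offset: float
    intensity: float
    background: float = 0.0
    frequency_hz: float | None = None
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("flash", "flicker"):
            raise ProtocolError(f"unknown epoch kind {self.kind!r}")
        if self.offset <= self.onset:
            raise ProtocolError("epoch offset must exceed onset")
        if self.intensity <= 0:
            raise ProtocolError("stimulus intensity must be positive (R*/rod/s)")
        if self.kind == "flicker" and (self.frequency_hz is None or self.frequency_hz <= 0):
            raise ProtocolError("flicker epoch requires a positive frequency")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping stimulus epochs on a single time axis."""

    epochs: tuple[Epoch, ...]
    duration: float

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        for a, b in zip(eps, eps[1:]):
            if b.onset < a.offset:
                raise ProtocolError(
                    f"epochs overlap: [{a.onset}, {a.offset}] and [{b.onset}, {b.offset}]"
                )
        if eps and eps[-1].offset > self.duration:
            raise ProtocolError("protocol duration does not cover all epochs")
        object.__setattr__(self, "epochs", eps)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def flash_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.kind == "flash"]

    def flicker_epochs(self, frequency_hz: float | None = None) -> list[Epoch]:
        eps = [e for e in self.epochs if e.kind == "flicker"]
        if frequency_hz is not None:
            eps = [e for e in eps if np.isclose(e.frequency_hz, frequency_hz)]
        return eps

    def dark_intervals(self, min_length: float = 0.0) -> list[tuple[float, float]]:
        """Maximal stimulus-free intervals, longest-first filterable by length."""
        out: list[tuple[float, float]] = []
        t = 0.0
        for e in self.epochs:
            if e.onset - t >= min_length and e.onset > t:
                out.append((t, e.onset))
            t = max(t, e.offset)
        if self.duration - t >= min_length and self.duration > t:
            out.append((t, self.duration))
        return out


@dataclass(frozen=True)
class MaskImage:
    """Binary fluorescence footprint with a pixel->µm affine placement.

    Pixel (row, col) maps to µm coordinates
    ``(x, y) = origin_um + um_per_px * (col, row)`` so the mask can be laid
    over the electrode grid.
    """

    data: np.ndarray  # bool, 2-D
    um_per_px: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=bool)
        if d.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def um_to_pixel(self, xy_um: Sequence[float]) -> tuple[int, int]:
        """Nearest pixel (row, col) for a µm coordinate."""
        x, y = float(xy_um[0]), float(xy_um[1])
        col = round((x - self.origin_um[0]) / self.um_per_px)
        row = round((y - self.origin_um[1]) / self.um_per_px)
        return int(row), int(col)


@dataclass
class Recording:
    """Complete MEA recording: grid, units, field traces, protocol, mask."""

    grid: ElectrodeGrid
    spike_trains: list[SpikeTrain]
    field_traces: list[FieldTrace]
    protocol: StimulusProtocol
    duration: float
    mask: MaskImage | None = None
    metadata: dict = field(default_factory=dict)

    def train(self, unit_id: str) -> SpikeTrain:
        for st in self.spike_trains:
            if st.unit_id == unit_id:
                return st
        raise KeyError(unit_id)

    def trace(self, electrode_id: int) -> FieldTrace:
        for tr in self.field_traces:
            if tr.electrode_id == electrode_id:
                return tr
        raise KeyError(electrode_id)
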