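"""On-disk recording container: a plain directory of JSON + CSV + array files.

Layout (documented in the README)::

    <dir>/
      meta.json           duration, sampling rate, schema version, metadata
      electrodes.csv      electrode_id, x_um, y_um
      spikes.csv          unit_id, electrode_id, t_s
      epochs.csv          kind, onset_s, offset_s, intensity, background,
                          frequency_hz, repeat_index
      traces/e<ID>.npy    float64 samples, µV   (or .csv with --trace-format)
      mask.npy            optional boolean graft mask
      mask.json           µm/pixel + origin for the mask

Two writes of the same Recording are byte-identical: key order, float
formatting and file order are all fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ElectrodeGrid,
    Epoch,
    FieldTrace,
    MaskImage,
    Recording,
    SpikeTrain,
    StimulusProtocol,
)

SCHEMA_VERSION = 1

__all__ = [
    "write_recording",
    "read_recording",
    "validate_recording",
    "refractory_qc",
    "Violation",
    "RecordingLoadError",
]


class RecordingLoadError(RuntimeError):
    """A member file is missing or corrupt; the message names the file."""


@dataclass(frozen=True)
class Violation:
    """One invariant breach found by :func:`validate_recording`."""

    kind: str
    target: str
    message: str


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_recording(rec: Recording, path: str | Path, trace_format: str = "npy") -> Path:
    """Serialize ``rec`` into directory ``path`` (created if needed)."""
    if trace_format not in ("npy", "csv"):
        raise ValueError("trace_format must be 'npy' or 'csv'")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    _json_dump(
        {
            "schema_version": SCHEMA_VERSION,
            "duration_s": rec.duration,
            "pitch_um": rec.grid.pitch_um,
            "electrode_size_um": rec.grid.electrode_size_um,
            "trace_format": trace_format,
            "metadata": rec.metadata,
        },
        root / "meta.json",
    )

    pd.DataFrame(
        {
            "electrode_id": list(rec.grid.ids),
            "x_um": rec.grid.positions_um[:, 0],
            "y_um": rec.grid.positions_um[:, 1],
        }
    ).to_csv(root / "electrodes.csv", index=False, float_format="%.6f")

    rows = [
        (st.unit_id, st.electrode_id, t)
        for st in rec.spike_trains
        for t in st.times
    ]
    pd.DataFrame(rows, columns=["unit_id", "electrode_id", "t_s"]).to_csv(
        root / "spikes.csv", index=False, float_format="%.7f"
    )
    # empty trains still need a row-less registry so they round-trip
    pd.DataFrame(
        [(st.unit_id, st.electrode_id) for st in rec.spike_trains],
        columns=["unit_id", "electrode_id"],
    ).to_csv(root / "units.csv", index=False)

    pd.DataFrame(
        [
            (e.kind, e.onset, e.offset, e.intensity, e.background,
             "" if e.frequency_hz is None else e.frequency_hz, e.repeat_index)
            for e in rec.protocol
        ],
        columns=["kind", "onset_s", "offset_s", "intensity", "background",
                 "frequency_hz", "repeat_index"],
    ).to_csv(root / "epochs.csv", index=False, float_format="%.6f")

    tdir = root / "traces"
    tdir.mkdir(exist_ok=True)
    for tr in sorted(rec.field_traces, key=lambda t: t.electrode_id):
        if trace_format == "npy":
            np.save(tdir / f"e{tr.electrode_id}.npy", tr.samples_uv)
        else:
            np.savetxt(tdir / f"e{tr.electrode_id}.csv", tr.samples_uv, fmt="%.6f")
    _json_dump(
        {
            "sampling_rate_hz": rec.field_traces[0].sampling_rate if rec.field_traces else 20000.0,
            "electrodes": sorted(tr.electrode_id for tr in rec.field_traces),
        },
        root / "traces" / "index.json",
    )

    if rec.mask is not None:
        np.save(root / "mask.npy", rec.mask.data)
        _json_dump(
            {"um_per_px": rec.mask.um_per_px, "origin_um": list(rec.mask.origin_um)},
            root / "mask.json",
        )
    return root


def _require(path: Path) -> Path:
    if not path.exists():
        raise RecordingLoadError(f"missing member file: {path.name}")
    return path


def read_recording(path: str | Path) -> Recording:
    """Load a recording container; inverse of :func:`write_recording`."""
    root = Path(path)
    if not root.is_dir():
        raise RecordingLoadError(f"not a recording directory: {root}")

    meta = json.loads(_require(root / "meta.json").read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise RecordingLoadError(
            f"schema-version mismatch in meta.json: "
            f"got {meta.get('schema_version')}, expected {SCHEMA_VERSION}"
        )

    edf = pd.read_csv(_require(root / "electrodes.csv"))
    grid = ElectrodeGrid(
        tuple(int(i) for i in edf["electrode_id"]),
        edf[["x_um", "y_um"]].to_numpy(float),
        float(meta["pitch_um"]),
        float(meta["electrode_size_um"]),
    )

    udf = pd.read_csv(_require(root / "units.csv"))
    sdf = pd.read_csv(_require(root / "spikes.csv"))
    by_unit = {uid: g["t_s"].to_numpy(float) for uid, g in sdf.groupby("unit_id")}
    trains = [
        SpikeTrain(str(r.unit_id), int(r.electrode_id),
                   by_unit.get(str(r.unit_id), np.empty(0)))
        for r in udf.itertuples()
    ]

    pdf = pd.read_csv(_require(root / "epochs.csv"))
    epochs = tuple(
        Epoch(
            kind=str(r.kind),
            onset=float(r.onset_s),
            offset=float(r.offset_s),
            intensity=float(r.intensity),
            background=float(r.background),
            frequency_hz=None if pd.isna(r.frequency_hz) else float(r.frequency_hz),
            repeat_index=int(r.repeat_index),
        )
        for r in pdf.itertuples()
    )
    protocol = StimulusProtocol(epochs, float(meta["duration_s"]))

    traces: list[FieldTrace] = []
    tindex = root / "traces" / "index.json"
    if tindex.exists():
        tmeta = json.loads(tindex.read_text())
        fs = float(tmeta["sampling_rate_hz"])
        fmt = meta.get("trace_format", "npy")
        for eid in tmeta["electrodes"]:
            fp = root / "traces" / f"e{eid}.{fmt}"
            try:
                samples = (np.load(_require(fp)) if fmt == "npy"
                           else np.loadtxt(fp, ndmin=1))
            except (ValueError, OSError) as exc:
                raise RecordingLoadError(
                    f"corrupt trace file for electrode {eid}: {fp.name} ({exc})"
                ) from exc
            traces.append(FieldTrace(int(eid), samples, fs))

    mask = None
    if (root / "mask.npy").exists():
        mmeta = json.loads(_require(root / "mask.json").read_text())
        mask = MaskImage(np.load(root / "mask.npy"), float(mmeta["um_per_px"]),
                         tuple(mmeta["origin_um"]))

    return Recording(
        grid=grid,
        spike_trains=trains,
        field_traces=traces,
        protocol=protocol,
        duration=float(meta["duration_s"]),
        mask=mask,
        metadata=dict(meta.get("metadata", {})),
    )


def validate_recording(rec: Recording) -> list[Violation]:
    """Check every container invariant; returns one record per breach.

    The validator reports and never raises, so a pipeline can list all
    problems at once before refusing a malformed container.
    """
    out: list[Violation] = []
    eids = set(rec.grid.ids)

    seen: set[str] = set()
    for st in rec.spike_trains:
        tgt = f"unit {st.unit_id}"
        if st.unit_id in seen:
            out.append(Violation("duplicate_unit", tgt, "duplicate unit id"))
        seen.add(st.unit_id)
        if st.electrode_id not in eids:
            out.append(Violation("unknown_electrode", tgt,
                                 f"electrode {st.electrode_id} not in grid"))
        t = st.times
        if t.size and np.any(np.diff(t) <= 0):
            out.append(Violation("sortedness", tgt,
                                 "spike times not strictly increasing"))
        if t.size and t[0] < 0:
            out.append(Violation("range", tgt, "negative spike time"))
        if t.size and t[-1] > rec.duration:
            out.append(Violation("range", tgt,
                                 f"spike at t={t[-1]:.4f}s beyond duration"))

    for tr in rec.field_traces:
        tgt = f"electrode {tr.electrode_id}"
        if tr.electrode_id not in eids:
            out.append(Violation("unknown_electrode", tgt, "trace on unknown electrode"))
        if tr.sampling_rate <= 200.0:
            out.append(Violation("sampling_rate", tgt,
                                 "sampling rate must exceed 2x the 100-Hz low-pass band"))

    if rec.protocol.epochs and rec.protocol.epochs[-1].offset > rec.duration:
        out.append(Violation("duration", "protocol",
                             "recording duration does not cover all epochs"))
    return out


def refractory_qc(train: SpikeTrain, window: float = 0.001) -> float:
    """Fraction of inter-spike intervals shorter than the refractory window.

    Spike sorting is trusted upstream; this check confirms each unit shows
    a refractory period (default ±1 ms) and flags contaminated units.
    Returns 0.0 for trains with fewer than two spikes.
    """
    if window < 0:
        raise ValueError("refractory window must be non-negative")
    if train.n_spikes < 2:
        return 0.0
    isi = np.diff(train.times)
    return float(np.mean(isi < window))
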