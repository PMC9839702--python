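"""Readers and writers for the pipeline's on-disk formats.

A *trace bundle* is a directory with:

``traces.csv`` (or ``traces.h5``)
    neurons x frames fluorescence; CSV rows carry ``neuron_id`` in the
    first column, HDF5 stores datasets ``values`` and ``neuron_ids``.
``events.csv``
    columns ``label, onset_s, offset_s``.
``meta.yaml``
    ``frame_rate`` (frames/s, default 6), ``t0`` (s), and the generator
    seed when the bundle is synthetic.

Tabular data (region counts, starter cells, sections, projections,
labels, fits) are plain CSV with the column schemas documented on the
functions that consume them.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import EventSchedule, SchemaError, TraceMatrix

EVENT_COLUMNS = ("label", "onset_s", "offset_s")


def write_trace_bundle(
    path: str,
    traces: TraceMatrix,
    schedule: EventSchedule,
    fmt: str = "csv",
    seed: int | None = None,
) -> None:
    """Write a trace bundle directory in CSV or HDF5 form."""
    os.makedirs(path, exist_ok=True)
    if fmt == "csv":
        df = pd.DataFrame(traces.values)
        df.insert(0, "neuron_id", traces.neuron_ids)
        df.to_csv(os.path.join(path, "traces.csv"), index=False)
    elif fmt == "hdf5":
        with h5py.File(os.path.join(path, "traces.h5"), "w") as f:
            f.create_dataset("values", data=traces.values)
            f.create_dataset("neuron_ids", data=np.asarray(traces.neuron_ids))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    pd.DataFrame(
        [(e.label, e.onset, e.offset) for e in schedule], columns=EVENT_COLUMNS
    ).to_csv(os.path.join(path, "events.csv"), index=False)
    meta = {"frame_rate": float(traces.frame_rate), "t0": float(traces.t0)}
    if seed is not None:
        meta["seed"] = int(seed)
    with open(os.path.join(path, "meta.yaml"), "w") as f:
        yaml.safe_dump(meta, f)


def read_trace_bundle(path: str) -> tuple[TraceMatrix, EventSchedule]:
    """Read a trace bundle directory written by :func:`write_trace_bundle`.

    Raises :class:`SchemaError` naming the offending column on schema
    mismatch; frame rate defaults to 6 frames/s when absent from the
    metadata.
    """
    meta: dict = {}
    meta_path = os.path.join(path, "meta.yaml")
    if os.path.exists(meta_path):
        with open(meta_path) as f:
            meta = yaml.safe_load(f) or {}
    frame_rate = float(meta.get("frame_rate", 6.0))
    t0 = float(meta.get("t0", 0.0))

    h5_path = os.path.join(path, "traces.h5")
    csv_path = os.path.join(path, "traces.csv")
    if os.path.exists(h5_path):
        with h5py.File(h5_path, "r") as f:
            values = f["values"][...]
            neuron_ids = f["neuron_ids"][...] if "neuron_ids" in f else None
    elif os.path.exists(csv_path):
        df = pd.read_csv(csv_path)
        if "neuron_id" not in df.columns:
            raise SchemaError("traces.csv missing column 'neuron_id'")
        neuron_ids = df["neuron_id"].to_numpy()
        values = df.drop(columns="neuron_id").to_numpy(float)
    else:
        raise FileNotFoundError(f"no traces.csv or traces.h5 under {path}")
    traces = TraceMatrix(values=values, frame_rate=frame_rate, neuron_ids=neuron_ids, t0=t0)

    events_path = os.path.join(path, "events.csv")
    ev = pd.read_csv(events_path)
    for col in EVENT_COLUMNS:
        if col not in ev.columns:
            raise SchemaError(f"events.csv missing column {col!r}")
    schedule = EventSchedule(
        [(row.label, float(row.onset_s), float(row.offset_s)) for row in ev.itertuples()]
    )
    return traces, schedule


def write_table(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{os.path.basename(path)} missing column {col!r}")
    return df
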