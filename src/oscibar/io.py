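"""File interfaces: HDF5 signal containers, CSV event tables, epoch slicing.

HDF5 layout (bit-exact round trip)::

    /lfp                         float64 [n_regions, n_samples]
        attrs: fs_hz, t0_s, subject_id, group
    /regions                     string array
    /units/<unit_id>/spike_times_s   float64
        attrs: region

Events travel as CSV with the exact header
``epoch_id,label,start_s,end_s,condition`` so behavioral re-labeling never
touches signal files.  All validation is eager at load so errors carry file
context.
"""

from __future__ import annotations

import math

import h5py
import numpy as np
import pandas as pd

from .core import (
    EVENT_COLUMNS,
    EventTable,
    Recording,
    SchemaError,
    SpikeUnit,
    ValidationError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "slice_epoch",
]


def write_recording(rec: Recording, path) -> None:
    """Write ``rec`` to ``path`` in the documented HDF5 layout."""
    rec.validate()
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=rec.lfp, dtype="float64")
        d.attrs["fs_hz"] = float(rec.fs_hz)
        d.attrs["t0_s"] = float(rec.t0_s)
        d.attrs["subject_id"] = rec.subject_id
        d.attrs["group"] = rec.group
        f.create_dataset(
            "regions", data=np.array(rec.regions, dtype=h5py.string_dtype())
        )
        units = f.create_group("units")
        for u in rec.units:
            g = units.create_group(u.unit_id)
            g.create_dataset("spike_times_s", data=u.spike_times_s, dtype="float64")
            g.attrs["region"] = u.region


def read_recording(path) -> Recording:
    """Read a Recording written by :func:`write_recording`; validates eagerly."""
    with h5py.File(path, "r") as f:
        for name in ("lfp", "regions"):
            if name not in f:
                raise SchemaError(f"{path}: missing dataset '/{name}'")
        d = f["lfp"]
        for attr in ("fs_hz", "t0_s", "subject_id", "group"):
            if attr not in d.attrs:
                raise SchemaError(f"{path}: /lfp missing attribute {attr!r}")
        lfp = d[()]
        bad = ~np.isfinite(lfp)
        if bad.any():
            idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"{path}: non-finite LFP value at region row {idx[0]}, "
                f"sample {idx[1]}"
            )
        regions = [r.decode() if isinstance(r, bytes) else str(r) for r in f["regions"][()]]
        units = []
        if "units" in f:
            for uid in sorted(f["units"]):
                g = f["units"][uid]
                if "spike_times_s" not in g:
                    raise SchemaError(f"{path}: /units/{uid} missing spike_times_s")
                units.append(
                    SpikeUnit(
                        unit_id=uid,
                        region=str(g.attrs["region"]),
                        spike_times_s=g["spike_times_s"][()],
                    )
                )
        return Recording(
            subject_id=str(d.attrs["subject_id"]),
            group=str(d.attrs["group"]),
            regions=regions,
            lfp=lfp,
            fs_hz=float(d.attrs["fs_hz"]),
            t0_s=float(d.attrs["t0_s"]),
            units=units,
        )


def write_events(table: EventTable, path) -> None:
    table.validate()
    table.df.to_csv(path, index=False, columns=EVENT_COLUMNS)


def read_events(path) -> EventTable:
    df = pd.read_csv(path, dtype={"epoch_id": str, "label": str, "condition": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing CSV columns {missing}")
    return EventTable(df)


def slice_epoch(rec: Recording, start_s: float, end_s: float) -> Recording:
    """Cut ``[start_s, end_s)`` out of ``rec``; spikes re-referenced to 0.

    Sample interval is the half-open ``[floor(start*fs), floor(end*fs))``
    relative to ``t0_s``; a spike at exactly ``end_s`` is excluded, so
    disjoint adjacent slices tile the original recording.
    """
    if end_s <= start_s:
        raise ValidationError(f"empty epoch [{start_s}, {end_s})")
    t_end = rec.t0_s + rec.duration_s
    if start_s < rec.t0_s or end_s > t_end + 1e-9:
        raise ValidationError(
            f"epoch [{start_s}, {end_s}) outside recording [{rec.t0_s}, {t_end}]"
        )
    i0 = math.floor((start_s - rec.t0_s) * rec.fs_hz)
    i1 = math.floor((end_s - rec.t0_s) * rec.fs_hz)
    i1 = min(i1, rec.n_samples)
    units = []
    for u in rec.units:
        t = u.spike_times_s
        keep = (t >= start_s) & (t < end_s)
        units.append(
            SpikeUnit(u.unit_id, u.region, t[keep] - start_s)
        )
    return Recording(
        subject_id=rec.subject_id,
        group=rec.group,
        regions=list(rec.regions),
        lfp=rec.lfp[:, i0:i1].copy(),
        fs_hz=rec.fs_hz,
        t0_s=0.0,
        units=units,
    )
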