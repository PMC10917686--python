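"""Serialization of simulation records.

Archives are HDF5 files with a small, versioned schema:

::

    /meta                 attrs: schema_version, seed, manifest (JSON)
    /phases               JSON-encoded phase table
    /intervals            columnar phase/t0/t1/on table
    /pop_rate             concatenated 10 ms population-rate trace
    /training_window/...  identification-window recordings
    /sessions/<k>/...     probing / recall branch recordings
    /weights/<name>/...   weight snapshots at phase boundaries

Spike rasters, when recorded, are stored as sorted (time, neuron)
pairs.  Reading a truncated or foreign file raises ``RecordError``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .protocol import SessionResult, SimulationRecord

__all__ = ["write_record", "read_record", "RecordError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class RecordError(RuntimeError):
    """Raised for corrupt or incompatible archives."""


def _write_session(g: h5py.Group, s: SessionResult) -> None:
    g.attrs["kind"] = s.kind
    g.attrs["stimulus"] = s.stimulus
    g.attrs["t_cons"] = s.t_cons
    g.attrs["on_time"] = s.on_time
    g.create_dataset("counts_on", data=s.counts_on)
    if s.interval_counts:
        g.create_dataset("interval_counts",
                         data=np.stack(s.interval_counts))
        g.create_dataset("interval_durations",
                         data=np.asarray(s.interval_durations))
    if s.bins_on is not None:
        g.create_dataset("bins_on", data=s.bins_on, compression="gzip")
    if s.pop_rate is not None:
        g.create_dataset("pop_rate", data=s.pop_rate)


def _read_session(g: h5py.Group) -> SessionResult:
    s = SessionResult(kind=str(g.attrs["kind"]),
                      stimulus=str(g.attrs["stimulus"]),
                      t_cons=float(g.attrs["t_cons"]),
                      on_time=float(g.attrs["on_time"]),
                      counts_on=g["counts_on"][...])
    if "interval_counts" in g:
        s.interval_counts = list(g["interval_counts"][...])
        s.interval_durations = list(g["interval_durations"][...])
    if "bins_on" in g:
        s.bins_on = g["bins_on"][...]
    if "pop_rate" in g:
        s.pop_rate = g["pop_rate"][...]
    return s


def write_record(record: SimulationRecord, path, *,
                 manifest: Optional[dict] = None) -> None:
    """Write a simulation record to an HDF5 archive (lossless)."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["schema_version"] = SCHEMA_VERSION
        meta.attrs["seed"] = record.seed
        meta.attrs["manifest"] = json.dumps(manifest or {})
        f.create_dataset("phases", data=json.dumps(record.phases))
        iv = pd.DataFrame(record.intervals) if record.intervals else \
            pd.DataFrame(columns=["phase", "t0", "t1", "on"])
        g = f.create_group("intervals")
        g.create_dataset("phase",
                         data=np.array(iv["phase"], dtype="S32"))
        for col in ("t0", "t1"):
            g.create_dataset(col, data=iv[col].to_numpy(dtype=float))
        g.create_dataset("on", data=iv["on"].to_numpy(dtype=bool))
        f.create_dataset("sample_times", data=np.asarray(record.sample_times))
        if record.pop_rate_trace:
            f.create_dataset(
                "pop_rate",
                data=np.concatenate([np.asarray(p, dtype=np.int64)
                                     for p in record.pop_rate_trace]))
        if record.training_engram is not None:
            f.create_dataset("training_engram", data=record.training_engram)
        if record.training_window is not None:
            _write_session(f.create_group("training_window"),
                           record.training_window)
        sess = f.create_group("sessions")
        for k, s in enumerate(record.sessions):
            _write_session(sess.create_group(f"{k:04d}"), s)
        w = f.create_group("weights")
        for name, snap in record.weight_snapshots.items():
            gg = w.create_group(name)
            for key, arr in snap.items():
                gg.create_dataset(key, data=arr)


def read_record(path) -> SimulationRecord:
    """Read an archive written by :func:`write_record`."""
    try:
        with h5py.File(path, "r") as f:
            if "meta" not in f or "schema_version" not in f["meta"].attrs:
                raise RecordError(f"{path}: not an engramsim archive")
            ver = int(f["meta"].attrs["schema_version"])
            if ver != SCHEMA_VERSION:
                raise RecordError(
                    f"{path}: archive schema v{ver}, expected "
                    f"v{SCHEMA_VERSION}")
            rec = SimulationRecord(seed=int(f["meta"].attrs["seed"]))
            rec.phases = json.loads(f["phases"][()])
            g = f["intervals"]
            phases = [p.decode() for p in g["phase"][...]]
            rec.intervals = [
                {"phase": ph, "t0": float(a), "t1": float(b), "on": bool(o)}
                for ph, a, b, o in zip(phases, g["t0"][...], g["t1"][...],
                                       g["on"][...])]
            rec.sample_times = list(f["sample_times"][...])
            if "pop_rate" in f:
                rec.pop_rate_trace = [f["pop_rate"][...]]
            if "training_engram" in f:
                rec.training_engram = f["training_engram"][...]
            if "training_window" in f:
                rec.training_window = _read_session(f["training_window"])
            for k in sorted(f["sessions"]):
                rec.sessions.append(_read_session(f["sessions"][k]))
            for name in f["weights"]:
                rec.weight_snapshots[name] = {
                    key: f["weights"][name][key][...]
                    for key in f["weights"][name]}
            return rec
    except OSError as e:
        raise RecordError(f"{path}: corrupt or unreadable archive "
                          f"({e})") from e


def manifest_for(params_dict: dict, seed: int) -> dict:
    """Run manifest with a content hash for provenance."""
    import hashlib
    blob = json.dumps({"params": params_dict, "seed": seed},
                      sort_keys=True).encode()
    return {"params": params_dict, "seed": seed,
            "hash": hashlib.sha256(blob).hexdigest()[:16],
            "schema_version": SCHEMA_VERSION}
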