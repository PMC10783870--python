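"""Round-trip serialization and file import.

All array objects are stored in a single HDF5 container format with a
schema version and an object-type tag, so files are self-describing and
a file of one type cannot silently be read as another. Audio comes in
as WAV; event tables and group tables as CSV/TSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings

import h5py
import numpy as np
import pandas as pd

from .boosting import BoostConfig, FitResult, Kernel, PartitionSpec
from .stats import ClusterResult
from .timecore import EventTable, TimeAxis, TimeSeries

__all__ = [
    "SCHEMA_VERSION",
    "read_wav",
    "read_events",
    "save_container",
    "load_container",
    "roundtrip_container",
    "read_delimited_series",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# WAV and text import


def read_wav(path) -> TimeSeries:
    """Read a PCM or float WAV file as a mono TimeSeries scaled to [-1, 1].

    Stereo/multichannel audio is downmixed by averaging, with a warning.
    """
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        _warnings.warn("multichannel WAV downmixed to mono by averaging")
        data = data.mean(axis=1)
    axis = TimeAxis(0.0, 1.0 / rate, data.size)
    return TimeSeries(data, axis, ["audio"], "scalar")


def read_events(path) -> EventTable:
    """Read an event table from CSV/TSV.

    Requires an ``onset`` column (seconds); ``value`` defaults to 1.0
    and ``label`` to the row's original position. Output is sorted by
    onset.
    """
    with open(path) as f:
        header = f.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if "onset" not in df.columns:
        raise ValueError(f"event table {path} lacks required column 'onset'")
    onsets = pd.to_numeric(df["onset"], errors="coerce")
    bad = np.flatnonzero(onsets.isna().to_numpy())
    if bad.size:
        raise ValueError(f"non-numeric onset in row {bad[0] + 1} of {path}")
    values = (
        pd.to_numeric(df["value"], errors="coerce").fillna(1.0).to_numpy()
        if "value" in df.columns
        else np.ones(len(df))
    )
    labels = (
        df["label"].astype(str).tolist()
        if "label" in df.columns
        else [str(i) for i in range(len(df))]
    )
    rows = list(zip(onsets.to_numpy(), values, labels))
    return EventTable.from_rows(rows)


def read_delimited_series(path, rate: float, tstart: float = 0.0) -> TimeSeries:
    """Import a 1-D series from plain delimited text at a stated rate."""
    vals = np.loadtxt(path).ravel()
    return TimeSeries(vals, TimeAxis(tstart, 1.0 / rate, vals.size))


# ---------------------------------------------------------------------------
# HDF5 containers


def _write_axis(grp, name, axis: TimeAxis):
    grp.attrs[f"{name}_tstart"] = axis.tstart
    grp.attrs[f"{name}_tstep"] = axis.tstep
    grp.attrs[f"{name}_n"] = axis.n_samples


def _read_axis(grp, name) -> TimeAxis:
    return TimeAxis(
        float(grp.attrs[f"{name}_tstart"]),
        float(grp.attrs[f"{name}_tstep"]),
        int(grp.attrs[f"{name}_n"]),
    )


def _str_list(grp, key):
    return [s.decode() if isinstance(s, bytes) else str(s) for s in grp.attrs[key]]


def _write_timeseries(g, ts: TimeSeries):
    g.create_dataset("values", data=ts.values)
    _write_axis(g, "time", ts.axis)
    g.attrs["component_labels"] = ts.component_labels
    g.attrs["component_kind"] = ts.component_kind


def _read_timeseries(g) -> TimeSeries:
    return TimeSeries(
        g["values"][()], _read_axis(g, "time"),
        _str_list(g, "component_labels"), str(g.attrs["component_kind"]),
    )


def _write_kernel(g, k: Kernel):
    g.create_dataset("values", data=k.values)
    _write_axis(g, "lag", k.lag_axis)
    g.attrs["predictor_labels"] = k.predictor_labels
    g.attrs["channel_labels"] = k.channel_labels
    g.attrs["info"] = json.dumps(k.info, default=str)
    if k.scale_info is not None:
        si = g.create_group("scale_info")
        for key, val in k.scale_info.items():
            if isinstance(val, np.ndarray):
                si.create_dataset(key, data=val)
            else:
                si.attrs[key] = val


def _read_kernel(g) -> Kernel:
    scale_info = None
    if "scale_info" in g:
        si = g["scale_info"]
        scale_info = {k: si[k][()] for k in si}
        scale_info.update({k: si.attrs[k] for k in si.attrs})
    return Kernel(
        g["values"][()], _read_axis(g, "lag"),
        _str_list(g, "predictor_labels"), _str_list(g, "channel_labels"),
        scale_info, json.loads(g.attrs["info"]),
    )


def _write_fitresult(g, fr: FitResult):
    _write_kernel(g.create_group("kernel"), fr.kernel)
    g.create_dataset("proportion_explained", data=fr.proportion_explained)
    g.create_dataset("residual_error", data=fr.residual_error)
    g.attrs["cross_validated"] = fr.cross_validated
    g.attrs["config"] = json.dumps(dataclasses.asdict(fr.config))
    p = fr.partitions
    g.attrs["partitions"] = json.dumps(
        {"k": p.k, "n_samples": p.n_samples, "segments": p.segments,
         "runs": p.runs, "has_test": p.has_test}
    )
    hist = g.create_group("history")
    for ri, run in enumerate(fr.history):
        rg = hist.create_group(str(ri))
        for ci, ch_hist in enumerate(run):
            arr = np.asarray(ch_hist, dtype=float).reshape(-1, 6)
            rg.create_dataset(str(ci), data=arr)
    rk = g.create_group("run_kernels")
    for i, kern in enumerate(fr.run_kernels):
        _write_kernel(rk.create_group(str(i)), kern)
    if fr.y_pred is not None:
        g.create_dataset("y_pred", data=fr.y_pred)
    if fr.min_validation_error is not None:
        g.create_dataset("min_validation_error", data=fr.min_validation_error)


def _read_fitresult(g) -> FitResult:
    pj = json.loads(g.attrs["partitions"])
    partitions = PartitionSpec(
        pj["k"], pj["n_samples"], [tuple(s) for s in pj["segments"]],
        pj["runs"], pj["has_test"],
    )
    hist = []
    hg = g["history"]
    for ri in sorted(hg, key=int):
        run = []
        rg = hg[ri]
        for ci in sorted(rg, key=int):
            arr = rg[ci][()]
            run.append([tuple(row) for row in arr])
        hist.append(run)
    run_kernels = [
        _read_kernel(g["run_kernels"][i]) for i in sorted(g["run_kernels"], key=int)
    ]
    return FitResult(
        kernel=_read_kernel(g["kernel"]),
        proportion_explained=g["proportion_explained"][()],
        residual_error=g["residual_error"][()],
        history=hist,
        config=BoostConfig(**json.loads(g.attrs["config"])),
        partitions=partitions,
        cross_validated=bool(g.attrs["cross_validated"]),
        run_kernels=run_kernels,
        y_pred=g["y_pred"][()] if "y_pred" in g else None,
        min_validation_error=(
            g["min_validation_error"][()] if "min_validation_error" in g else None
        ),
    )


def _write_clusterresult(g, cr: ClusterResult):
    g.create_dataset("t_map", data=cr.t_map)
    g.create_dataset("cluster_labels", data=cr.cluster_labels)
    g.create_dataset("cluster_masses", data=cr.cluster_masses)
    g.create_dataset("cluster_p", data=cr.cluster_p)
    g.attrs["n_permutations"] = cr.n_permutations
    g.attrs["exhaustive"] = cr.exhaustive
    g.attrs["threshold"] = cr.threshold
    g.attrs["warnings"] = cr.warnings


def _read_clusterresult(g) -> ClusterResult:
    return ClusterResult(
        g["t_map"][()], g["cluster_labels"][()], g["cluster_masses"][()],
        g["cluster_p"][()], int(g.attrs["n_permutations"]),
        bool(g.attrs["exhaustive"]), float(g.attrs["threshold"]),
        list(_str_list(g, "warnings")),
    )


_WRITERS = {
    "TimeSeries": _write_timeseries,
    "Kernel": _write_kernel,
    "FitResult": _write_fitresult,
    "ClusterResult": _write_clusterresult,
}
_READERS = {
    "TimeSeries": _read_timeseries,
    "Kernel": _read_kernel,
    "FitResult": _read_fitresult,
    "ClusterResult": _read_clusterresult,
}


def save_container(obj, path):
    """Write a TimeSeries / Kernel / FitResult / ClusterResult to HDF5."""
    tname = type(obj).__name__
    if tname == "Spectrogram":
        tname = "TimeSeries"  # stored as a plain series; band centers in labels
    if tname not in _WRITERS:
        raise TypeError(f"cannot serialize objects of type {tname}")
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["object_type"] = tname
        _WRITERS[tname](f, obj)


def load_container(path, expect: str | None = None):
    """Read a container written by :func:`save_container`.

    ``expect`` guards against reading a file of the wrong type.
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"container schema version {version} != supported {SCHEMA_VERSION}"
            )
        tname = str(f.attrs["object_type"])
        if expect is not None and tname != expect:
            raise TypeError(f"expected a {expect} container, found {tname}")
        return _READERS[tname](f)


def roundtrip_container(obj, path):
    """Write then re-read an object; returns the re-read copy."""
    save_container(obj, path)
    return load_container(path)
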