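"""Epochs container (HDF5 + JSON sidecar) and report serialization."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .layout import ChannelLayout
from .simulate import EpochsDataset

__all__ = [
    "FORMAT_VERSION",
    "ContainerFormatError",
    "write_epochs",
    "read_epochs",
    "write_report",
    "read_report",
]

FORMAT_VERSION = 1


class ContainerFormatError(RuntimeError):
    """Raised when a container misses or mismatches the format version."""


def _layout_dict(layout: ChannelLayout) -> dict:
    edges = [
        [layout.names[i], layout.names[j]]
        for i, j in zip(*np.nonzero(np.triu(layout.neighbors, 1)))
    ]
    return {
        "names": list(layout.names),
        "positions": layout.positions.tolist(),
        "mirror_pairs": dict(layout.mirror_pairs),
        "midline": sorted(layout.midline),
        "edges": edges,
    }


def _layout_from_dict(d: dict) -> ChannelLayout:
    names = tuple(d["names"])
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    for a, b in d["edges"]:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return ChannelLayout(
        names=names,
        positions=np.asarray(d["positions"], dtype=float),
        mirror_pairs=dict(d["mirror_pairs"]),
        midline=frozenset(d["midline"]),
        neighbors=adj,
    )


def write_epochs(path, epochs: EpochsDataset, behavior: pd.DataFrame | None = None) -> Path:
    """Write an epochs dataset (and optional behavior columns) to HDF5.

    A JSON sidecar mirroring the layout and trial table is written next to
    the HDF5 file for portability.
    """
    path = Path(path)
    trials = epochs.trials.copy()
    if behavior is not None:
        for col in behavior.columns:
            trials[col] = behavior[col].to_numpy()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["srate"] = epochs.srate
        f.attrs["subject_id"] = epochs.subject_id
        f.create_dataset("data", data=epochs.data.astype(np.float32), compression="gzip")
        f.create_dataset("times", data=epochs.times.astype(np.float64))
        lg = f.create_group("layout")
        ld = _layout_dict(epochs.layout)
        lg.create_dataset("names", data=np.array(ld["names"], dtype="S8"))
        lg.create_dataset("positions", data=epochs.layout.positions)
        lg.create_dataset(
            "mirror_pairs",
            data=np.array([[a, b] for a, b in ld["mirror_pairs"].items()], dtype="S8"),
        )
        lg.create_dataset("midline", data=np.array(ld["midline"], dtype="S8"))
        lg.create_dataset("edges", data=np.array(ld["edges"], dtype="S8"))
        tg = f.create_group("trials")
        for col in trials.columns:
            v = trials[col].to_numpy()
            if v.dtype == object or v.dtype.kind in "US":
                tg.create_dataset(col, data=v.astype("S16"))
            else:
                tg.create_dataset(col, data=v)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "format_version": FORMAT_VERSION,
                "subject_id": epochs.subject_id,
                "srate": epochs.srate,
                "layout": _layout_dict(epochs.layout),
                "trials": json.loads(trials.to_json(orient="records")),
            },
            indent=1,
        )
    )
    return path


def read_epochs(path) -> EpochsDataset:
    """Read an epochs dataset written by :func:`write_epochs`.

    Raises :class:`ContainerFormatError` on a missing or mismatched format
    version rather than misparsing silently.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise ContainerFormatError(f"not a readable epochs container: {path}") from e
    with f:
        version = f.attrs.get("format_version")
        if version is None or int(version) != FORMAT_VERSION:
            raise ContainerFormatError(
                f"container version {version!r} does not match expected {FORMAT_VERSION}"
            )
        data = f["data"][()]
        times = f["times"][()]
        srate = float(f.attrs["srate"])
        subject_id = str(f.attrs["subject_id"])
        lg = f["layout"]
        names = [n.decode() for n in lg["names"][()]]
        pairs = {a.decode(): b.decode() for a, b in lg["mirror_pairs"][()]}
        midline = frozenset(m.decode() for m in lg["midline"][()])
        idx = {n: i for i, n in enumerate(names)}
        adj = np.zeros((len(names), len(names)), dtype=bool)
        for a, b in lg["edges"][()]:
            i, j = idx[a.decode()], idx[b.decode()]
            adj[i, j] = adj[j, i] = True
        layout = ChannelLayout(
            names=tuple(names),
            positions=lg["positions"][()],
            mirror_pairs=pairs,
            midline=midline,
            neighbors=adj,
        )
        cols = {}
        for col in f["trials"]:
            v = f["trials"][col][()]
            if v.dtype.kind == "S":
                v = np.array([x.decode() for x in v])
            cols[col] = v
        trials = pd.DataFrame(cols)
    return EpochsDataset(
        data=data, times=times, srate=srate, layout=layout,
        trials=trials, subject_id=subject_id,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path) -> Path:
    """Serialize a report dict to stable, sorted JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=1, sort_keys=True))
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
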