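"""Readers and writers for recordings, layouts, protocols and tables.

The recording container is HDF5 (datasets ``/data`` [channels × samples,
float32 µV], ``/channel_ids``, ``/layout/{electrode_id,x_um,y_um,
is_reference}``; root attrs ``sample_rate_hz``, ``t0_s``).  A CSV dialect
(one column per channel, header = channel ids, JSON sidecar for metadata and
layout) is supported as a plain-text fallback.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (ElectrodeLayout, FormatError, MultichannelRecording,
                   StimulusProtocol)


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

def write_recording(rec: MultichannelRecording, path) -> None:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or CSV + JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        _write_h5(rec, path)
    elif path.suffix.lower() == ".csv":
        _write_csv(rec, path)
    else:
        raise FormatError(f"unknown recording container suffix: {path.suffix!r}")


def read_recording(path) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _read_h5(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    raise FormatError(f"unknown recording container suffix: {path.suffix!r}")


def _write_h5(rec: MultichannelRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("channel_ids", data=rec.channel_ids)
        f.attrs["sample_rate_hz"] = float(rec.sample_rate_hz)
        f.attrs["t0_s"] = float(rec.t0_s)
        g = f.create_group("layout")
        g.create_dataset("electrode_id", data=rec.layout.electrode_ids)
        g.create_dataset("x_um", data=rec.layout.x_um)
        g.create_dataset("y_um", data=rec.layout.y_um)
        g.create_dataset("is_reference", data=rec.layout.is_reference)


def _read_h5(path: Path) -> MultichannelRecording:
    with h5py.File(path, "r") as f:
        for key in ("data", "channel_ids"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset '/{key}'")
        for attr in ("sample_rate_hz", "t0_s"):
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute '{attr}'")
        if "layout" not in f:
            raise FormatError(f"{path}: missing group '/layout'")
        g = f["layout"]
        layout = ElectrodeLayout(
            electrode_ids=g["electrode_id"][:],
            x_um=g["x_um"][:],
            y_um=g["y_um"][:],
            is_reference=g["is_reference"][:] if "is_reference" in g else None,
        )
        return MultichannelRecording(
            data=f["data"][:],
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            channel_ids=f["channel_ids"][:],
            layout=layout,
            t0_s=float(f.attrs["t0_s"]),
        )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_csv(rec: MultichannelRecording, path: Path) -> None:
    df = pd.DataFrame(rec.data.T.astype(np.float32),
                      columns=[str(c) for c in rec.channel_ids])
    df.to_csv(path, index=False)
    meta = {
        "sample_rate_hz": float(rec.sample_rate_hz),
        "t0_s": float(rec.t0_s),
        "layout": {
            "electrode_id": rec.layout.electrode_ids.tolist(),
            "x_um": rec.layout.x_um.tolist(),
            "y_um": rec.layout.y_um.tolist(),
            "is_reference": rec.layout.is_reference.tolist(),
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path) -> MultichannelRecording:
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"{path}: missing JSON sidecar {side.name}")
    meta = json.loads(side.read_text())
    if "sample_rate_hz" not in meta:
        raise FormatError(f"{side}: missing field 'sample_rate_hz'")
    df = pd.read_csv(path)
    lay = meta.get("layout")
    channel_ids = np.array([int(c) for c in df.columns])
    if lay is None:
        # minimal sidecar: synthesise a degenerate layout on a line
        layout = ElectrodeLayout(channel_ids,
                                 200.0 * np.arange(len(channel_ids)),
                                 np.zeros(len(channel_ids)))
    else:
        layout = ElectrodeLayout(lay["electrode_id"], lay["x_um"], lay["y_um"],
                                 lay.get("is_reference"))
    return MultichannelRecording(
        data=df.to_numpy(dtype=np.float32).T,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        channel_ids=channel_ids,
        layout=layout,
        t0_s=float(meta.get("t0_s", 0.0)),
    )


# --------------------------------------------------------------------------
# layouts and protocols
# --------------------------------------------------------------------------

def write_layout(layout: ElectrodeLayout, path) -> None:
    pd.DataFrame({
        "electrode_id": layout.electrode_ids,
        "x_um": layout.x_um,
        "y_um": layout.y_um,
        "is_reference": layout.is_reference,
    }).to_csv(path, index=False)


def read_layout(path) -> ElectrodeLayout:
    df = pd.read_csv(path)
    for col in ("electrode_id", "x_um", "y_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}'")
    ref = df["is_reference"] if "is_reference" in df.columns else None
    return ElectrodeLayout(df["electrode_id"].to_numpy(),
                           df["x_um"].to_numpy(), df["y_um"].to_numpy(), ref)


def load_protocol(path) -> StimulusProtocol:
    """Load a stimulus protocol from JSON (list of epoch triples or dicts)
    or CSV with columns t_start_s, t_end_s, irradiance_uW_mm2."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text() or "[]")
        if isinstance(raw, dict):
            raw = raw.get("epochs", [])
        epochs = [
            (e["t_start_s"], e["t_end_s"], e["irradiance_uW_mm2"])
            if isinstance(e, dict) else tuple(e)
            for e in raw
        ]
    else:
        text = path.read_text().strip()
        if not text:
            return StimulusProtocol(())
        df = pd.read_csv(path)
        for col in ("t_start_s", "t_end_s", "irradiance_uW_mm2"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column '{col}'")
        epochs = list(df[["t_start_s", "t_end_s",
                          "irradiance_uW_mm2"]].itertuples(index=False,
                                                           name=None))
    return StimulusProtocol(tuple(epochs))


def write_protocol(protocol: StimulusProtocol, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            [{"t_start_s": a, "t_end_s": b, "irradiance_uW_mm2": i}
             for a, b, i in protocol.epochs], indent=1))
    else:
        pd.DataFrame(list(protocol.epochs),
                     columns=["t_start_s", "t_end_s", "irradiance_uW_mm2"]
                     ).to_csv(path, index=False)
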