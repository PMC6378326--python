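"""Recording and result I/O.

Recordings travel as a flat binary (float32, channel-major) next to a
JSON sidecar holding the sampling rate and channel table, or inside an
HDF5 container (one dataset plus attributes).  Both dialects round-trip
samples and metadata losslessly at float32 precision; the flat binary of
a float32-valued array is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import Channel, TimeSeries

__all__ = [
    "write_flatbin",
    "read_flatbin",
    "write_hdf5",
    "read_hdf5",
    "write_truth_manifest",
]


def _channel_dicts(ts: TimeSeries) -> list[dict]:
    return [
        dict(id=c.id, region=c.region, depth_um=c.depth_um,
             montage=c.montage, kind=c.kind, sources=list(c.sources))
        for c in ts.channels
    ]


def _channels_from(dicts) -> list[Channel]:
    return [
        Channel(id=d["id"], region=d["region"], depth_um=d["depth_um"],
                montage=d["montage"], kind=d.get("kind", "lfp"),
                sources=tuple(d.get("sources", ())))
        for d in dicts
    ]


def write_flatbin(ts: TimeSeries, path) -> None:
    """``<path>.bin`` (float32 channel-major) + ``<path>.json`` sidecar."""
    path = Path(path)
    data = np.asarray(ts.data, dtype=np.float32)
    data.tofile(path.with_suffix(".bin"))
    sidecar = dict(
        fs=ts.fs, t0=ts.t0, n_channels=ts.n_channels, n_samples=ts.n_samples,
        dtype="float32", order="channel-major", channels=_channel_dicts(ts),
    )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_flatbin(path) -> TimeSeries:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs", "n_channels", "n_samples", "channels"):
        if key not in meta:
            raise ValueError(f"sidecar missing field {key!r}")
    data = np.fromfile(path.with_suffix(".bin"), dtype=np.float32)
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    return TimeSeries(
        data=data.astype(float), fs=meta["fs"], t0=meta.get("t0", 0.0),
        channels=_channels_from(meta["channels"]),
    )


def write_hdf5(ts: TimeSeries, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=np.asarray(ts.data, dtype=np.float32))
        d.attrs["fs"] = ts.fs
        d.attrs["t0"] = ts.t0
        d.attrs["channels"] = json.dumps(_channel_dicts(ts))


def read_hdf5(path) -> TimeSeries:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return TimeSeries(
            data=d[()].astype(float), fs=float(d.attrs["fs"]),
            t0=float(d.attrs["t0"]),
            channels=_channels_from(json.loads(d.attrs["channels"])),
        )


def write_truth_manifest(truth, path) -> None:
    """Ground truth as a JSON manifest (times in seconds)."""
    path = Path(path)
    manifest = dict(
        fr_onsets={k: np.asarray(v).tolist() for k, v in truth.fr_onsets.items()},
        ied_times=np.asarray(truth.ied_times).tolist(),
        complex_windows=np.asarray(truth.complex_windows).tolist(),
        spike_counts={k: int(np.asarray(v).size) for k, v in truth.spike_times.items()},
        lags={f"{a}->{b}": v for (a, b), v in truth.lags.items()},
        coupling_freqs=list(truth.coupling_freqs),
        duration=truth.duration,
    )
    path.write_text(json.dumps(manifest, indent=1))
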