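"""Recording containers and file formats.

Canonical on-disk form is HDF5: dataset /signal (float32, channels x
samples), attributes fs_hz and units, and a /meta JSON string with
provenance (source, filters applied, M, L, normalization scale).  A flat
binary (int16 or float32) plus JSON sidecar is supported for
acquisition-system exports.  Spike trains travel as CSV with columns
channel, unit, sample_index, time_s.  Sample indices are 0-based; times in
seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthio import GroundTruth, Recording


def write_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal.astype(np.float32))
        f.attrs["fs_hz"] = float(rec.fs)
        f.attrs["units"] = rec.meta.get("units", "uV")
        if rec.channel_ids is not None:
            f.attrs["channel_ids"] = json.dumps(list(rec.channel_ids))
        f.create_dataset("meta", data=json.dumps(rec.meta))


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5", ".h5py"):
        with h5py.File(path, "r") as f:
            if "fs_hz" not in f.attrs:
                raise ValueError("recording is missing the fs_hz attribute")
            sig = f["signal"][()].astype(np.float64)
            fs = float(f.attrs["fs_hz"])
            meta = json.loads(f["meta"][()]) if "meta" in f else {}
            ch = (json.loads(f.attrs["channel_ids"])
                  if "channel_ids" in f.attrs else None)
        return Recording(sig, fs, ch, meta)
    return _read_flat_binary(path)


def _read_flat_binary(path: Path) -> Recording:
    """Raw interleaved binary + JSON sidecar (<path>.json) with fields fs,
    n_channels, dtype ('int16'|'float32'), and scale_uV_per_lsb for int16."""
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"flat binary requires a sidecar {sidecar.name} "
                         "(sampling rate is never guessed)")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "n_channels", "dtype"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field {key!r}")
    dtype = np.dtype(meta["dtype"])
    raw = np.fromfile(path, dtype=dtype)
    k = int(meta["n_channels"])
    raw = raw.reshape(-1, k).T  # interleaved samples -> (channels, samples)
    if dtype == np.int16:
        if "scale_uV_per_lsb" not in meta:
            raise ValueError("int16 binary requires scale_uV_per_lsb")
        sig = raw.astype(np.float64) * float(meta["scale_uV_per_lsb"])
    else:
        sig = raw.astype(np.float64)
    return Recording(sig, float(meta["fs"]), meta=dict(meta))


def write_spike_trains(trains: dict, fs: float, path: str | Path) -> None:
    """trains: {channel: sorted sample indices} or
    {channel: {unit: sorted sample indices}}."""
    rows = []
    for ch, v in trains.items():
        per_unit = v if isinstance(v, dict) else {"": v}
        for unit, times in per_unit.items():
            t = np.asarray(times)
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"unsorted spike times for channel {ch}")
            for s in t:
                rows.append((ch, unit, int(s), round(int(s) / fs, 9)))
    df = pd.DataFrame(rows, columns=["channel", "unit", "sample_index", "time_s"])
    df.to_csv(path, index=False)


def read_spike_trains(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    rows = []
    for ch in range(len(gt.spike_times)):
        for unit, times in zip(gt.unit_ids[ch], gt.spike_times[ch]):
            for s in times:
                rows.append((ch, unit, int(s)))
    pd.DataFrame(rows, columns=["channel", "unit", "sample_index"]).to_csv(
        path, index=False)


def read_ground_truth_times(path: str | Path) -> dict[int, dict[int, np.ndarray]]:
    df = pd.read_csv(path)
    out: dict[int, dict[int, np.ndarray]] = {}
    for (ch, unit), g in df.groupby(["channel", "unit"]):
        out.setdefault(int(ch), {})[int(unit)] = np.sort(
            g["sample_index"].to_numpy())
    return out


def write_normalized_pairs(pairs: list, path: str | Path, M: int, L: int,
                           cutoff_hz: float, mode: str) -> None:
    with h5py.File(path, "w") as f:
        f.attrs.update({"M": M, "L": L, "cutoff_hz": cutoff_hz, "mode": mode})
        for i, p in enumerate(pairs):
            g = f.create_group(f"electrode_{i}")
            g.create_dataset("lpf_input", data=p.lpf_input.astype(np.float32))
            g.create_dataset("hpf_gt", data=p.hpf_gt.astype(np.float32))
            g.attrs["scale"] = p.scale
            g.attrs["fs_hz"] = p.fs
            g.attrs["electrode_id"] = str(p.electrode_id)


def read_normalized_pairs(path: str | Path) -> tuple[list, dict]:
    from .dsp import NormalizedPair

    pairs = []
    with h5py.File(path, "r") as f:
        meta = {k: f.attrs[k] for k in f.attrs}
        names = sorted(f.keys(), key=lambda s: int(s.split("_")[1]))
        for name in names:
            g = f[name]
            pairs.append(NormalizedPair(
                g["lpf_input"][()].astype(np.float64),
                g["hpf_gt"][()].astype(np.float64),
                float(g.attrs["scale"]), float(g.attrs["fs_hz"]),
                g.attrs["electrode_id"]))
    return pairs, meta
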