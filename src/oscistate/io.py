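"""Readers and writers for recordings, templates, labels and parameters.

Recordings travel as HDF5 (a ``data`` dataset with ``fs``/``band``
attributes plus a channel table) or as plain CSV matrices with a channel
sidecar; group templates and tidy parameter tables are CSV; model
metadata goes to JSON sidecars.  Native MEG FIF files can be ingested
when ``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import SensorRecording, make_channel_meta
from .microstate import MicrostateModel

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "write_recording_csv",
    "read_recording_csv",
    "read_fif",
    "write_templates_csv",
    "read_templates_csv",
    "write_labels_csv",
    "write_params_csv",
    "write_model_json",
]


def write_recording_h5(recording: SensorRecording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=recording.data)
        d.attrs["fs"] = recording.fs
        d.attrs["band"] = recording.band
        meta = recording.channels
        f.create_dataset("channel_name", data=meta["name"].astype(str).to_numpy(dtype="S"))
        f.create_dataset("channel_kind", data=meta["kind"].astype(str).to_numpy(dtype="S"))
        pair = meta["pair"].fillna("").astype(str).to_numpy(dtype="S")
        f.create_dataset("channel_pair", data=pair)


def read_recording_h5(path) -> SensorRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f["data"].attrs["fs"])
        band = str(f["data"].attrs["band"])
        names = [s.decode() for s in f["channel_name"][()]]
        kinds = [s.decode() for s in f["channel_kind"][()]]
        pairs = [s.decode() or None for s in f["channel_pair"][()]]
    return SensorRecording(data, fs, band, make_channel_meta(names, kinds, pairs))


def write_recording_csv(recording: SensorRecording, path, sidecar=None) -> None:
    """Matrix CSV (rows = channels, first column = channel name) plus an
    optional channel-metadata sidecar CSV."""
    df = pd.DataFrame(recording.data)
    df.insert(0, "name", recording.channels["name"].to_numpy())
    df.to_csv(path, index=False)
    if sidecar is not None:
        meta = recording.channels.copy()
        meta["fs"] = recording.fs
        meta["band"] = recording.band
        meta.to_csv(sidecar, index=False)


def read_recording_csv(path, sidecar) -> SensorRecording:
    df = pd.read_csv(path)
    meta = pd.read_csv(sidecar)
    fs = float(meta["fs"].iloc[0])
    band = str(meta["band"].iloc[0])
    names = df["name"].tolist()
    if names != meta["name"].tolist():
        raise ValueError("channel order mismatch between matrix and sidecar")
    pair = meta["pair"].where(meta["pair"].notna(), None) if "pair" in meta else None
    channels = make_channel_meta(
        names, meta["kind"].tolist(), list(pair) if pair is not None else None
    )
    return SensorRecording(df.drop(columns="name").to_numpy(float), fs, band, channels)


def read_fif(path) -> SensorRecording:
    """Ingest a raw FIF file (requires the optional ``mne`` dependency).

    Magnetometers map to MAG; planar gradiometers map to GRAD with the
    pair id taken from the shared channel-name stem, ready for
    :func:`oscistate.preprocess.combine_planar`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading FIF files requires the 'mne' package") from exc

    raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    picks = mne.pick_types(raw.info, meg=True, ref_meg=False)
    data = raw.get_data(picks=picks)
    names, kinds, pairs = [], [], []
    for i in picks:
        ch = raw.info["chs"][i]
        name = ch["ch_name"]
        unit_kind = mne.io.pick.channel_type(raw.info, i)
        names.append(name)
        if unit_kind == "mag":
            kinds.append("MAG")
            pairs.append(None)
        elif unit_kind == "grad":
            kinds.append("GRAD")
            pairs.append(name.replace(" ", "")[:-1])  # MEG0112/0113 share a stem
        else:
            raise ValueError(f"unexpected channel type {unit_kind!r} for {name}")
    rec = SensorRecording(
        data, float(raw.info["sfreq"]), "broadband-raw", make_channel_meta(names, kinds, pairs)
    )
    return rec


def write_templates_csv(maps: np.ndarray, channel_names, path) -> None:
    """Templates as channels x K CSV with a channel-name column."""
    maps = np.asarray(maps, float)
    df = pd.DataFrame(
        maps.T, columns=[f"MS{j + 1}" for j in range(maps.shape[0])]
    )
    df.insert(0, "name", list(channel_names))
    df.to_csv(path, index=False)


def read_templates_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    names = df["name"].tolist()
    return df.drop(columns="name").to_numpy(float).T, names


def write_labels_csv(seq, path) -> None:
    pd.DataFrame(
        {"sample": np.arange(seq.n_samples), "state": seq.labels}
    ).to_csv(path, index=False)


def write_params_csv(params: pd.DataFrame, path) -> None:
    cols = ["subject", "group", "band", "state", "duration_s", "occurrence_hz", "coverage"]
    params[cols].to_csv(path, index=False)


def write_model_json(model: MicrostateModel, path) -> None:
    payload = {
        "K": int(model.K),
        "n_channels": int(model.n_channels),
        "gev": float(model.gev),
        "n_restarts": int(model.n_restarts),
        "chosen_restart": int(model.chosen_restart),
        "seed": int(model.seed),
        "n_iter": int(model.n_iter),
        "restart_gevs": [float(g) for g in (model.restart_gevs if model.restart_gevs is not None else [])],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
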