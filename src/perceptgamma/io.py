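"""Readers and writers for recordings, events, behaviour logs and arrays.

Two on-disk forms are supported for continuous data:

* **EDF** (16-bit European Data Format) for interchange.  Reading goes
  through :func:`mne.io.read_raw_edf`; writing uses a minimal EDF encoder
  implemented here (the installed mne cannot export EDF).  EDF quantizes
  amplitudes to the 16-bit grid of each channel's physical range.
* A **hierarchical container** (HDF5) for lossless intermediates: float64
  signal plus a JSON metadata block (labels, kinds, sampling rate,
  positions) and the event table.  Epoch sets and time-frequency arrays
  use the same container.

Events and behaviour logs are plain CSV/TSV with a header row.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    BehaviourLog,
    EventTable,
    EpochSet,
    FormatError,
    InvariantError,
    Recording,
)

_EDF_HDR = 256


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def _write_edf(rec: Recording, path: Path) -> None:
    data = rec.data
    n_ch, n_samp = data.shape
    sr = rec.sr
    # one record per second when the length allows, else a single record
    if abs(sr - round(sr)) < 1e-9 and n_samp % int(round(sr)) == 0:
        spr = int(round(sr))
        n_rec, rec_dur = n_samp // spr, 1.0
    else:
        spr, n_rec, rec_dur = n_samp, 1, n_samp / sr

    pmax = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig = 32767
    scale = pmax / dig

    with open(path, "wb") as f:
        hdr_bytes = _EDF_HDR * (1 + n_ch)
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(hdr_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad(f"{rec_dur:g}", 8))
        f.write(_pad(str(n_ch), 4))
        for lab in rec.channel_labels:
            f.write(_pad(lab, 16))
        for _ in range(n_ch):
            f.write(_pad("", 80))
        for _ in range(n_ch):
            f.write(_pad("uV", 8))
        for p in pmax:
            f.write(_pad(f"{-p:.6g}"[:8], 8))
        for p in pmax:
            f.write(_pad(f"{p:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_pad(str(-dig), 8))
        for _ in range(n_ch):
            f.write(_pad(str(dig), 8))
        for _ in range(n_ch):
            f.write(_pad("", 80))
        for _ in range(n_ch):
            f.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            f.write(_pad("", 32))
        for r in range(n_rec):
            chunk = data[:, r * spr:(r + 1) * spr]
            dig_chunk = np.clip(
                np.round(chunk / scale[:, None]), -dig, dig
            ).astype("<i2")
            f.write(dig_chunk.tobytes())


def _edf_header_labels(path: Path) -> list[str]:
    with open(path, "rb") as f:
        hdr = f.read(_EDF_HDR)
        if len(hdr) < _EDF_HDR:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_ch = int(hdr[252:256].decode("ascii").strip())
        except ValueError as e:
            raise FormatError(f"{path}: malformed EDF header ({e})") from e
        raw = f.read(16 * n_ch)
    return [raw[i * 16:(i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(n_ch)]


def _read_edf(path: Path) -> Recording:
    import mne

    labels = _edf_header_labels(path)
    if len(set(labels)) != len(labels):
        raise InvariantError(f"{path}: duplicate channel labels in EDF header")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except InvariantError:
        raise
    except Exception as e:  # mne raises various types for malformed files
        raise FormatError(f"{path}: unreadable EDF ({e})") from e
    sr = float(raw.info["sfreq"])
    if not sr > 0:
        raise FormatError(f"{path}: missing or invalid sampling rate")
    data = raw.get_data() * 1e6  # mne returns Volts for µV-dimensioned channels
    kinds = []
    for lab in labels:
        up = lab.upper()
        kinds.append("EOG" if ("EOG" in up) else "EEG")
    from . import montage

    pos = montage.positions_for(labels)
    for i, k in enumerate(kinds):
        # channels without a standard position cannot feed topographic maps;
        # keep them but mark them BAD rather than dropping
        if k == "EEG" and not np.all(np.isfinite(pos[i])):
            kinds[i] = "BAD"
    return Recording(
        data=data, sr=sr, channel_labels=labels, channel_kinds=kinds,
        positions=pos,
    )


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _write_events(g: h5py.Group, events: EventTable) -> None:
    eg = g.create_group("events")
    eg.create_dataset("sample", data=events.df["sample"].to_numpy(np.int64))
    eg.create_dataset("trial", data=events.df["trial"].to_numpy(np.int64))
    eg.create_dataset(
        "code",
        data=np.array(events.df["code"], dtype=h5py.string_dtype("utf-8")),
    )


def _read_events(g: h5py.Group) -> EventTable:
    if "events" not in g:
        return EventTable()
    eg = g["events"]
    codes = [c.decode() if isinstance(c, bytes) else str(c) for c in eg["code"][()]]
    return EventTable(pd.DataFrame({
        "sample": eg["sample"][()], "code": codes, "trial": eg["trial"][()],
    }))


def _write_container(rec: Recording, path: Path) -> None:
    meta = {
        "sr": rec.sr,
        "channel_labels": rec.channel_labels,
        "channel_kinds": rec.channel_kinds,
        "positions": None if rec.positions is None else rec.positions.tolist(),
    }
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "recording"
        f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("signal", data=rec.data)
        _write_events(f, rec.events)


def _read_container(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "recording":
            raise FormatError(f"{path}: container does not hold a recording")
        meta = json.loads(f.attrs["meta"])
        if "sr" not in meta:
            raise FormatError(f"{path}: sampling rate missing from metadata")
        pos = meta.get("positions")
        return Recording(
            data=f["signal"][()],
            sr=meta["sr"],
            channel_labels=meta["channel_labels"],
            channel_kinds=meta["channel_kinds"],
            positions=None if pos is None else np.asarray(pos),
            events=_read_events(f),
        )


# ---------------------------------------------------------------------------
# Public recording API
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suf = path.suffix.lower()
    if suf == ".edf":
        return "edf"
    if suf in (".h5", ".hdf5", ".pgc"):
        return "container"
    raise FormatError(f"cannot infer format from suffix {suf!r}")


def read_recording(path, format: str | None = None) -> Recording:
    """Read a continuous recording from EDF or the hierarchical container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "container":
        return _read_container(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording; EDF quantizes, the container is lossless."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "container":
        _write_container(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel amplitude quantum the EDF round trip introduces."""
    pmax = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    return pmax / 32767


# ---------------------------------------------------------------------------
# Events and behaviour CSV
# ---------------------------------------------------------------------------

def read_events(path) -> EventTable:
    """Read a comma- or tab-separated event table with a header row."""
    df = pd.read_csv(path, sep=None, engine="python")
    return EventTable(df)


def write_events(events: EventTable, path) -> None:
    events.df.to_csv(path, index=False)


def read_behaviour(path, trial_duration: float | None = None) -> BehaviourLog:
    df = pd.read_csv(path, sep=None, engine="python")
    return BehaviourLog(df, trial_duration=trial_duration)


def write_behaviour(log: BehaviourLog, path) -> None:
    log.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Epochs and TFR containers
# ---------------------------------------------------------------------------

def save_epochs(ep: EpochSet, path) -> None:
    meta = {
        "sr": ep.sr, "tmin": ep.tmin, "tmax": ep.tmax, "lock": ep.lock,
        "labels": ep.labels,
        "channel_labels": ep.channel_labels, "channel_kinds": ep.channel_kinds,
        "positions": None if ep.positions is None else ep.positions.tolist(),
        "trial_ids": ep.trial_ids.tolist(), "provenance": ep.provenance,
    }
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "epochs"
        f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("data", data=ep.data)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "epochs":
            raise FormatError(f"{path}: container does not hold epochs")
        m = json.loads(f.attrs["meta"])
        pos = m.get("positions")
        return EpochSet(
            data=f["data"][()], sr=m["sr"], tmin=m["tmin"], tmax=m["tmax"],
            lock=m["lock"], labels=m["labels"],
            channel_labels=m["channel_labels"], channel_kinds=m["channel_kinds"],
            positions=None if pos is None else np.asarray(pos),
            trial_ids=np.asarray(m["trial_ids"]), provenance=m["provenance"],
        )


def save_tfr(tfr, path) -> None:
    meta = {
        "freqs": np.asarray(tfr.freqs).tolist(),
        "times": np.asarray(tfr.times).tolist(),
        "channel_labels": tfr.channel_labels,
        "labels": tfr.labels,
        "normalized": bool(tfr.normalized),
        "baseline": tfr.baseline,
        "clip_fraction": tfr.clip_fraction,
    }
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = "tfr"
        f.attrs["meta"] = json.dumps(meta)
        f.create_dataset("power", data=tfr.power)
        if tfr.coeffs is not None:
            f.create_dataset("coeffs", data=tfr.coeffs)


def load_tfr(path):
    from .timefreq import TFR

    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "tfr":
            raise FormatError(f"{path}: container does not hold a TFR")
        m = json.loads(f.attrs["meta"])
        return TFR(
            power=f["power"][()],
            coeffs=f["coeffs"][()] if "coeffs" in f else None,
            freqs=np.asarray(m["freqs"]),
            times=np.asarray(m["times"]),
            channel_labels=m["channel_labels"],
            labels=m["labels"],
            normalized=m["normalized"],
            baseline=None if m["baseline"] is None else tuple(m["baseline"]),
            clip_fraction=m["clip_fraction"],
        )
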