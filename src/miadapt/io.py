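"""File interchange: EDF recordings, epoch containers, feature tables.

Recordings go to EDF+C (16-bit European Data Format with the imagery
onsets as EDF+ annotations) — a deliberately minimal writer covering
exactly what this pipeline produces — and are read back through
``mne.io.read_raw_edf``.  Epoch sets are stored as a binary block
(``.npz``) plus a JSON sidecar with labels, sampling rate, window and
channel order; feature matrices and connectivity matrices are delimited
text with headers.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np

from .connectivity import BinaryNetwork, ConnectivityMatrix
from .features import FeatureMatrix
from .preprocess import EpochSet
from .synthgen import Recording

__all__ = [
    "write_edf",
    "read_edf",
    "save_epochs",
    "load_epochs",
    "save_features",
    "load_features",
    "save_connectivity",
    "save_edge_list",
]


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width} bytes")
    return b.ljust(width)


def write_edf(rec: Recording, path) -> Path:
    """Write a recording as EDF+C with events as annotations.

    The sampling rate must be a positive integer (one data record per
    second); the final record is zero-padded if the signal length is not
    a whole number of seconds.
    """
    path = Path(path)
    fs = rec.fs
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF export needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))

    # physical scaling per channel (symmetric range, 16-bit digital)
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_max = 32767

    # annotation TALs per record: a timestamp TAL plus any events starting
    # in that second
    tals: list[bytes] = []
    events = list(rec.events)
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        while events and events[0][0] // fs == r:
            onset, task = events.pop(0)
            tal += f"+{onset / fs:.4f}\x14{task}\x14\x00".encode("ascii")
        tals.append(tal)
    annot_bytes = max(len(t) for t in tals)
    annot_bytes += annot_bytes % 2  # int16 alignment
    n_annot_samples = annot_bytes // 2

    ns = n_ch + 1
    start = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(start.strftime("%d.%m.%y"), 8),
            _pad(start.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    labels = [_pad(name, 16) for name in rec.channel_names] + [_pad("EDF Annotations", 16)]
    transducer = [_pad("", 80)] * ns
    phys_dim = [_pad("uV", 8)] * n_ch + [_pad("", 8)]
    phys_min = [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max] + [_pad("-1", 8)]
    phys_max_f = [_pad(f"{m:.6g}"[:8], 8) for m in phys_max] + [_pad("1", 8)]
    dig_min = [_pad("-32768", 8)] * ns
    dig_max_f = [_pad("32767", 8)] * ns
    prefilter = [_pad("", 80)] * ns
    spr = [_pad(str(fs), 8)] * n_ch + [_pad(str(n_annot_samples), 8)]
    reserved = [_pad("", 32)] * ns
    for block in (labels, transducer, phys_dim, phys_min, phys_max_f,
                  dig_min, dig_max_f, prefilter, spr, reserved):
        header += b"".join(block)

    scale = dig_max / phys_max  # digital per physical unit
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = rec.data[:, r * fs : (r + 1) * fs]
            if chunk.shape[1] < fs:
                chunk = np.pad(chunk, ((0, 0), (0, fs - chunk.shape[1])))
            dig = np.clip(np.round(chunk * scale[:, None]), -32768, 32767).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(tals[r].ljust(annot_bytes, b"\x00"))
    return path


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (annotations whose
    description matches a task label become events)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = []
    for onset, _dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        events.append((int(round(onset * raw.info["sfreq"])), str(desc)))
    events.sort(key=lambda e: e[0])
    # collapse duplicate sample indices (timestamp TALs are not returned
    # by mne, but be safe about coincident annotations)
    dedup, seen = [], set()
    for idx, task in events:
        if idx not in seen:
            dedup.append((idx, task))
            seen.add(idx)
    return Recording(
        data=data,
        channel_names=tuple(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        events=dedup,
    )


def save_epochs(epochs: EpochSet, path) -> Path:
    """Binary epoch block + JSON sidecar (labels, fs, window, channels)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data)
    sidecar = {
        "labels": [str(x) for x in epochs.labels],
        "fs": epochs.fs,
        "window": list(epochs.window),
        "channel_names": list(epochs.channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_epochs(path) -> EpochSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        labels=np.asarray(meta["labels"]),
        fs=meta["fs"],
        channel_names=tuple(meta["channel_names"]),
        window=tuple(meta["window"]),
    )


def save_features(fm: FeatureMatrix, path) -> Path:
    path = Path(path)
    fm.to_frame().to_csv(path, index=False)
    return path


def load_features(path, extractor: str = "") -> FeatureMatrix:
    import pandas as pd

    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return FeatureMatrix(df.to_numpy(), labels, extractor, tuple(df.columns))


def save_connectivity(cm: ConnectivityMatrix, path) -> Path:
    path = Path(path)
    cm.to_frame().to_csv(path)
    return path


def save_edge_list(net: BinaryNetwork, path) -> Path:
    path = Path(path)
    lines = [f"{a}\t{b}" for a, b in net.edge_list()]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
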