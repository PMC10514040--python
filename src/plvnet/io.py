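"""Standard-format I/O: delimited matrices with JSON sidecars, and EDF.

EDF files are written with a small built-in plain-EDF (16-bit) writer — one
data record per epoch, one signal per channel — and read back through
``mne.io.read_raw_edf``, which doubles as an independent check of the
writer. Round-trip accuracy is limited by EDF's 16-bit quantization of the
stated physical range.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import MontageSpec
from .synth import Condition, EpochedRecording


# ---------------------------------------------------------------------------
# Delimited matrix + sidecar
# ---------------------------------------------------------------------------

def write_matrix(path, matrix: np.ndarray, labels=None) -> None:
    """Write a square matrix as CSV with channel labels as header/index."""
    m = np.asarray(matrix)
    labels = list(labels) if labels is not None else [str(i) for i in range(m.shape[0])]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def recording_sidecar(rec: EpochedRecording, extra: dict | None = None) -> dict:
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "n_epochs": rec.n_epochs,
        "labels": list(rec.montage.labels),
        "region_sets": {k: list(v) for k, v in rec.montage.region_sets.items()},
        "group": rec.group,
        "subject_id": rec.subject_id,
        "condition": (
            {"mood": rec.condition.mood, "target_frequency": rec.condition.target_frequency}
            if rec.condition
            else None
        ),
    }
    if extra:
        meta.update(extra)
    return meta


def write_recording_delimited(path_stem, rec: EpochedRecording, extra_meta: dict | None = None) -> None:
    """Write a recording as ``<stem>.csv`` (channels x (samples*epochs), epochs
    concatenated) plus ``<stem>.json`` sidecar."""
    stem = Path(path_stem)
    flat = rec.data.transpose(0, 2, 1).reshape(rec.n_channels, -1)  # epochs concatenated
    pd.DataFrame(flat, index=list(rec.montage.labels)).to_csv(stem.with_suffix(".csv"), header=False)
    stem.with_suffix(".json").write_text(json.dumps(recording_sidecar(rec, extra_meta), indent=1))


def read_recording_delimited(path_stem) -> EpochedRecording:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"), header=None, index_col=0)
    labels = tuple(str(i) for i in df.index)
    if labels != tuple(meta["labels"]):
        raise ValueError("channel labels in CSV disagree with sidecar")
    flat = df.to_numpy(dtype=float)
    n_ep, n_samp = meta["n_epochs"], meta["n_samples"]
    data = flat.reshape(len(labels), n_ep, n_samp).transpose(0, 2, 1)
    cond = meta.get("condition")
    return EpochedRecording(
        data=data,
        fs=meta["fs"],
        montage=MontageSpec(labels=labels, region_sets={k: tuple(v) for k, v in meta.get("region_sets", {}).items()}),
        condition=Condition(**cond) if cond else None,
        group=meta.get("group"),
        subject_id=meta.get("subject_id"),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_recording_edf(path, rec: EpochedRecording) -> None:
    """Write a plain EDF file: one data record per epoch, one signal per channel.

    Physical range is the symmetric data maximum; samples are quantized to
    16-bit integers over [-32768, 32767].
    """
    path = Path(path)
    n_ch, n_samp, n_ep = rec.n_channels, rec.n_samples, rec.n_epochs
    record_dur = n_samp / rec.fs
    phys_max = float(np.max(np.abs(rec.data))) or 1.0
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _pad("0", 8)  # version
    header += _pad(rec.subject_id or "X", 80)  # patient id
    header += _pad("synthetic", 80)  # recording id
    header += _pad("01.01.00", 8)  # start date
    header += _pad("00.00.00", 8)  # start time
    header += _pad(str(256 + 256 * n_ch), 8)  # header bytes
    header += _pad("", 44)  # reserved
    header += _pad(str(n_ep), 8)  # number of records
    header += _pad(f"{record_dur:g}", 8)  # record duration (s)
    header += _pad(str(n_ch), 4)

    fields = [
        (16, [label for label in rec.montage.labels]),
        (80, ["EEG" for _ in range(n_ch)]),
        (8, ["uV" for _ in range(n_ch)]),
        (8, [f"{-phys_max:.6g}"[:8] for _ in range(n_ch)]),
        (8, [f"{phys_max:.6g}"[:8] for _ in range(n_ch)]),
        (8, [str(dig_min) for _ in range(n_ch)]),
        (8, [str(dig_max) for _ in range(n_ch)]),
        (80, ["" for _ in range(n_ch)]),
        (8, [str(n_samp) for _ in range(n_ch)]),
        (32, ["" for _ in range(n_ch)]),
    ]
    for width, values in fields:
        for v in values:
            header += _pad(v, width)

    scale = (dig_max - dig_min) / (2 * phys_max)
    with open(path, "wb") as fh:
        fh.write(header)
        for e in range(n_ep):
            block = rec.data[:, :, e]
            dig = np.round((block + phys_max) * scale + dig_min).astype("<i2")
            fh.write(dig.tobytes())


def read_recording_edf(
    path,
    n_epochs: int,
    epoch_len: float,
    montage: MontageSpec | None = None,
    condition: Condition | None = None,
    group: str | None = None,
    subject_id: str | None = None,
) -> EpochedRecording:
    """Read an EDF file via mne and re-epoch it into (ch, samples, epochs).

    If ``montage`` is given its labels must match the EDF channel labels.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = tuple(raw.ch_names)
    if montage is not None and tuple(montage.labels) != labels:
        offenders = [
            (a, b) for a, b in zip(montage.labels, labels) if a != b
        ] or list(set(montage.labels) ^ set(labels))
        raise ValueError(f"EDF channel labels disagree with montage: {offenders[:5]}")
    montage = montage or MontageSpec(labels=labels)
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    nsamp = int(round(epoch_len * fs))
    if data.shape[1] < n_epochs * nsamp:
        raise ValueError("EDF file shorter than the requested epoch layout")
    epochs = data[:, : n_epochs * nsamp].reshape(len(labels), n_epochs, nsamp).transpose(0, 2, 1)
    return EpochedRecording(
        data=epochs,
        fs=fs,
        montage=montage,
        condition=condition,
        group=group,
        subject_id=subject_id,
    )
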