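"""Recording and hypnogram I/O plus channel derivation.

EDF/EDF+ files are read through :mod:`mne`; a quick ASCII header scan
first validates the file so malformed headers and mixed sampling rates
fail with a clear message.  Hypnograms are CSV with one row per epoch:
``epoch_index,start_sec,stage,changed_from``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .edfio_min import scan_header, write_edf
from .hypnogram import Hypnogram
from .wavelets import EEGRecording

__all__ = [
    "read_recording",
    "write_recording",
    "derive_third_channel",
    "write_hypnogram",
    "read_hypnogram",
]

_ANNOTATION_LABELS = {"EDF Annotations", "BDF Annotations"}


def read_recording(path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    All data signals must share one sampling rate; annotation channels
    are ignored.  NaN runs in the data are an ingest error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    header = scan_header(path)
    rates = {}
    for lbl, spr in zip(header["labels"], header["samples_per_record"]):
        if lbl in _ANNOTATION_LABELS:
            continue
        rates.setdefault(spr / header["record_duration"], []).append(lbl)
    if len(rates) > 1:
        detail = "; ".join(f"{fs:g} Hz: {chs}" for fs, chs in sorted(rates.items()))
        raise ValueError(f"{path}: channels have mismatched sampling rates ({detail})")

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6          # mne reports volts
    meas = raw.info.get("meas_date")
    start = meas.replace(tzinfo=None) if meas is not None else header["start_time"]
    return EEGRecording(
        samples=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=start,
    )


def write_recording(rec: EEGRecording, path) -> None:
    """Write a recording to 16-bit EDF (microvolt physical units)."""
    write_edf(
        path,
        rec.samples,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        start_time=rec.start_time,
    )


def derive_third_channel(
    rec: EEGRecording,
    minuend: str = "FP1-AFz",
    subtrahend: str = "FP1-FP2",
    out_label: str = "FP2-AFz",
) -> EEGRecording:
    """Derive the third forehead channel by subtraction.

    With FP1 as the shared reference, (FP1-AFz) - (FP1-FP2) = FP2-AFz
    sample for sample; the derived channel is appended to the recording.
    """
    a = rec.channel(minuend)
    b = rec.channel(subtrahend)
    return EEGRecording(
        samples=np.vstack([rec.samples, (a - b)[None, :]]),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels) + [out_label],
        start_time=rec.start_time,
    )


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Serialise to CSV: epoch_index,start_sec,stage,changed_from."""
    frame = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "start_sec": hyp.start_seconds(),
            "stage": hyp.stages,
            "changed_from": ["" if c is None else c for c in hyp.changed_from],
        }
    )
    frame.to_csv(path, index=False)


def read_hypnogram(path, epoch_len: float | None = None) -> Hypnogram:
    """Read a hypnogram CSV back; unknown stage tokens are an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such hypnogram file: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty hypnogram file") from None
    if frame.empty or "stage" not in frame.columns:
        raise ValueError(f"{path}: hypnogram must have a non-empty 'stage' column")
    if epoch_len is None:
        if "start_sec" in frame.columns and len(frame) >= 2:
            epoch_len = float(frame["start_sec"].iloc[1] - frame["start_sec"].iloc[0])
        else:
            epoch_len = 30.0
    changed = [None] * len(frame)
    if "changed_from" in frame.columns:
        changed = [
            None if (pd.isna(c) or c == "") else str(c) for c in frame["changed_from"]
        ]
    return Hypnogram(
        stages=[str(s) for s in frame["stage"]],
        epoch_len=epoch_len,
        changed_from=changed,
    )
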