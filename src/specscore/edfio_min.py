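"""Minimal EDF (European Data Format) writing and header scanning.

Reading goes through ``mne``; this module only covers what no installed
backend provides: serialising a recording to a plain 16-bit EDF file, and
a lightweight ASCII header scan used to validate per-signal sampling
rates before handing the file to the reader.  Only the original EDF
subset is produced (no annotations, one fixed record duration).
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = ["write_edf", "scan_header"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b.ljust(width)


def write_edf(
    path,
    samples: np.ndarray,
    fs: float,
    channel_labels: list[str],
    start_time: datetime | None = None,
    physical_dim: str = "uV",
) -> None:
    """Write channels (rows of ``samples``, physical units) as 16-bit EDF.

    The record duration is 1 s; the signal is zero-padded to a whole
    number of records.  Physical min/max are taken per channel from the
    data, so round-tripped values agree to 16-bit quantisation.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    n_ch, n_samp = samples.shape
    if n_ch != len(channel_labels):
        raise ValueError("one label per channel required")
    if n_ch == 0:
        raise ValueError("cannot write an EDF with zero channels")
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("integer sampling rates only")
    spr = int(round(fs))                       # samples per 1-s record
    n_rec = int(np.ceil(n_samp / spr))
    start = start_time or datetime(2000, 1, 1, 0, 0, 0)

    pmin = samples.min(axis=1)
    pmax = samples.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)

    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in channel_labels),
            b"".join(_field("", 80) for _ in channel_labels),
            b"".join(_field(physical_dim, 8) for _ in channel_labels),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmin),
            b"".join(_field(f"{v:.8g}"[:8], 8) for v in pmax),
            b"".join(_field(str(_DIG_MIN), 8) for _ in channel_labels),
            b"".join(_field(str(_DIG_MAX), 8) for _ in channel_labels),
            b"".join(_field("", 80) for _ in channel_labels),
            b"".join(_field(str(spr), 8) for _ in channel_labels),
            b"".join(_field("", 32) for _ in channel_labels),
        ]
    )

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = samples
    digital = np.round(
        (padded - pmin[:, None]) * gain[:, None] + _DIG_MIN
    ).astype("<i2")
    # record-major, signal within record
    body = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2).tobytes()
    Path(path).write_bytes(header + sig + body)


def scan_header(path) -> dict:
    """Parse the ASCII EDF header: labels, per-signal rates, start time."""
    path = Path(path)
    raw = path.open("rb").read(256)
    if len(raw) < 256:
        raise ValueError(f"{path}: truncated EDF header")
    try:
        n_ch = int(raw[252:256].decode("ascii").strip())
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        date = raw[168:176].decode("ascii").strip()
        time = raw[176:184].decode("ascii").strip()
    except (UnicodeDecodeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed EDF header ({exc})") from None
    if n_ch <= 0:
        raise ValueError(f"{path}: EDF file declares zero signals")
    with path.open("rb") as fh:
        fh.seek(256)
        sig = fh.read(256 * n_ch)
    if len(sig) < 256 * n_ch:
        raise ValueError(f"{path}: truncated signal headers")
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii", errors="replace").strip()
        for i in range(n_ch)
    ]
    off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    spr = [
        int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_ch)
    ]
    try:
        start = datetime.strptime(date + " " + time, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = None
    return {
        "labels": labels,
        "samples_per_record": spr,
        "record_duration": rec_dur,
        "n_records": n_rec,
        "start_time": start,
    }
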