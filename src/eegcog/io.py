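"""Reading and writing of recordings and tables.

EDF support is a minimal, self-contained implementation of the standard
16-bit EDF layout (fixed-length header plus per-signal headers and
little-endian two-byte samples in data records), sufficient for
round-tripping the synthetic cohorts and for ingesting plain resting-EEG
files. Delimited numeric matrices with a channel-label header row are
supported as a text alternative.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: EEGRecording, record_duration: float = 1.0) -> None:
    """Write a 16-bit EDF file, one data record per ``record_duration`` s."""
    path = Path(path)
    spr = int(round(rec.sfreq * record_duration))
    if abs(spr - rec.sfreq * record_duration) > 1e-9 or spr < 1:
        raise ValueError("sfreq * record_duration must be a positive integer")
    n_ch, n_samp = rec.data.shape
    n_records = n_samp // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.data[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = phys_max - phys_min
    phys_min = np.where(span == 0, phys_min - 1, phys_min)
    phys_max = np.where(span == 0, phys_max + 1, phys_max)

    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.round(
        (data - phys_min[:, None]) * scale[:, None] + _EDF_DIG_MIN
    ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id or "X", 80),
            _pad("synthetic", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(f"{record_duration:g}", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        (rec.channel_labels, 16),
        (["" for _ in range(n_ch)], 80),  # transducer
        (["uV" for _ in range(n_ch)], 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([str(_EDF_DIG_MIN) for _ in range(n_ch)], 8),
        ([str(_EDF_DIG_MAX) for _ in range(n_ch)], 8),
        (["" for _ in range(n_ch)], 80),  # prefiltering
        ([str(spr) for _ in range(n_ch)], 8),
        (["" for _ in range(n_ch)], 32),  # reserved
    ]
    sig_header = b"".join(
        b"".join(_pad(v, width) for v in values) for values, width in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path) -> EEGRecording:
    """Read a 16-bit EDF file written by :func:`write_edf` or any plain
    continuous EDF with identical samples-per-record across signals."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        subject_id = head[8:88].decode("ascii").strip()
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch)

        def field(offset, width):
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = field(0, 16)
        phys_min = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        phys_max = np.array(
            [float(v) for v in field(16 + 80 + 8 + 8, 8)]
        )
        dig_min = np.array([float(v) for v in field(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in field(16 + 80 + 8 + 24, 8)])
        spr_list = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr_list)) != 1:
            raise ValueError("signals with differing sampling rates are unsupported")
        spr = spr_list[0]
        raw = np.frombuffer(fh.read(n_records * n_ch * spr * 2), dtype="<i2")
    raw = raw.reshape(n_records, n_ch, spr)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    sfreq = spr / record_duration
    return EEGRecording(
        data=data, channel_labels=labels, sfreq=sfreq, subject_id=subject_id
    )


def write_delimited(path, rec: EEGRecording, sep: str = ",") -> None:
    """Delimited matrix: header row of channel labels, samples as rows."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, sep=sep, index=False)


def read_delimited(path, sfreq: float, subject_id: str = "", sep: str = ",") -> EEGRecording:
    df = pd.read_csv(path, sep=sep)
    return EEGRecording(
        data=df.to_numpy(dtype=float).T,
        channel_labels=[str(c) for c in df.columns],
        sfreq=sfreq,
        subject_id=subject_id,
    )
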