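"""Sensor-level cleaning: filtering, re-referencing, epoching, rejection.

The cleaning chain is a documented, deterministic substitute for
platform-internal artifact pipelines: zero-phase 4th-order Butterworth
band-pass (plus optional notch), common average reference, fixed-length
overlapping epochs, and amplitude/variance-based bad-epoch rejection.
An external ICA cleanup can be plugged in via :func:`apply_spatial_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


class NoAnalyzableDataError(RuntimeError):
    """Raised when every epoch is rejected."""


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples in microvolts."""

    data: np.ndarray
    channel_labels: list[str]
    sfreq: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """Epoch store after rejection: n_epochs x channels x samples."""

    epochs: np.ndarray
    sfreq: float
    epoch_length: float
    overlap: float
    rejection_log: list[dict] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# Standard 10-20 labels in the order used by the synthetic generator.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]


def bandpass_notch(
    rec: EEGRecording,
    lo: float = 1.0,
    hi: float = 45.5,
    notch: float | None = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass with optional IIR notch.

    Applied forward-backward (``filtfilt``) so the response has zero
    phase; signal length is preserved.
    """
    nyq = rec.sfreq / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"hi={hi} must be below Nyquist {nyq}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=-1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch={notch} must be below Nyquist {nyq}")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.sfreq)
        out = signal.filtfilt(b, a, out, axis=-1)
    return replace(rec, data=out)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def apply_spatial_filter(rec: EEGRecording, matrix: np.ndarray) -> EEGRecording:
    """Hook for external spatial cleanup (e.g. an ICA mixing/unmixing product)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (rec.n_channels, rec.n_channels):
        raise ValueError("spatial filter must be channels x channels")
    return replace(rec, data=matrix @ rec.data)


def n_epochs_available(n_samples: int, epoch_samples: int, step: int) -> int:
    if n_samples < epoch_samples:
        return 0
    return (n_samples - epoch_samples) // step + 1


def epoch_and_reject(
    rec: EEGRecording,
    epoch_length: float = 4.0,
    overlap: float = 0.5,
    amp_thresh: float = 100.0,
    var_ratio_thresh: float = 5.0,
) -> EpochedEEG:
    """Cut overlapping fixed-length epochs and drop bad ones.

    An epoch is dropped when its peak absolute amplitude exceeds
    ``amp_thresh`` (microvolts) or when any channel's variance exceeds
    ``var_ratio_thresh`` times the median epoch variance of that channel.
    Every decision is recorded in the rejection log.
    """
    epoch_samples = int(round(epoch_length * rec.sfreq))
    if epoch_samples < 2:
        raise ValueError("epoch_length * sfreq must be >= 2 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(epoch_samples * (1 - overlap))))
    n = n_epochs_available(rec.n_samples, epoch_samples, step)
    if n == 0:
        raise NoAnalyzableDataError(
            f"recording shorter ({rec.n_samples} samples) than one epoch "
            f"({epoch_samples} samples)"
        )
    starts = np.arange(n) * step
    all_epochs = np.stack([rec.data[:, s : s + epoch_samples] for s in starts])

    peak = np.abs(all_epochs).max(axis=(1, 2))
    var = all_epochs.var(axis=2)  # n x channels
    med_var = np.median(var, axis=0)  # per channel
    # guard: channels with zero median variance cannot trigger the ratio rule
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(med_var > 0, var / med_var, 0.0)
    amp_bad = peak > amp_thresh
    var_bad = (ratio > var_ratio_thresh).any(axis=1)

    log = []
    keep_idx = []
    for i in range(n):
        if amp_bad[i]:
            reason = f"amplitude {peak[i]:.1f} uV > {amp_thresh}"
        elif var_bad[i]:
            reason = f"variance ratio > {var_ratio_thresh}"
        else:
            reason = None
        log.append(
            {
                "epoch": int(i),
                "start_sample": int(starts[i]),
                "kept": reason is None,
                "reason": reason,
            }
        )
        if reason is None:
            keep_idx.append(i)

    if not keep_idx:
        raise NoAnalyzableDataError("all epochs rejected; no analyzable data")

    return EpochedEEG(
        epochs=all_epochs[keep_idx],
        sfreq=rec.sfreq,
        epoch_length=epoch_length,
        overlap=overlap,
        rejection_log=log,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
    )
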