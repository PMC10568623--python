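"""Standardized minimum-norm (sLORETA-style) inverse and ROI aggregation.

The inverse kernel is the Tikhonov-regularized minimum-norm operator
``K = G' (G G' + alpha I)^+``; each source estimate is standardized by
the square root of the corresponding diagonal entry of the resolution
matrix ``K G``. With noiseless single-source data this standardization
gives zero localization error. Sources are scalar (fixed orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedEEG
from .rois import N_ROIS


@dataclass
class Leadfield:
    """Forward gain matrix (channels x sources) with a source->ROI map."""

    gain: np.ndarray
    source_roi_map: np.ndarray  # source index -> ROI index, 0-based

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_roi_map = np.asarray(self.source_roi_map, dtype=int)
        if self.gain.ndim != 2:
            raise ValueError("gain must be 2-D (channels x sources)")
        if self.source_roi_map.shape != (self.gain.shape[1],):
            raise ValueError("source_roi_map must have one entry per source")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class InverseOperator:
    kernel: np.ndarray  # sources x channels
    standardization: np.ndarray  # per-source positive scale
    alpha: float

    @property
    def standardized_kernel(self) -> np.ndarray:
        return self.kernel / self.standardization[:, None]


def default_alpha(gain: np.ndarray) -> float:
    """Scale-free default: 0.05 x mean eigenvalue of the sensor Gram matrix."""
    gram = gain @ gain.T
    return 0.05 * float(np.trace(gram)) / gram.shape[0]


def sloreta_operator(lf: Leadfield, alpha: float | None = None) -> InverseOperator:
    """Build the standardized minimum-norm inverse operator."""
    gain = lf.gain
    if alpha is None:
        alpha = default_alpha(gain)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    gram = gain @ gain.T + alpha * np.eye(lf.n_channels)
    if alpha == 0 and np.linalg.matrix_rank(gain) < lf.n_channels:
        raise np.linalg.LinAlgError(
            "gain is rank deficient; use alpha > 0 for a regularized inverse"
        )
    # pinv tolerates alpha=0 with a full-rank gain and is stable otherwise
    kernel = gain.T @ np.linalg.pinv(gram)
    resolution_diag = np.einsum("ij,ji->i", kernel, gain)
    resolution_diag = np.clip(resolution_diag, 1e-300, None)
    standardization = np.sqrt(resolution_diag)
    return InverseOperator(kernel=kernel, standardization=standardization, alpha=alpha)


def apply_inverse(epochs: EpochedEEG, op: InverseOperator) -> np.ndarray:
    """Standardized source estimates, n_epochs x sources x samples."""
    n_ch = epochs.epochs.shape[1]
    if op.kernel.shape[1] != n_ch:
        raise ValueError(
            f"kernel expects {op.kernel.shape[1]} channels, data has {n_ch}"
        )
    k = op.standardized_kernel
    return np.einsum("sc,ect->est", k, epochs.epochs)


@dataclass
class ROITimecourses:
    """ROI source signals: n_epochs x n_rois x samples."""

    signals: np.ndarray
    sfreq: float
    roi_labels: list[str]

    @property
    def n_rois(self) -> int:
        return self.signals.shape[1]


def roi_timecourses(
    src: np.ndarray,
    source_roi_map: np.ndarray,
    sfreq: float,
    n_rois: int = N_ROIS,
    roi_labels: list[str] | None = None,
    method: str = "mean",
) -> ROITimecourses:
    """Aggregate member sources per ROI (arithmetic mean by default).

    ``method="pca"`` takes the first principal component per ROI instead,
    sign-aligned with the mean signal.
    """
    src = np.asarray(src, dtype=float)
    if src.ndim == 2:
        src = src[None]
    source_roi_map = np.asarray(source_roi_map, dtype=int)
    n_epochs, n_sources, n_samples = src.shape
    if source_roi_map.shape != (n_sources,):
        raise ValueError("source_roi_map must have one entry per source")
    out = np.zeros((n_epochs, n_rois, n_samples))
    for roi in range(n_rois):
        members = np.flatnonzero(source_roi_map == roi)
        if members.size == 0:
            raise ValueError(f"ROI {roi} has no member sources")
        block = src[:, members, :]
        if method == "mean":
            out[:, roi, :] = block.mean(axis=1)
        elif method == "pca":
            for e in range(n_epochs):
                x = block[e]
                xc = x - x.mean(axis=1, keepdims=True)
                u, s, vt = np.linalg.svd(xc, full_matrices=False)
                pc = s[0] * vt[0]
                if np.dot(pc, x.mean(axis=0)) < 0:
                    pc = -pc
                out[e, roi, :] = pc / np.sqrt(x.shape[0])
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    labels = roi_labels or [f"ROI{i + 1}" for i in range(n_rois)]
    return ROITimecourses(signals=out, sfreq=sfreq, roi_labels=labels)


def read_leadfield(gain_path, map_path) -> Leadfield:
    """Read a delimited gain matrix (channels as rows) and a two-column
    source->ROI map file (source index, ROI number 1-based)."""
    gain = np.loadtxt(gain_path, delimiter=None)
    pairs = np.loadtxt(map_path, delimiter=None, dtype=int).reshape(-1, 2)
    order = np.argsort(pairs[:, 0])
    roi_map = pairs[order, 1] - 1  # file uses 1-based ROI numbers
    return Leadfield(gain=gain, source_roi_map=roi_map)
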