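"""Welch spectra, band powers (absolute/relative) and power ratios.

Defaults: Hann window, 2-s segments (0.5 Hz resolution, resolving every
band edge exactly), 50% segment overlap, averaged across segments and
epochs. Band integration uses half-open intervals [lo, hi) so shared
edges are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .bands import BandScheme
from .preprocess import EpochedEEG


@dataclass
class PowerSpectrum:
    """Power spectral density: channels x frequency bins (uV^2/Hz)."""

    psd: np.ndarray
    freqs: np.ndarray
    channel_labels: list[str]


@dataclass
class BandPowerTable:
    """Per channel x band absolute power (uV^2) and relative power."""

    absolute: np.ndarray  # channels x bands
    relative: np.ndarray  # channels x bands, rows sum to 1
    band_names: list[str]
    channel_labels: list[str]

    def band(self, name: str, kind: str = "absolute") -> np.ndarray:
        j = self.band_names.index(name)
        return (self.absolute if kind == "absolute" else self.relative)[:, j]


@dataclass
class RatioTable:
    """Per-channel TAR, TBR, TBR2, DAR; NaN marks an undefined ratio."""

    ratios: np.ndarray  # channels x 4
    ratio_names: tuple[str, ...]
    channel_labels: list[str]


def welch_psd(
    epochs: EpochedEEG,
    seg_length: int | None = None,
    seg_overlap: float = 0.5,
    window: str = "hann",
) -> PowerSpectrum:
    """Welch PSD averaged over segments within epochs and across epochs."""
    if seg_length is None:
        seg_length = int(round(2.0 * epochs.sfreq))
    n_samples = epochs.epochs.shape[2]
    if seg_length > n_samples:
        raise ValueError(
            f"seg_length {seg_length} exceeds epoch samples {n_samples}"
        )
    noverlap = int(round(seg_length * seg_overlap))
    freqs, psd = signal.welch(
        epochs.epochs,
        fs=epochs.sfreq,
        window=window,
        nperseg=seg_length,
        noverlap=noverlap,
        axis=-1,
    )
    return PowerSpectrum(
        psd=psd.mean(axis=0), freqs=freqs, channel_labels=list(epochs.channel_labels)
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)


def band_powers(psd: PowerSpectrum, scheme: BandScheme | None = None) -> BandPowerTable:
    """Integrate the PSD over each band; relative = band / total over all bands."""
    scheme = scheme or BandScheme()
    freqs = psd.freqs
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    lo_all, hi_all = scheme.total_range
    if freqs[0] > lo_all + 1e-9 or freqs[-1] < hi_all - 1e-9:
        raise ValueError(
            f"frequency grid [{freqs[0]}, {freqs[-1]}] does not cover "
            f"the band scheme range [{lo_all}, {hi_all})"
        )
    cols = []
    for name in scheme.names:
        lo, hi = scheme.edges(name)
        mask = _band_mask(freqs, lo, hi)
        if not mask.any():
            raise ValueError(f"no frequency bins inside band {name!r}")
        cols.append(psd.psd[:, mask].sum(axis=1) * df)
    absolute = np.column_stack(cols)
    total = absolute.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(total > 0, absolute / total, np.nan)
    return BandPowerTable(
        absolute=absolute,
        relative=relative,
        band_names=scheme.names,
        channel_labels=list(psd.channel_labels),
    )


RATIO_NAMES = ("TAR", "TBR", "TBR2", "DAR")


def power_ratios(bp: BandPowerTable) -> RatioTable:
    """TAR=theta/alpha, TBR=theta/beta, TBR2=theta/beta2, DAR=delta/alpha.

    "Alpha" is alpha1+alpha2 (8-12 Hz) and "beta" is beta1+beta2+beta3
    (12-30 Hz). A zero denominator yields NaN (flagged missing), never inf.
    """
    theta = bp.band("theta")
    delta = bp.band("delta")
    alpha = bp.band("alpha1") + bp.band("alpha2")
    beta = bp.band("beta1") + bp.band("beta2") + bp.band("beta3")
    beta2 = bp.band("beta2")

    def safe(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    ratios = np.column_stack(
        [safe(theta, alpha), safe(theta, beta), safe(theta, beta2), safe(delta, alpha)]
    )
    return RatioTable(
        ratios=ratios, ratio_names=RATIO_NAMES, channel_labels=list(bp.channel_labels)
    )


def spectral_feature_row(
    bp: BandPowerTable, rt: RatioTable
) -> dict[str, float]:
    """Flatten band powers and ratios into named feature columns."""
    row: dict[str, float] = {}
    for ci, ch in enumerate(bp.channel_labels):
        for bi, band in enumerate(bp.band_names):
            row[f"{ch}_{band}_abs"] = float(bp.absolute[ci, bi])
            row[f"{ch}_{band}_rel"] = float(bp.relative[ci, bi])
        for ri, rname in enumerate(rt.ratio_names):
            row[f"{ch}_{rname}"] = float(rt.ratios[ci, ri])
    return row
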