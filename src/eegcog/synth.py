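"""Synthetic EEG cohorts with known ground truth.

Everything downstream (preprocessing, spectra, inverse, connectivity,
modeling) is testable against cohorts generated here: band-limited
stochastic oscillators with imposed phase-lagged coupling (nonzero
imaginary coherence at chosen pairs/bands), a hemisphere-lateralized
slow-wave power excess encoding lesion side, and an outcome score that
is a noisy linear function of planted network features.

All randomness flows from a single cohort seed through
``numpy.random.SeedSequence.spawn`` so each subject is independently
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .bands import BandScheme
from .preprocess import CHANNELS_1020, EEGRecording
from .rois import N_ROIS, left_roi_numbers, right_roi_numbers, roi_table
from .source import Leadfield, ROITimecourses

OUTCOME_COL = "moca_std"
GROUP_COL = "lesion_side"
ID_COL = "subject_id"


@dataclass(frozen=True)
class CouplingSpec:
    """A set of phase-lagged couplings sharing one carrier band."""

    band: str
    pairs: list[tuple[int, int, float, float]]  # (roi_i, roi_j, lag_rad, strength)
    carrier_freq: float

    def validate(self, n_rois: int, scheme: BandScheme) -> None:
        lo, hi = scheme.edges(self.band)
        if not lo <= self.carrier_freq < hi:
            raise ValueError(
                f"carrier {self.carrier_freq} Hz outside band {self.band} [{lo},{hi})"
            )
        for i, j, lag, strength in self.pairs:
            if not (0 <= i < n_rois and 0 <= j < n_rois):
                raise ValueError(f"pair ({i},{j}) references roi >= {n_rois}")
            if not 0 <= strength <= 1:
                raise ValueError(f"strength {strength} outside [0,1]")
            if not -np.pi < lag <= np.pi:
                raise ValueError(f"lag {lag} outside (-pi, pi]")


@dataclass(frozen=True)
class SubjectProfile:
    lesion_side: str  # left | right | bilateral
    slow_wave_asymmetry: float = 1.0  # >= 1, applied to lesioned hemisphere
    network_effect: dict[str, float] = field(default_factory=dict)
    moca_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right", "bilateral"):
            raise ValueError(f"bad lesion side {self.lesion_side!r}")
        if self.slow_wave_asymmetry < 1.0:
            raise ValueError("slow_wave_asymmetry must be >= 1")
        if self.moca_noise_sd < 0:
            raise ValueError("moca_noise_sd must be >= 0")


@dataclass
class SyntheticSubject:
    subject_id: str
    lesion_side: str
    moca_std: float
    recording: EEGRecording | None = None
    roi_signals: ROITimecourses | None = None
    features: dict[str, float] | None = None


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    planted_features: list[tuple[str, float]]
    seed: int
    leadfield: Leadfield | None = None

    def feature_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {ID_COL: s.subject_id, GROUP_COL: s.lesion_side,
                   OUTCOME_COL: s.moca_std}
            row.update(s.features or {})
            rows.append(row)
        return pd.DataFrame(rows)


def _narrowband_analytic(
    rng: np.random.Generator,
    n_samples: int,
    sfreq: float,
    f_lo: float,
    f_hi: float,
) -> np.ndarray:
    """Band-pass-filtered Gaussian noise as a complex analytic signal,
    normalized to unit variance of its real part."""
    white = rng.standard_normal(n_samples + 2 * int(sfreq))
    sos = sp_signal.butter(4, [f_lo, f_hi], btype="bandpass", fs=sfreq, output="sos")
    nb = sp_signal.sosfiltfilt(sos, white)[int(sfreq) : int(sfreq) + n_samples]
    z = sp_signal.hilbert(nb)
    sd = np.real(z).std()
    return z / (sd if sd > 0 else 1.0)


def gen_coupled_sources(
    n_rois: int,
    sfreq: float,
    duration: float,
    specs: list[CouplingSpec],
    noise_sd: float = 1.0,
    seed: int = 0,
    scheme: BandScheme | None = None,
    carrier_bw: float = 2.0,
) -> ROITimecourses:
    """Stochastic ROI sources with phase-lagged coupling at chosen pairs.

    For a pair (i, j, lag, strength), ROI i carries a narrowband
    oscillation around the spec's carrier frequency and ROI j carries
    ``strength`` times a copy rotated by ``lag`` radians plus
    ``sqrt(1-strength^2)`` of an independent oscillation in the same
    band; a zero lag therefore yields (near-)zero imaginary coherence
    while any nonzero lag produces it in proportion to strength.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    scheme = scheme or BandScheme()
    n_samples = int(round(duration * sfreq))
    if n_samples < 4:
        raise ValueError("duration too short")
    for spec in specs:
        spec.validate(n_rois, scheme)
    rng = np.random.default_rng(seed)
    x = noise_sd * rng.standard_normal((n_rois, n_samples))
    for spec in specs:
        lo, hi = scheme.edges(spec.band)
        f_lo = max(lo, spec.carrier_freq - carrier_bw / 2)
        f_hi = min(hi, spec.carrier_freq + carrier_bw / 2)
        for i, j, lag, strength in spec.pairs:
            z = _narrowband_analytic(rng, n_samples, sfreq, f_lo, f_hi)
            z_ind = _narrowband_analytic(rng, n_samples, sfreq, f_lo, f_hi)
            x[i] += np.real(z)
            x[j] += strength * np.real(z * np.exp(-1j * lag)) + np.sqrt(
                max(0.0, 1.0 - strength**2)
            ) * np.real(z_ind)
    labels = [f"ROI{k + 1}" for k in range(n_rois)]
    return ROITimecourses(signals=x[None], sfreq=sfreq, roi_labels=labels)


def gen_leadfield(
    n_channels: int,
    n_sources: int,
    smoothness: float = 0.0,
    seed: int = 0,
) -> Leadfield:
    """Random full-row-rank gain matrix; ``smoothness`` > 0 correlates the
    topographies of adjacent sources (Gaussian smoothing along the
    source axis)."""
    if n_channels < 2 or n_sources < 1:
        raise ValueError("n_channels >= 2 and n_sources >= 1 required")
    rng = np.random.default_rng(seed)
    gain = rng.standard_normal((n_channels, n_sources))
    if smoothness > 0:
        from scipy.ndimage import gaussian_filter1d

        gain = gaussian_filter1d(gain, sigma=5.0 * smoothness, axis=1, mode="wrap")
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    if np.linalg.matrix_rank(gain) < n_channels:  # pragma: no cover
        gain += 1e-6 * rng.standard_normal(gain.shape)
    roi_map = np.arange(n_sources) % N_ROIS if n_sources >= N_ROIS else np.arange(n_sources)
    return Leadfield(gain=gain, source_roi_map=np.asarray(roi_map))


# Schematic 10-20 electrode coordinates (x: left<0, y: anterior>0).
_POS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.54), "Fz": (0.0, 0.50),
    "F4": (0.43, 0.54), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.54), "Pz": (0.0, -0.50),
    "P4": (0.43, -0.54), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

_LOBE_Y = {"frontal": 0.65, "temporal": 0.0, "parietal": -0.5,
           "occipital": -0.9, "isthmus": -0.35, "others": 0.2}


def _roi_positions() -> np.ndarray:
    """Deterministic schematic scalp positions for the 68 ROIs."""
    pos = np.zeros((N_ROIS, 2))
    by_lobe: dict[str, list[int]] = {}
    for r in roi_table():
        by_lobe.setdefault(r.lobe, []).append(r.number)
    for lobe, numbers in by_lobe.items():
        # one x slot per region pair, spread across the hemisphere
        pairs = sorted({(n + 1) // 2 for n in numbers})
        xs = np.linspace(0.25, 0.85, len(pairs))
        slot = {p: xs[k] for k, p in enumerate(pairs)}
        for n in numbers:
            sign = -1.0 if n % 2 == 0 else 1.0  # even = left hemisphere
            jitter = 0.08 * np.sin(3.1 * n)  # deterministic spread in y
            pos[n - 1] = (sign * slot[(n + 1) // 2], _LOBE_Y[lobe] + jitter)
    return pos


def structured_leadfield_1020(
    channel_labels: list[str] | None = None, sigma: float = 0.45
) -> Leadfield:
    """Gaussian-distance gain from 68 schematic ROI positions to the 19
    standard 10-20 electrodes; left ROIs project mostly to left channels."""
    labels = channel_labels or CHANNELS_1020
    ch_pos = np.array([_POS_1020[c] for c in labels])
    src_pos = _roi_positions()
    d2 = ((ch_pos[:, None, :] - src_pos[None, :, :]) ** 2).sum(axis=2)
    gain = np.exp(-d2 / (2 * sigma**2))
    return Leadfield(gain=gain, source_roi_map=np.arange(N_ROIS))


def gen_feature_table(
    n_subjects: int,
    n_features: int,
    planted: list[tuple[int, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table with a linear planted outcome.

    All features are iid standard normal; the outcome is the weighted sum
    of the planted columns plus Gaussian noise. Returns a frame with
    ``subject_id``, ``lesion_side`` (empty), feature columns and
    ``moca_std``.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if len(planted) > n_features:
        raise ValueError("more planted features than features")
    for idx, _ in planted:
        if not 0 <= idx < n_features:
            raise ValueError(f"planted index {idx} >= n_features {n_features}")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    elif len(feature_names) != n_features:
        raise ValueError("feature_names length mismatch")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_subjects, n_features))
    y = np.zeros(n_subjects)
    for idx, w in planted:
        y += w * X[:, idx]
    if not planted and noise_sd == 0:
        warnings.warn("no planted effect and zero noise: constant outcome",
                      RuntimeWarning, stacklevel=2)
    y += noise_sd * rng.standard_normal(n_subjects)
    df = pd.DataFrame(X, columns=feature_names)
    df.insert(0, ID_COL, [f"S{i:03d}" for i in range(n_subjects)])
    df.insert(1, GROUP_COL, "")
    df[OUTCOME_COL] = y
    return df


def network_feature_names(scheme: BandScheme | None = None) -> list[str]:
    """The full 1120-column network feature layout (8 bands x 140)."""
    scheme = scheme or BandScheme()
    names = []
    for band in scheme.names:
        names += [
            f"{band}_global_efficiency",
            f"{band}_char_path_length",
            f"{band}_clustering",
            f"{band}_modularity",
        ]
        names += [f"{band}_clustering_ROI{k}" for k in range(1, N_ROIS + 1)]
        names += [f"{band}_nodal_efficiency_ROI{k}" for k in range(1, N_ROIS + 1)]
    return names


DEFAULT_PLANTED = [
    ("theta_global_efficiency", 1.0),
    ("theta_clustering_ROI2", 0.8),
    ("theta_clustering_ROI5", 0.8),
]


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort (see ``docs`` in the README)."""

    n_subjects: int = 20
    mode: str = "features"  # "features" (fast) or "eeg" (full signal chain)
    seed: int = 0
    # lesion-side distribution
    p_left: float = 0.45
    p_right: float = 0.45
    p_bilateral: float = 0.10
    slow_wave_asymmetry: float = 2.0
    # outcome model
    planted: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_PLANTED)
    )
    signal_fraction: float = 0.8  # var(signal) / var(outcome)
    moca_mean: float = 50.0
    moca_scale: float = 10.0
    # eeg mode
    duration: float = 60.0
    sfreq: float = 250.0
    theta_pairs: list[tuple[int, int]] = field(
        default_factory=lambda: [(0, 4), (1, 5), (2, 8), (3, 9), (6, 10), (7, 11)]
    )
    sensor_noise_sd: float = 0.5
    # skip the per-subject network-feature chain (laterality-only cohorts)
    compute_features: bool = True


def _outcome_from_features(
    feats: np.ndarray, weights: np.ndarray, signal_fraction: float,
    rng: np.random.Generator, mean: float, scale: float,
) -> np.ndarray:
    """Noisy linear outcome with a controlled signal-variance fraction."""
    raw = feats @ weights
    sd = raw.std()
    if sd == 0:
        warnings.warn("degenerate planted signal: constant outcome",
                      RuntimeWarning, stacklevel=2)
        z = np.zeros_like(raw)
    else:
        z = (raw - raw.mean()) / sd
    if not 0 < signal_fraction <= 1:
        raise ValueError("signal_fraction must be in (0, 1]")
    noise_sd = np.sqrt((1 - signal_fraction) / signal_fraction)
    y = z + noise_sd * rng.standard_normal(len(raw))
    return mean + scale * y


def gen_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort in feature mode (fast) or full EEG mode."""
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if config.mode == "features":
        return _gen_cohort_features(config)
    if config.mode == "eeg":
        return _gen_cohort_eeg(config)
    raise ValueError(f"unknown cohort mode {config.mode!r}")


def _draw_sides(config: CohortConfig, rng: np.random.Generator) -> list[str]:
    p = np.array([config.p_left, config.p_right, config.p_bilateral], dtype=float)
    if p.sum() <= 0:
        raise ValueError("lesion-side probabilities must sum to > 0")
    p = p / p.sum()
    return list(rng.choice(["left", "right", "bilateral"], size=config.n_subjects, p=p))


def _gen_cohort_features(config: CohortConfig) -> SyntheticCohort:
    names = network_feature_names()
    idx = {n: i for i, n in enumerate(names)}
    for name, _ in config.planted:
        if name not in idx:
            raise ValueError(f"planted feature {name!r} not in the network layout")
    ss = np.random.SeedSequence(config.seed)
    rng_x, rng_y, rng_side = [np.random.default_rng(s) for s in ss.spawn(3)]
    X = rng_x.standard_normal((config.n_subjects, len(names)))
    weights = np.zeros(len(names))
    for name, w in config.planted:
        weights[idx[name]] = w
    feats = X
    y = _outcome_from_features(
        feats, weights, config.signal_fraction, rng_y,
        config.moca_mean, config.moca_scale,
    )
    sides = _draw_sides(config, rng_side)
    subjects = []
    for i in range(config.n_subjects):
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:03d}",
                lesion_side=sides[i],
                moca_std=float(y[i]),
                features=dict(zip(names, X[i])),
            )
        )
    return SyntheticCohort(
        subjects=subjects, planted_features=list(config.planted), seed=config.seed
    )


def _lesioned_roi_indices(side: str) -> np.ndarray:
    if side == "left":
        nums = left_roi_numbers()
    elif side == "right":
        nums = right_roi_numbers()
    else:
        nums = left_roi_numbers() + right_roi_numbers()
    return np.asarray(nums) - 1


def gen_subject_sources(
    config: CohortConfig, side: str, rng: np.random.Generator
) -> ROITimecourses:
    """One subject's 68-ROI source signals: per-band background activity,
    theta coupling with subject-varying strength, and a delta+theta
    amplitude excess on the lesioned hemisphere."""
    scheme = BandScheme()
    n = int(round(config.duration * config.sfreq))
    sf = config.sfreq
    x = 0.3 * rng.standard_normal((N_ROIS, n))

    def nb(lo, hi, size):
        white = rng.standard_normal((size, n + int(sf)))
        sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=sf, output="sos")
        out = sp_signal.sosfiltfilt(sos, white, axis=1)[:, int(sf) // 2 : int(sf) // 2 + n]
        sd = out.std(axis=1, keepdims=True)
        return out / np.where(sd > 0, sd, 1.0)

    slow = nb(1.0, 8.0, N_ROIS)  # delta+theta background
    alpha = nb(8.0, 12.0, N_ROIS)
    lesion_gain = np.ones(N_ROIS)
    lesion_gain[_lesioned_roi_indices(side)] = config.slow_wave_asymmetry
    x += lesion_gain[:, None] * slow + 0.7 * alpha

    # subject-varying theta coupling drives between-subject network variation
    strengths = rng.uniform(0.2, 0.95, size=len(config.theta_pairs))
    lags = rng.uniform(np.pi / 4, 3 * np.pi / 4, size=len(config.theta_pairs))
    for (i, j), s, lag in zip(config.theta_pairs, strengths, lags):
        z = _narrowband_analytic(rng, n, sf, 5.0, 7.0)
        z2 = _narrowband_analytic(rng, n, sf, 5.0, 7.0)
        x[i] += lesion_gain[i] * np.real(z)
        x[j] += lesion_gain[j] * (
            s * np.real(z * np.exp(-1j * lag))
            + np.sqrt(1 - s**2) * np.real(z2)
        )
    labels = [r.name for r in roi_table()]
    _ = scheme
    return ROITimecourses(signals=x[None], sfreq=sf, roi_labels=labels)


def _gen_cohort_eeg(config: CohortConfig) -> SyntheticCohort:
    from .connectivity import subject_network_features

    lf = structured_leadfield_1020()
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.n_subjects + 2)
    rng_side = np.random.default_rng(child[-2])
    rng_y = np.random.default_rng(child[-1])
    sides = _draw_sides(config, rng_side)

    subjects: list[SyntheticSubject] = []
    feat_rows: list[dict[str, float]] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(child[i])
        roi = gen_subject_sources(config, sides[i], rng)
        sensors = lf.gain @ roi.signals[0]
        sensors += config.sensor_noise_sd * rng.standard_normal(sensors.shape)
        rec = EEGRecording(
            data=sensors, channel_labels=list(CHANNELS_1020),
            sfreq=config.sfreq, subject_id=f"S{i:03d}",
        )
        row = None
        if config.compute_features:
            row, _ = subject_network_features(roi, seed=config.seed)
            feat_rows.append(row)
        subjects.append(
            SyntheticSubject(
                subject_id=f"S{i:03d}", lesion_side=sides[i], moca_std=np.nan,
                recording=rec, roi_signals=roi, features=row,
            )
        )
    if not config.compute_features:
        y = config.moca_mean + config.moca_scale * rng_y.standard_normal(
            config.n_subjects
        )
        for s, yi in zip(subjects, y):
            s.moca_std = float(yi)
        return SyntheticCohort(
            subjects=subjects, planted_features=[], seed=config.seed, leadfield=lf,
        )
    names = list(feat_rows[0])
    feats = np.array([[r[n] for n in names] for r in feat_rows])
    weights = np.zeros(len(names))
    name_idx = {n: k for k, n in enumerate(names)}
    for name, w in config.planted:
        if name not in name_idx:
            raise ValueError(f"planted feature {name!r} not produced by the chain")
        weights[name_idx[name]] = w
    y = _outcome_from_features(
        feats, weights, config.signal_fraction, rng_y,
        config.moca_mean, config.moca_scale,
    )
    for s, yi in zip(subjects, y):
        s.moca_std = float(yi)
    return SyntheticCohort(
        subjects=subjects, planted_features=list(config.planted),
        seed=config.seed, leadfield=lf,
    )
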