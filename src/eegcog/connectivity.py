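"""Cross-spectral density, imaginary coherence, proportional thresholding
and graph metrics over the ROI network.

The connectivity edge weight between ROIs x and y in a band is the mean
over band bins of ``|Im(S_xy / sqrt(S_xx S_yy))|`` — the magnitude of the
imaginary part of complex coherency, which is insensitive to zero-lag
(volume-conducted) mixing. Networks are built per band by retaining the
top fraction (default 25%) of edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms import community as nx_comm
from scipy import signal as sp_signal
from scipy.sparse.csgraph import shortest_path

from .bands import BandScheme
from .rois import N_ROIS
from .source import ROITimecourses


@dataclass
class CrossSpectrum:
    """Complex cross-spectral density, n x n x frequency bins.

    Hermitian at every bin; the diagonal holds each signal's (real,
    nonnegative) PSD.
    """

    S: np.ndarray
    freqs: np.ndarray

    @property
    def n_signals(self) -> int:
        return self.S.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric |Im(coherency)| matrix for one band; zero diagonal."""

    values: np.ndarray
    band: str


@dataclass
class ThresholdedNetwork:
    """Weighted adjacency after proportional thresholding."""

    adjacency: np.ndarray
    density: float
    band: str
    n_retained: int = 0


@dataclass
class NetworkFeatureSet:
    band: str
    global_efficiency: float
    char_path_length: float
    clustering_mean: float
    modularity: float
    nodal_clustering: np.ndarray
    nodal_efficiency: np.ndarray
    partition: list[set[int]]
    disconnected: bool


def cross_spectral_density(
    roi: ROITimecourses,
    seg_length: int | None = None,
    seg_overlap: float = 0.5,
    window: str = "hann",
) -> CrossSpectrum:
    """Welch-style CSD averaged over segments within and across epochs."""
    x = roi.signals
    sfreq = roi.sfreq
    if seg_length is None:
        seg_length = int(round(2.0 * sfreq))
    n_epochs, n_sig, n_samples = x.shape
    if seg_length > n_samples:
        raise ValueError("seg_length exceeds samples per epoch")
    step = seg_length - int(round(seg_length * seg_overlap))
    step = max(1, step)
    starts = range(0, n_samples - seg_length + 1, step)
    win = sp_signal.get_window(window, seg_length)
    scale = 1.0 / (sfreq * (win**2).sum())
    freqs = np.fft.rfftfreq(seg_length, d=1.0 / sfreq)
    n_f = len(freqs)
    acc = np.zeros((n_sig, n_sig, n_f), dtype=complex)
    n_segs = 0
    for e in range(n_epochs):
        for s in starts:
            seg = x[e, :, s : s + seg_length]
            seg = seg - seg.mean(axis=1, keepdims=True)
            X = np.fft.rfft(seg * win, axis=1)
            acc += np.einsum("if,jf->ijf", X, np.conj(X))
            n_segs += 1
    if n_segs < 2:
        warnings.warn(
            "fewer than 2 segments: imaginary cross-spectra are degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    S = acc * (scale / max(n_segs, 1))
    # one-sided correction: double every bin except DC (and Nyquist if present)
    factor = np.full(n_f, 2.0)
    factor[0] = 1.0
    if seg_length % 2 == 0:
        factor[-1] = 1.0
    S *= factor
    return CrossSpectrum(S=S, freqs=freqs)


def icoh_matrix(
    cs: CrossSpectrum, band: str, scheme: BandScheme | None = None
) -> ConnectivityMatrix:
    """Band-mean |Im(coherency)|: entry (x,y) = mean over band bins of
    |Im(S_xy / sqrt(S_xx S_yy))|."""
    scheme = scheme or BandScheme()
    lo, hi = scheme.edges(band)
    mask = (cs.freqs >= lo - 1e-9) & (cs.freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"frequency grid has no bins inside band {band!r}")
    S = cs.S[:, :, mask]
    psd = np.real(np.einsum("iif->if", S))
    bad = (psd <= 0).any(axis=1)
    denom = np.sqrt(psd[:, None, :] * psd[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = S / denom
    icoh = np.abs(np.imag(coherency)).mean(axis=2)
    icoh[bad, :] = np.nan
    icoh[:, bad] = np.nan
    np.fill_diagonal(icoh, 0.0)
    icoh = np.clip(icoh, 0.0, 1.0)
    icoh = (icoh + icoh.T) / 2.0  # enforce exact symmetry
    return ConnectivityMatrix(values=icoh, band=band)


def proportional_threshold(
    cm: ConnectivityMatrix, density: float = 0.25
) -> ThresholdedNetwork:
    """Retain the ``floor(density * n_pairs)`` largest upper-triangle
    entries, zeroing the rest. Ties break deterministically by lower
    (row, col) index first."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    vals = np.nan_to_num(cm.values, nan=0.0)
    n = vals.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = vals[iu, ju]
    n_pairs = len(w)
    k = int(np.floor(density * n_pairs))
    adj = np.zeros_like(vals)
    if np.all(w == 0) or k == 0:
        warnings.warn("all-zero connectivity: empty network", RuntimeWarning,
                      stacklevel=2)
        return ThresholdedNetwork(adjacency=adj, density=density, band=cm.band,
                                  n_retained=0)
    # stable sort on -w keeps (row, col) order among ties
    order = np.argsort(-w, kind="stable")[:k]
    adj[iu[order], ju[order]] = w[order]
    adj = adj + adj.T
    return ThresholdedNetwork(adjacency=adj, density=density, band=cm.band,
                              n_retained=k)


def _distances(adj: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        lengths = (adj > 0).astype(float)
    else:
        with np.errstate(divide="ignore"):
            lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    return shortest_path(lengths, method="D", directed=False, unweighted=(mode == "binary"))


def network_metrics(
    net: ThresholdedNetwork,
    mode: str = "weighted",
    community_restarts: int = 10,
    seed: int = 0,
) -> NetworkFeatureSet:
    """Global efficiency, characteristic path length, clustering (mean and
    nodal), modularity (best of seeded restarts) and nodal efficiency.

    Weighted mode uses edge length ``1/weight`` for distances and the
    geometric-mean (Onnela) weighted clustering coefficient. The
    characteristic path length is averaged over connected pairs only; a
    flag records whether the graph was disconnected.
    """
    if mode not in ("weighted", "binary"):
        raise ValueError("mode must be 'weighted' or 'binary'")
    adj = net.adjacency
    n = adj.shape[0]
    if n < 2:
        raise ValueError("network metrics need >= 2 nodes")

    d = _distances(adj, mode)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    with np.errstate(divide="ignore"):
        inv_d = np.where(finite, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    global_eff = float(inv_d[off].sum() / (n * (n - 1)))
    nodal_eff = inv_d.sum(axis=1) / (n - 1)
    disconnected = bool((~finite & off).any())
    cpl = float(d[finite].mean()) if finite.any() else float("inf")

    G = nx.from_numpy_array(adj)
    weight_key = "weight" if mode == "weighted" else None
    clust = nx.clustering(G, weight=weight_key)
    nodal_clust = np.array([clust[i] for i in range(n)])

    edges_exist = net.n_retained > 0 and adj.sum() > 0
    best_q = 0.0
    best_part: list[set[int]] = [set(range(n))]
    if edges_exist:
        best_q = -np.inf
        for r in range(max(1, community_restarts)):
            part = nx_comm.louvain_communities(
                G, weight="weight" if mode == "weighted" else None,
                seed=seed + r,
            )
            q = nx_comm.modularity(
                G, part, weight="weight" if mode == "weighted" else None
            )
            if q > best_q:
                best_q = q
                best_part = [set(c) for c in part]

    return NetworkFeatureSet(
        band=net.band,
        global_efficiency=global_eff,
        char_path_length=cpl,
        clustering_mean=float(nodal_clust.mean()),
        modularity=float(best_q),
        nodal_clustering=nodal_clust,
        nodal_efficiency=nodal_eff,
        partition=best_part,
        disconnected=disconnected,
    )


GLOBAL_METRICS = ("global_efficiency", "char_path_length", "clustering", "modularity")
NODAL_METRICS = ("clustering", "nodal_efficiency")


def assemble_network_features(
    nets: dict[str, NetworkFeatureSet], scheme: BandScheme | None = None
) -> dict[str, float]:
    """One feature row: ``<band>_<metric>`` globals plus
    ``<band>_<metric>_ROI<k>`` nodal columns (ROI numbers 1-based)."""
    scheme = scheme or BandScheme()
    missing = [b for b in scheme.names if b not in nets]
    if missing:
        raise ValueError(f"missing band feature sets: {missing}")
    row: dict[str, float] = {}
    for band in scheme.names:
        fs = nets[band]
        row[f"{band}_global_efficiency"] = fs.global_efficiency
        row[f"{band}_char_path_length"] = fs.char_path_length
        row[f"{band}_clustering"] = fs.clustering_mean
        row[f"{band}_modularity"] = fs.modularity
        for k in range(len(fs.nodal_clustering)):
            row[f"{band}_clustering_ROI{k + 1}"] = float(fs.nodal_clustering[k])
        for k in range(len(fs.nodal_efficiency)):
            row[f"{band}_nodal_efficiency_ROI{k + 1}"] = float(fs.nodal_efficiency[k])
    return row


@dataclass(frozen=True)
class FeatureName:
    band: str
    metric: str
    roi: int | None  # 1-based ROI number, None for graph-global features
    hemisphere: str | None
    lobe: str | None


def parse_feature_name(name: str, scheme: BandScheme | None = None) -> FeatureName:
    """Parse ``<band>_<metric>[_ROI<k>]`` back into its parts."""
    from .rois import hemisphere_of, lobe_of

    scheme = scheme or BandScheme()
    band, _, rest = name.partition("_")
    if band not in scheme.names:
        raise ValueError(f"feature {name!r} does not start with a known band")
    roi: int | None = None
    if "_ROI" in rest:
        rest, _, num = rest.rpartition("_ROI")
        roi = int(num)
    return FeatureName(
        band=band,
        metric=rest,
        roi=roi,
        hemisphere=hemisphere_of(roi) if roi else None,
        lobe=lobe_of(roi) if roi else None,
    )


def connectivity_long_table(
    matrices: dict[str, ConnectivityMatrix]
) -> list[tuple[str, int, int, float]]:
    """Long-format export rows (band, roi_i, roi_j, icoh), 1-based upper triangle."""
    rows = []
    for band, cm in matrices.items():
        n = cm.values.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        for i, j in zip(iu, ju):
            rows.append((band, int(i) + 1, int(j) + 1, float(cm.values[i, j])))
    return rows


def subject_network_features(
    roi: ROITimecourses,
    scheme: BandScheme | None = None,
    density: float = 0.25,
    mode: str = "weighted",
    seed: int = 0,
    seg_length: int | None = None,
) -> tuple[dict[str, float], dict[str, ConnectivityMatrix]]:
    """Full per-subject chain: CSD -> per-band iCOH -> threshold -> metrics."""
    scheme = scheme or BandScheme()
    cs = cross_spectral_density(roi, seg_length=seg_length)
    matrices: dict[str, ConnectivityMatrix] = {}
    nets: dict[str, NetworkFeatureSet] = {}
    for band in scheme.names:
        cm = icoh_matrix(cs, band, scheme)
        matrices[band] = cm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tn = proportional_threshold(cm, density)
        nets[band] = network_metrics(tn, mode=mode, seed=seed)
    return assemble_network_features(nets, scheme), matrices
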