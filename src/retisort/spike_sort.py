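"""Spike sorting: wavelet-packet features + K-means with silhouette model selection.

Each detected waveform is decomposed with a full three-level wavelet
packet tree (8 terminal sub-bands); the standard deviation and first
quartile of each terminal node's coefficients give a 16-dimensional
feature vector. Features are column-standardized, clustered with
K-means (Lloyd's algorithm, squared-Euclidean distance, several random
restarts), and the number of clusters is chosen by maximizing the mean
silhouette coefficient

    s(i) = (b(i) - a(i)) / max{a(i), b(i)}

where a(i) is the mean distance from sample i to the rest of its own
cluster and b(i) the smallest mean distance to any other cluster. A
single unit (k = 1) is returned when too few spikes are available or
when no split reaches a minimum mean silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "SilhouetteReport",
    "SortingConfig",
    "UnitLabels",
    "wpd_features",
    "kmeans_fit",
    "mean_silhouette",
    "select_k",
    "sort_channel",
]


@dataclass
class FeatureMatrix:
    """Standardized spike features (rows: spikes, columns: node x statistic)."""

    X: np.ndarray
    names: list[str]
    means: np.ndarray  # pre-standardization column means (kept columns)
    sds: np.ndarray  # pre-standardization column sds (kept columns)
    raw: np.ndarray  # unstandardized features, all 2^depth * 2 columns

    @property
    def n_spikes(self) -> int:
        return self.X.shape[0]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    seed: int | None
    n_iterations: int
    inertia_history: list[float] = field(default_factory=list)


@dataclass
class SilhouetteReport:
    """Per-sample silhouette terms plus, when used for model selection,
    the mean silhouette per candidate k and the chosen k."""

    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    mean_sc: float
    by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None


@dataclass
class SortingConfig:
    wavelet: str = "haar"
    depth: int = 3
    raw_features: bool = False  # raw terminal-node coefficients instead of {sd, Q1}
    k_max: int = 5
    sc_floor: float = 0.20
    min_spikes: int = 10
    restarts: int = 10
    max_iter: int = 300
    seed: int = 0


@dataclass
class UnitLabels:
    """Per-spike unit assignment for one channel (unit = channel x cluster)."""

    channel: int
    spike_indices: np.ndarray
    labels: np.ndarray
    n_units: int
    model: ClusterModel | None = None
    report: SilhouetteReport | None = None


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def wpd_features(
    waveforms: np.ndarray,
    depth: int = 3,
    wavelet: str = "haar",
    summaries: bool = True,
) -> FeatureMatrix:
    """Wavelet-packet {sd, Q1} features per terminal node, standardized.

    The full packet tree to ``depth`` levels has ``2**depth`` terminal
    nodes; per spike and node the standard deviation and first quartile
    (linear-interpolation quantile at p = 0.25) of the node's
    coefficients are computed. With ``summaries=False`` the raw
    terminal-node coefficients themselves are the features instead.
    Columns are standardized to mean 0 / sd 1; constant columns are
    dropped from the standardized matrix.
    """
    waveforms = np.asarray(waveforms, dtype=np.float64)
    if waveforms.ndim != 2:
        raise ValueError("waveforms must be a 2-D (spikes x samples) matrix")
    n, L = waveforms.shape
    if L < 2**depth:
        raise ValueError(f"waveform length {L} < 2**depth = {2 ** depth}")
    rows: list[list[float]] = []
    names: list[str] = []
    for i in range(n):
        wp = pywt.WaveletPacket(
            data=waveforms[i], wavelet=wavelet, mode="periodization", maxlevel=depth
        )
        nodes = wp.get_level(depth, order="natural")
        row: list[float] = []
        for node in nodes:
            c = np.asarray(node.data, dtype=np.float64)
            if summaries:
                row.extend([c.std(), np.quantile(c, 0.25)])
            else:
                row.extend(c)
        rows.append(row)
        if i == 0:
            for node in nodes:
                if summaries:
                    names.extend([f"{node.path}_sd", f"{node.path}_q1"])
                else:
                    names.extend(
                        f"{node.path}_c{j}" for j in range(len(node.data))
                    )
    feats = np.asarray(rows)
    means = feats.mean(axis=0)
    sds = feats.std(axis=0)
    keep = sds > 0
    X = (feats[:, keep] - means[keep]) / sds[keep]
    return FeatureMatrix(
        X=X,
        names=[nm for nm, k in zip(names, keep) if k],
        means=means[keep],
        sds=sds[keep],
        raw=feats,
    )


# ---------------------------------------------------------------------------
# K-means (Lloyd)
# ---------------------------------------------------------------------------


def _as_array(X: FeatureMatrix | np.ndarray) -> np.ndarray:
    return X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=np.float64)


def _lloyd_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1, dtype=np.int64)
    history: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centroids, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # re-seed emptied clusters to the current farthest point, repeating
        # until every cluster is populated (each pass strictly fills one)
        for _ in range(n):
            empty = [j for j in range(k) if not np.any(new_labels == j)]
            if not empty:
                break
            far = int(d2[np.arange(n), new_labels].argmax())
            centroids[empty[0]] = X[far]
            d2 = cdist(X, centroids, metric="sqeuclidean")
            new_labels = d2.argmin(axis=1)
        converged = np.array_equal(new_labels, labels)
        labels = new_labels
        for j in range(k):
            members = labels == j
            if members.any():  # ties on duplicate points can defeat re-seeding
                centroids[j] = X[members].mean(axis=0)
        inertia = float(((X - centroids[labels]) ** 2).sum())
        history.append(inertia)
        if converged:
            break
    # degenerate inputs (fewer distinct points than k) can leave clusters
    # empty after convergence; split members off the largest clusters so the
    # returned model never has an empty cluster
    for j in range(k):
        if not np.any(labels == j):
            donor = int(np.bincount(labels, minlength=k).argmax())
            member = int(np.flatnonzero(labels == donor)[0])
            labels = labels.copy()
            labels[member] = j
            centroids[j] = X[member]
            centroids[donor] = X[labels == donor].mean(axis=0)
    inertia = float(((X - centroids[labels]) ** 2).sum())
    if not history or inertia != history[-1]:
        history.append(inertia)
    return labels, centroids, inertia, it, history


def kmeans_fit(
    X: FeatureMatrix | np.ndarray,
    k: int,
    seed: int | None = 0,
    restarts: int = 10,
    max_iter: int = 300,
) -> ClusterModel:
    """Lloyd's K-means: random-sample initialization, best of ``restarts``.

    Assignment uses squared-Euclidean distance; centroids are cluster
    means; iteration stops when assignments no longer change. Clusters
    that empty during iteration are re-seeded to the farthest point, so
    the returned model never has an empty cluster.
    """
    Xa = _as_array(X)
    n = Xa.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(max(restarts, 1)):
        labels, centroids, inertia, n_it, hist = _lloyd_once(Xa, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, n_it, hist)
    labels, centroids, inertia, n_it, hist = best
    return ClusterModel(
        k=k, centroids=centroids, labels=labels, inertia=inertia,
        seed=seed, n_iterations=n_it, inertia_history=hist,
    )


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------


def mean_silhouette(X: FeatureMatrix | np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Per-sample silhouette terms and the mean silhouette coefficient.

    a(i) is the mean Euclidean distance to the other members of i's
    cluster (0 when i is alone in its cluster); b(i) the minimum over
    other clusters of the mean distance to that cluster; s(i) is 0
    whenever a(i) = b(i) (including the all-identical-points case).
    """
    Xa = _as_array(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    D = cdist(Xa, Xa)
    n = Xa.shape[0]
    a = np.zeros(n)
    b = np.full(n, np.inf)
    for lab in uniq:
        in_c = labels == lab
        size = int(in_c.sum())
        mean_to_c = D[:, in_c].sum(axis=1)
        # own cluster: exclude self; singleton -> a = 0
        own = mean_to_c[in_c]
        a[in_c] = own / (size - 1) if size > 1 else 0.0
        other = ~in_c
        b[other] = np.minimum(b[other], mean_to_c[other] / size)
    denom = np.maximum(a, b)
    s = np.zeros(n)
    neq = a != b
    s[neq] = (b[neq] - a[neq]) / denom[neq]
    return SilhouetteReport(a=a, b=b, s=s, mean_sc=float(s.mean()))


# ---------------------------------------------------------------------------
# Model selection and channel sorting
# ---------------------------------------------------------------------------


def _single_cluster_model(Xa: np.ndarray, seed: int | None) -> ClusterModel:
    centroid = Xa.mean(axis=0, keepdims=True) if Xa.size else np.zeros((1, 1))
    labels = np.zeros(Xa.shape[0], dtype=np.int64)
    inertia = float(((Xa - centroid) ** 2).sum()) if Xa.size else 0.0
    return ClusterModel(k=1, centroids=centroid, labels=labels, inertia=inertia,
                        seed=seed, n_iterations=0)


def select_k(
    X: FeatureMatrix | np.ndarray,
    k_max: int = 5,
    seed: int | None = 0,
    restarts: int = 10,
    sc_floor: float = 0.20,
    min_spikes: int = 10,
    max_iter: int = 300,
) -> tuple[ClusterModel, SilhouetteReport]:
    """Fit k = 2..k_max and keep the k maximizing the mean silhouette.

    Returns a single cluster (k = 1) when fewer than ``min_spikes``
    spikes are available or when the best mean silhouette falls below
    ``sc_floor`` — K-means always produces a partition, so a quality
    floor is needed to recognize a channel that carries one unit only.
    Ties are broken toward the smaller k.
    """
    Xa = _as_array(X)
    n = Xa.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spikes")
    if n < min_spikes:
        report = SilhouetteReport(
            a=np.zeros(n), b=np.zeros(n), s=np.zeros(n),
            mean_sc=float("nan"), chosen_k=1,
        )
        return _single_cluster_model(Xa, seed), report
    candidates: dict[int, tuple[ClusterModel, SilhouetteReport]] = {}
    by_k: dict[int, float] = {}
    for k in range(2, min(k_max, n - 1) + 1):
        model = kmeans_fit(Xa, k, seed=seed, restarts=restarts, max_iter=max_iter)
        rep = mean_silhouette(Xa, model.labels)
        candidates[k] = (model, rep)
        by_k[k] = rep.mean_sc
    if not candidates:
        report = SilhouetteReport(
            a=np.zeros(n), b=np.zeros(n), s=np.zeros(n),
            mean_sc=float("nan"), by_k=by_k, chosen_k=1,
        )
        return _single_cluster_model(Xa, seed), report
    best_k = min(by_k, key=lambda k: (-by_k[k], k))
    if by_k[best_k] < sc_floor:
        report = SilhouetteReport(
            a=np.zeros(n), b=np.zeros(n), s=np.zeros(n),
            mean_sc=by_k[best_k], by_k=by_k, chosen_k=1,
        )
        return _single_cluster_model(Xa, seed), report
    model, rep = candidates[best_k]
    rep.by_k = by_k
    rep.chosen_k = best_k
    return model, rep


def sort_channel(det, cfg: SortingConfig, channel: int = 0) -> UnitLabels:
    """Split one channel's detected spikes into putative single units."""
    indices = np.asarray(det.indices, dtype=np.int64)
    n = len(indices)
    if n == 0:
        return UnitLabels(
            channel=channel, spike_indices=indices,
            labels=np.empty(0, dtype=np.int64), n_units=0,
        )
    if n < 2:
        return UnitLabels(
            channel=channel, spike_indices=indices,
            labels=np.zeros(n, dtype=np.int64), n_units=1,
        )
    feats = wpd_features(
        det.waveforms, depth=cfg.depth, wavelet=cfg.wavelet,
        summaries=not cfg.raw_features,
    )
    if feats.X.shape[1] == 0:
        # all features constant (identical waveforms): one unit
        return UnitLabels(
            channel=channel, spike_indices=indices,
            labels=np.zeros(n, dtype=np.int64), n_units=1,
        )
    model, report = select_k(
        feats, k_max=cfg.k_max, seed=cfg.seed, restarts=cfg.restarts,
        sc_floor=cfg.sc_floor, min_spikes=cfg.min_spikes, max_iter=cfg.max_iter,
    )
    return UnitLabels(
        channel=channel, spike_indices=indices, labels=model.labels,
        n_units=model.k, model=model, report=report,
    )
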