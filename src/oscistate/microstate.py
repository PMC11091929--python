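"""Polarity-invariant modified k-means microstate clustering.

The pipeline's core statistic machinery:

- global field power (GFP): per-sample population standard deviation of
  the signal across sensors; its strict local maxima mark the samples of
  best topographic signal-to-noise, which are the clustering input;
- modified k-means: k-means over topographic maps that ignores map
  polarity, assigning samples by squared cosine similarity and updating
  each centroid as the principal eigenvector of its members' outer-product
  sum (the polarity-invariant analogue of the cluster mean);
- global explained variance (GEV): the fraction of GFP-weighted spatial
  variance of the data explained by its assigned maps, using the standard
  GFP-weighted squared spatial-correlation definition
  ``GEV = sum_t (GFP_t * r_t)**2 / sum_t GFP_t**2`` with ``r_t`` the
  Pearson correlation across channels between sample t and its map.

Clustering is restarted from random initial centroids (default 20
restarts) and the restart with the highest GEV is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SensorRecording

__all__ = [
    "GFPTrace",
    "MicrostateModel",
    "global_field_power",
    "find_gfp_peaks",
    "polarity_invariant_similarity",
    "spatial_correlation",
    "gev",
    "modified_kmeans",
    "extract_peak_maps",
    "fit_microstates",
]


@dataclass
class GFPTrace:
    """Global field power per sample (nonnegative) with its sampling rate."""

    values: np.ndarray
    fs: float


@dataclass
class MicrostateModel:
    """Result of polarity-invariant clustering at subject or group level.

    ``maps`` rows are unit-norm with the largest-magnitude channel
    positive; ``peak_labels`` assigns each clustered sample to a state;
    ``gev`` is the global explained variance of that assignment.  Restart
    provenance (``n_restarts``, ``chosen_restart``, ``restart_gevs``,
    ``seed``) is kept so the selection can be audited.
    """

    maps: np.ndarray
    peak_labels: np.ndarray
    gev: float
    n_restarts: int
    chosen_restart: int
    seed: int
    restart_gevs: np.ndarray | None = None
    n_iter: int = 0

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def _as_data(recording) -> tuple[np.ndarray, float | None]:
    if isinstance(recording, SensorRecording):
        return recording.data, recording.fs
    return np.asarray(recording, dtype=float), None


def global_field_power(recording) -> GFPTrace:
    """GFP trace: population standard deviation across channels per sample."""
    data, fs = _as_data(recording)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("global field power needs at least 2 channels")
    values = data.std(axis=0, ddof=0)
    return GFPTrace(values=values, fs=fs if fs is not None else float("nan"))


def find_gfp_peaks(gfp) -> np.ndarray:
    """Indices of strict local maxima of the GFP trace.

    A peak satisfies ``gfp[t-1] < gfp[t] > gfp[t+1]``; endpoints and
    plateaus are excluded.  Indices are returned in ascending order.
    """
    v = gfp.values if isinstance(gfp, GFPTrace) else np.asarray(gfp, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("peak finding needs a 1-D trace of length >= 3")
    inner = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(inner) + 1


def polarity_invariant_similarity(x: np.ndarray, m: np.ndarray) -> float:
    """Absolute cosine similarity |x.m| / (|x||m|); in [0, 1].

    The clustering distance is one minus this value; a map and its
    polarity-reversed copy are maximally similar.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    nx, nm = np.linalg.norm(x), np.linalg.norm(m)
    if nx == 0 or nm == 0:
        raise ValueError("similarity undefined for a zero vector")
    return float(abs(x @ m) / (nx * nm))


def spatial_correlation(x: np.ndarray, m: np.ndarray) -> float:
    """Pearson correlation across channels (channel-demeaned cosine)."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    xd = x - x.mean()
    md = m - m.mean()
    nx, nm = np.linalg.norm(xd), np.linalg.norm(md)
    if nx == 0 or nm == 0:
        raise ValueError("spatial correlation undefined for a constant vector")
    return float(xd @ md / (nx * nm))


def _demean_normalize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-demean and row-normalize; zero-variance rows become zero rows."""
    d = a - a.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(d, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return d / safe[:, None], norms


def gev(maps: np.ndarray, data: np.ndarray, labels: np.ndarray) -> float:
    """Global explained variance of a labelled sample set.

    ``GEV = sum_t (GFP_t * r_t)**2 / sum_t GFP_t**2`` where ``GFP_t`` is
    the across-channel population standard deviation of sample t and
    ``r_t`` the Pearson spatial correlation between sample t and its
    assigned map.  Samples with zero across-channel variance contribute
    nothing (their GFP is zero).
    """
    maps = np.asarray(maps, dtype=float)
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.shape[0] != labels.shape[0]:
        raise ValueError("one label per sample required")
    if labels.size and (labels.min() < 0 or labels.max() >= maps.shape[0]):
        raise ValueError("labels outside [0, K)")
    gfp = data.std(axis=1, ddof=0)
    den = float(np.sum(gfp**2))
    if den == 0:
        raise ValueError("GEV undefined for all-zero data")
    dn, _ = _demean_normalize(data)
    mn, _ = _demean_normalize(maps)
    r = np.einsum("ij,ij->i", dn, mn[labels])
    return float(np.sum((gfp * r) ** 2) / den)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    s = np.sign(v[np.argmax(np.abs(v))])
    return v * (s if s != 0 else 1.0)


def _principal_map(members: np.ndarray) -> np.ndarray:
    """First right singular vector of the member maps: the polarity-invariant
    centroid (maximizes the summed squared projection)."""
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    return _fix_sign(vt[0])


def modified_kmeans(
    maps: np.ndarray,
    K: int = 4,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    init_maps: np.ndarray | None = None,
) -> MicrostateModel:
    """Polarity-invariant k-means over topographic maps.

    Parameters
    ----------
    maps : ndarray, shape (n_samples, n_channels)
        Input topographies (typically maps at GFP peaks).
    K : int
        Number of microstate classes (default 4).
    n_restarts : int
        Independent random initializations; the restart with the highest
        GEV wins (default 20).
    seed : int
        Seed for the restart initializations.
    max_iter, tol : int, float
        Per-restart iteration cap and minimum GEV improvement.
    init_maps : ndarray, optional
        Explicit initial centroids (K x n_channels); used as a single
        extra warm-started restart in addition to the random ones.

    Each restart initializes centroids as K distinct input maps, then
    alternates (i) assignment of every map to the centroid of highest
    squared cosine similarity and (ii) centroid update to the principal
    eigenvector of the members' outer-product sum, until labels are
    stable or the GEV gain drops below ``tol``.  An emptied cluster is
    re-seeded from the worst-fit map so K never shrinks.
    """
    X = np.asarray(maps, dtype=float)
    if X.ndim != 2:
        raise ValueError("maps must be 2-D (samples x channels)")
    n_samples, n_channels = X.shape
    if K > n_samples:
        raise ValueError(f"K={K} exceeds the {n_samples} available maps")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("input maps contain an all-zero row")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_restarts)

    best: tuple[float, int, np.ndarray, np.ndarray, int] | None = None
    restart_gevs = []

    inits: list[np.ndarray | None] = [None] * n_restarts
    if init_maps is not None:
        inits.append(np.asarray(init_maps, dtype=float))
        children = list(children) + [ss.spawn(1)[0]]

    for r, (child, init) in enumerate(zip(children, inits)):
        rng = np.random.default_rng(child)
        if init is None:
            idx = rng.choice(n_samples, size=K, replace=False)
            C = X[idx] / norms[idx][:, None]
        else:
            cn = np.linalg.norm(init, axis=1)
            if init.shape != (K, n_channels) or np.any(cn == 0):
                raise ValueError("init_maps must be K x n_channels, nonzero rows")
            C = init / cn[:, None]
        C = np.apply_along_axis(_fix_sign, 1, C)

        labels = np.full(n_samples, -1)
        g = -np.inf
        snapshot: tuple[float, np.ndarray, np.ndarray] | None = None
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            A = np.abs(X @ C.T) / norms[:, None]
            new_labels = np.argmax(A, axis=1)

            # empty-cluster rescue: re-seed from the worst-fit maps
            counts = np.bincount(new_labels, minlength=K)
            if np.any(counts == 0):
                fit = A[np.arange(n_samples), new_labels]
                order = np.argsort(fit)
                used = 0
                for k in np.flatnonzero(counts == 0):
                    i = order[used]
                    used += 1
                    C[k] = _fix_sign(X[i] / norms[i])
                    new_labels[i] = k

            for k in range(K):
                members = X[new_labels == k]
                if len(members):
                    C[k] = _principal_map(members)

            new_g = gev(C, X, new_labels)
            if snapshot is None or new_g > snapshot[0]:
                snapshot = (new_g, C.copy(), new_labels.copy())
            if np.array_equal(new_labels, labels) or (new_g - g) < tol:
                labels, g = new_labels, new_g
                break
            labels, g = new_labels, new_g

        g, C, labels = snapshot  # type: ignore[misc]
        restart_gevs.append(g)
        if best is None or g > best[0]:
            best = (g, r, C.copy(), labels.copy(), n_iter)

    g, r, C, labels, n_iter = best  # type: ignore[misc]
    return MicrostateModel(
        maps=C,
        peak_labels=labels,
        gev=float(g),
        n_restarts=len(inits),
        chosen_restart=int(r),
        seed=seed,
        restart_gevs=np.asarray(restart_gevs),
        n_iter=int(n_iter),
    )


def extract_peak_maps(recording: SensorRecording) -> tuple[np.ndarray, np.ndarray]:
    """Topographic maps at the strict local maxima of the GFP.

    Returns (maps, peak_indices) with maps shaped peaks x channels.
    """
    trace = global_field_power(recording)
    peaks = find_gfp_peaks(trace)
    if peaks.size == 0:
        raise ValueError("recording has no GFP peaks")
    return recording.data[:, peaks].T, peaks


def fit_microstates(
    recording: SensorRecording,
    K: int = 4,
    n_restarts: int = 20,
    seed: int = 0,
    **kwargs,
) -> MicrostateModel:
    """Subject-level clustering: GFP peaks -> modified k-means."""
    maps, _ = extract_peak_maps(recording)
    return modified_kmeans(maps, K=K, n_restarts=n_restarts, seed=seed, **kwargs)
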