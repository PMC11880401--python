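"""DTW-metric k-means over chair-rise cycles and internal validation.

Clustering operates on peak-normalized single-cycle series (typically the
first rise of each participant). Lloyd iterations alternate DTW
nearest-barycenter assignment with DBA barycenter refinement; the algorithm
is restarted ``n_init`` times from different seeded centroid draws and the
restart with the lowest inertia is kept. Inertia is the sum of squared DTW
distances of members to their barycenter (the quantity the DBA update
provably does not increase); the summed unsquared DTW objective is exposed
alongside.

Validation follows the usual internal indices, both computed in DTW space:
mean silhouette over a sweep of k (on the full pairwise DTW distance
matrix) and the Davies-Bouldin index with cluster scatter S_i = mean DTW of
members to their barycenter and separation M_ij = DTW between barycenters.

K-means labels are arbitrary; ``canonicalize_labels`` reorders them by
ascending mean stabilization-phase force so that "cluster 1" always denotes
the low-stabilization-force movement pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

from .dtw import (_acc_cost_matrix, _backtrack, _dtw_sqdist, _resample,
                  dba_barycenter, pairwise_distances)

__all__ = [
    "ClusterModel",
    "ValidationScores",
    "fit",
    "assign",
    "silhouette_sweep",
    "davies_bouldin",
    "canonicalize_labels",
]


@dataclass
class ClusterModel:
    k: int
    barycenters: list = field(repr=False)
    n_init: int
    max_iter: int
    seed: int
    inertia: float                 # sum of squared DTW distances (best restart)
    summed_dtw: float              # sum of unsquared DTW distances (best restart)
    labels_: np.ndarray = field(default=None, repr=False)
    inertia_history_: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")


@dataclass(frozen=True)
class ValidationScores:
    silhouette_by_k: dict
    davies_bouldin: float | None = None

    def __post_init__(self):
        for k, s in self.silhouette_by_k.items():
            if not -1.0 <= s <= 1.0:
                raise ValueError(f"silhouette for k={k} outside [-1, 1]")
        if self.davies_bouldin is not None and self.davies_bouldin < 0:
            raise ValueError("Davies-Bouldin index must be non-negative")

    @property
    def best_k(self) -> int:
        return max(self.silhouette_by_k, key=self.silhouette_by_k.get)


def _as_series_list(dataset):
    out = [np.ascontiguousarray(np.asarray(s, dtype=np.float64)) for s in dataset]
    if any(s.ndim != 1 or s.size == 0 for s in out):
        raise ValueError("dataset must contain non-empty 1-D series")
    return out


def _dists_to_barycenters(series, barycenters):
    d = np.empty((len(series), len(barycenters)))
    for j, b in enumerate(barycenters):
        for i, s in enumerate(series):
            d[i, j] = _dtw_sqdist(s, b)
    return d  # squared DTW


def _dba_update(members, init, max_iter, tol=1e-6):
    mu = init.copy()
    prev = np.inf
    for _ in range(max_iter):
        sums = np.zeros_like(mu)
        counts = np.zeros(mu.shape[0])
        obj = 0.0
        for s in members:
            acc = _acc_cost_matrix(mu, s)
            obj += acc[-1, -1]
            pi = _backtrack(acc)
            np.add.at(sums, pi[:, 0], s[pi[:, 1]])
            np.add.at(counts, pi[:, 0], 1.0)
        mu = sums / counts
        if prev - obj <= tol * max(prev, 1e-12):
            break
        prev = obj
    return mu


def _update_barycenter(members, previous, dba_max_iter):
    """Best-of-candidates barycenter update for one cluster.

    Runs DBA twice - warm-started from the previous barycenter (resampled to
    the current median member length) and freshly initialized from the DTW
    medoid - and keeps whichever candidate, including the unchanged previous
    barycenter, has the lowest summed squared DTW to the members. Keeping
    the previous barycenter as a candidate makes the Lloyd inertia provably
    non-increasing; the medoid restart lets the barycenter length and shape
    track the cluster as memberships move, which warm-starting alone cannot
    (DBA never changes the barycenter's length).
    """
    length = int(np.median([s.shape[0] for s in members]))
    candidates = [previous,
                  _dba_update(members, _resample(previous, length), dba_max_iter),
                  dba_barycenter(members, max_iter=dba_max_iter)]
    scores = [sum(_dtw_sqdist(s, b) for s in members) for b in candidates]
    return candidates[int(np.argmin(scores))]


def fit(dataset, k: int, n_init: int = 10, max_iter: int = 100,
        seed: int = 0, dba_max_iter: int = 10) -> ClusterModel:
    """DTW/DBA k-means, best of ``n_init`` seeded restarts by inertia.

    Each restart initializes the barycenters as ``k`` distinct members drawn
    without replacement from its own seed substream, then alternates DTW
    assignment (ties to the lowest label) and DBA barycenter updates until
    the labels stabilize or ``max_iter`` is reached. Empty clusters are
    reseeded with the member farthest from its current barycenter.
    """
    series = _as_series_list(dataset)
    n = len(series)
    if n < k:
        raise ValueError(f"dataset of size {n} cannot support k={k}")
    if k > 1 and all(np.array_equal(series[0], s) for s in series[1:]):
        warnings.warn("all series identical: clusters are degenerate")

    best = None
    streams = np.random.SeedSequence(seed).spawn(n_init)
    for stream in streams:
        rng = np.random.default_rng(stream)
        barycenters = [series[i].copy() for i in rng.choice(n, size=k, replace=False)]
        labels = np.full(n, -1)
        history = []
        for _ in range(max_iter):
            d = _dists_to_barycenters(series, barycenters)
            new_labels = np.argmin(d, axis=1)
            # reseed empty clusters with the farthest member
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(np.argmax(d[np.arange(n), new_labels]))
                    barycenters[c] = series[far].copy()
                    d[:, c] = [_dtw_sqdist(s, barycenters[c]) for s in series]
                    new_labels = np.argmin(d, axis=1)
            history.append(float(d[np.arange(n), new_labels].sum()))
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            for c in range(k):
                members = [series[i] for i in np.where(labels == c)[0]]
                if members:     # degenerate data can leave a cluster empty
                    barycenters[c] = _update_barycenter(members, barycenters[c],
                                                        dba_max_iter)
        d = _dists_to_barycenters(series, barycenters)
        sq = d[np.arange(n), labels]
        inertia = float(sq.sum())
        if best is None or inertia < best.inertia:
            best = ClusterModel(k=k, barycenters=barycenters, n_init=n_init,
                                max_iter=max_iter, seed=seed, inertia=inertia,
                                summed_dtw=float(np.sqrt(sq).sum()),
                                labels_=labels.copy(),
                                inertia_history_=np.asarray(history))
    return best


def assign(model: ClusterModel, series) -> int:
    """Label of the DTW-nearest barycenter (deterministic, ties lowest)."""
    if not model.barycenters:
        raise ValueError("model has no barycenters")
    s = np.ascontiguousarray(np.asarray(series, dtype=np.float64))
    d = [_dtw_sqdist(s, b) for b in model.barycenters]
    return int(np.argmin(d))


def silhouette_sweep(dataset, k_range=range(2, 11), seed: int = 0,
                     n_init: int = 10, max_iter: int = 100,
                     dba_max_iter: int = 10,
                     distance_matrix: np.ndarray | None = None) -> ValidationScores:
    """Mean silhouette of a fresh k-means fit for each k in ``k_range``.

    Silhouettes are computed on the full precomputed pairwise DTW distance
    matrix. k values exceeding the dataset size are skipped with a warning.
    """
    series = _as_series_list(dataset)
    if distance_matrix is None:
        distance_matrix = pairwise_distances(series)
    scores = {}
    streams = np.random.SeedSequence(seed).spawn(len(list(k_range)))
    for stream, k in zip(streams, k_range):
        if k > len(series):
            warnings.warn(f"k={k} exceeds dataset size; skipped")
            continue
        model = fit(series, k, n_init=n_init, max_iter=max_iter,
                    seed=int(stream.generate_state(1)[0] % (2**31)),
                    dba_max_iter=dba_max_iter)
        if len(np.unique(model.labels_)) < 2:
            warnings.warn(f"k={k} collapsed to a single cluster; skipped")
            continue
        scores[k] = float(silhouette_score(distance_matrix, model.labels_,
                                           metric="precomputed"))
    return ValidationScores(silhouette_by_k=scores)


def davies_bouldin(dataset, labels, model: ClusterModel) -> float:
    """Davies-Bouldin index in DTW space: mean over clusters of
    max_j (S_i + S_j) / M_ij."""
    series = _as_series_list(dataset)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if ks.size < 2:
        raise ValueError("need at least two non-empty clusters")
    S, cent = [], []
    for c in ks:
        members = [series[i] for i in np.where(labels == c)[0]]
        if not members:
            raise ValueError(f"cluster {c} is empty")
        b = model.barycenters[int(c)]
        S.append(np.mean([np.sqrt(_dtw_sqdist(s, b)) for s in members]))
        cent.append(b)
    db = 0.0
    for i in range(ks.size):
        ratios = [(S[i] + S[j]) / np.sqrt(_dtw_sqdist(cent[i], cent[j]))
                  for j in range(ks.size) if j != i]
        db += max(ratios)
    return float(db / ks.size)


def canonicalize_labels(labels, order_values):
    """Relabel clusters by ascending mean of ``order_values``.

    ``order_values`` carries one scalar per sample (e.g. the
    stabilization-phase force of that participant's first cycle); cluster 0
    after canonicalization is the one with the lowest mean value. Returns
    ``(new_labels, mapping)`` with ``mapping[old] = new``.
    """
    labels = np.asarray(labels)
    values = np.asarray(order_values, dtype=float)
    if labels.shape != values.shape:
        raise ValueError("labels and order_values must align")
    ks = np.unique(labels)
    means = {c: values[labels == c].mean() for c in ks}
    mapping = {int(c): rank for rank, c in
               enumerate(sorted(ks, key=lambda c: means[c]))}
    return np.array([mapping[int(l)] for l in labels]), mapping
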