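"""Dynamic time warping, DBA barycenter averaging and soft-DTW.

This is the metric core of the package. DTW aligns two univariate series of
possibly different lengths by a monotone warp path and scores the alignment as

    DTW(x, y) = sqrt( min_pi sum_{(i,j) in pi} (x_i - y_j)^2 )

i.e. squared differences accumulate along the path and a single square root is
taken at the end. The DBA barycenter of a set ``D`` minimizes the summed DTW
cost to all members by iterative align-and-average refinement; soft-DTW
replaces the hard ``min`` in the recursion by a soft minimum with temperature
``gamma`` and yields a differentiable cost whose barycenter can be found by
gradient descent.

The dynamic programs are compiled with numba; all entry points accept plain
sequences and return numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

__all__ = [
    "WarpPath",
    "DtwResult",
    "cross_similarity",
    "dtw_distance",
    "pairwise_distances",
    "dba_barycenter",
    "softdtw_cost",
    "softdtw_barycenter",
]


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _acc_cost_matrix(x, y):
    """Accumulated-cost DP matrix with squared inner cost."""
    m, n = x.shape[0], y.shape[0]
    acc = np.empty((m, n))
    acc[0, 0] = (x[0] - y[0]) ** 2
    for i in range(1, m):
        acc[i, 0] = acc[i - 1, 0] + (x[i] - y[0]) ** 2
    for j in range(1, n):
        acc[0, j] = acc[0, j - 1] + (x[0] - y[j]) ** 2
    for i in range(1, m):
        for j in range(1, n):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + (x[i] - y[j]) ** 2
    return acc


@njit(cache=True)
def _dtw_sqdist(x, y):
    """Squared DTW cost only, two-row rolling DP (no path)."""
    m, n = x.shape[0], y.shape[0]
    prev = np.empty(n)
    cur = np.empty(n)
    prev[0] = (x[0] - y[0]) ** 2
    for j in range(1, n):
        prev[j] = prev[j - 1] + (x[0] - y[j]) ** 2
    for i in range(1, m):
        cur[0] = prev[0] + (x[i] - y[0]) ** 2
        for j in range(1, n):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + (x[i] - y[j]) ** 2
        prev, cur = cur, prev
    return prev[n - 1]


@njit(cache=True)
def _backtrack(acc):
    """Optimal path from an accumulated-cost matrix.

    Ties are broken in fixed order diagonal > vertical > horizontal so paths
    are bit-reproducible.
    """
    m, n = acc.shape
    # worst-case path length m + n - 1
    pi = np.empty((m + n - 1, 2), dtype=np.int64)
    k = m + n - 2
    i, j = m - 1, n - 1
    pi[k, 0] = i
    pi[k, 1] = j
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            d = acc[i - 1, j - 1]
            v = acc[i - 1, j]
            h = acc[i, j - 1]
            if d <= v and d <= h:
                i -= 1
                j -= 1
            elif v <= h:
                i -= 1
            else:
                j -= 1
        k -= 1
        pi[k, 0] = i
        pi[k, 1] = j
    return pi[k:]


@njit(cache=True)
def _softmin3(a, b, c, gamma):
    lo = min(a, min(b, c))
    s = np.exp(-(a - lo) / gamma) + np.exp(-(b - lo) / gamma) + np.exp(-(c - lo) / gamma)
    return lo - gamma * np.log(s)


@njit(cache=True)
def _softdtw_forward(x, y, gamma):
    m, n = x.shape[0], y.shape[0]
    big = np.inf
    r = np.full((m + 2, n + 2), big)
    r[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d = (x[i - 1] - y[j - 1]) ** 2
            r[i, j] = d + _softmin3(r[i - 1, j], r[i - 1, j - 1], r[i, j - 1], gamma)
    return r


@njit(cache=True)
def _softdtw_grad(x, y, gamma):
    """Gradient of soft-DTW cost w.r.t. x (Cuturi & Blondel backward pass)."""
    m, n = x.shape[0], y.shape[0]
    r = _softdtw_forward(x, y, gamma)
    e = np.zeros((m + 2, n + 2))
    e[m + 1, n + 1] = 1.0
    r[m + 1, n + 1] = r[m, n]
    for i in range(m + 1):
        r[i, n + 1] = -np.inf
    for j in range(n + 1):
        r[m + 1, j] = -np.inf
    for j in range(n, 0, -1):
        for i in range(m, 0, -1):
            d_right = (x[i] - y[j - 1]) ** 2 if i < m else 0.0
            d_up = (x[i - 1] - y[j]) ** 2 if j < n else 0.0
            d_diag = (x[i] - y[j]) ** 2 if (i < m and j < n) else 0.0
            a = np.exp((r[i + 1, j] - r[i, j] - d_right) / gamma) if r[i + 1, j] != -np.inf else 0.0
            b = np.exp((r[i, j + 1] - r[i, j] - d_up) / gamma) if r[i, j + 1] != -np.inf else 0.0
            c = np.exp((r[i + 1, j + 1] - r[i, j] - d_diag) / gamma) if r[i + 1, j + 1] != -np.inf else 0.0
            e[i, j] = a * e[i + 1, j] + b * e[i, j + 1] + c * e[i + 1, j + 1]
    g = np.zeros(m)
    for i in range(1, m + 1):
        acc = 0.0
        for j in range(1, n + 1):
            acc += e[i, j] * 2.0 * (x[i - 1] - y[j - 1])
        g[i - 1] = acc
    return r[m, n], g


# ---------------------------------------------------------------------------
# public api
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpPath:
    """Monotone alignment between two series.

    ``pairs`` is a (K, 2) integer array; the first pair is (0, 0), the last
    (M-1, N-1), and successive pairs differ by a step in {(1,0),(0,1),(1,1)}.
    """

    pairs: np.ndarray

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class DtwResult:
    distance: float
    path: WarpPath
    acc_cost: np.ndarray | None = field(default=None, repr=False)


def _as1d(x, name="series"):
    a = np.ascontiguousarray(np.asarray(x, dtype=np.float64))
    if a.ndim != 1 or a.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def cross_similarity(x, y) -> np.ndarray:
    """M x N matrix of squared pointwise differences (x_i - y_j)^2."""
    x, y = _as1d(x, "x"), _as1d(y, "y")
    return (x[:, None] - y[None, :]) ** 2


def dtw_distance(x, y, return_cost_matrix: bool = False) -> DtwResult:
    """Exact DTW distance with optimal path recovery.

    Lengths may differ; no band constraint is applied. The distance is zero
    exactly when ``x`` and ``y`` are identical.
    """
    x, y = _as1d(x, "x"), _as1d(y, "y")
    acc = _acc_cost_matrix(x, y)
    path = WarpPath(_backtrack(acc))
    dist = float(np.sqrt(acc[-1, -1]))
    return DtwResult(dist, path, acc if return_cost_matrix else None)


def dtw_sqdist(x, y) -> float:
    """Squared DTW cost without path recovery (fast inner loop)."""
    return float(_dtw_sqdist(_as1d(x, "x"), _as1d(y, "y")))


def pairwise_distances(dataset) -> np.ndarray:
    """Symmetric matrix of DTW distances between all pairs in ``dataset``."""
    series = [_as1d(s) for s in dataset]
    n = len(series)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = np.sqrt(_dtw_sqdist(series[i], series[j]))
    return out


def _resample(series: np.ndarray, length: int) -> np.ndarray:
    if series.shape[0] == length:
        return series.copy()
    old = np.linspace(0.0, 1.0, series.shape[0])
    new = np.linspace(0.0, 1.0, length)
    return np.interp(new, old, series)


def dtw_medoid_index(dataset) -> int:
    """Index of the member minimizing summed DTW distance to all others."""
    d = pairwise_distances(dataset)
    return int(np.argmin(d.sum(axis=1)))


def dba_barycenter(
    dataset,
    init=None,
    max_iter: int = 30,
    tol: float = 1e-6,
    return_history: bool = False,
):
    """DBA barycenter of a set of series.

    Each iteration aligns every member to the current barycenter by exact DTW
    and replaces each barycenter sample by the mean of all member samples
    aligned to it; this provably does not increase the summed *squared* DTW
    objective, which is tracked as the convergence criterion (relative change
    below ``tol`` stops early).

    When ``init`` is None the barycenter is initialized as the DTW medoid of
    the set, linearly resampled to the median member length.
    """
    series = [_as1d(s) for s in dataset]
    if len(series) == 0:
        raise ValueError("dataset must contain at least one series")
    if init is None:
        length = int(np.median([s.shape[0] for s in series]))
        mu = _resample(series[dtw_medoid_index(series)], length)
    else:
        mu = _as1d(init, "init").copy()
    history = []
    for _ in range(max_iter):
        sums = np.zeros_like(mu)
        counts = np.zeros(mu.shape[0])
        obj = 0.0
        for s in series:
            acc = _acc_cost_matrix(mu, s)
            obj += acc[-1, -1]
            pi = _backtrack(acc)
            np.add.at(sums, pi[:, 0], s[pi[:, 1]])
            np.add.at(counts, pi[:, 0], 1.0)
        history.append(obj)
        mu_new = sums / counts
        if len(history) >= 2 and history[-2] - history[-1] <= tol * max(history[-2], 1e-12):
            mu = mu_new
            break
        mu = mu_new
    if return_history:
        return mu, np.asarray(history)
    return mu


def softdtw_cost(x, y, gamma: float = 1.0) -> float:
    """Soft-DTW cost; converges to the squared DTW cost as gamma -> 0."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x, y = _as1d(x, "x"), _as1d(y, "y")
    return float(_softdtw_forward(x, y, gamma)[x.shape[0], y.shape[0]])


def softdtw_barycenter(dataset, gamma: float = 1.0, max_iter: int = 30, init=None):
    """Barycenter under the soft-DTW cost, found by L-BFGS-B.

    Initialized at the pointwise mean of members resampled to the median
    length. Used for smooth barycenter visualization; clustering itself uses
    hard DTW/DBA.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    series = [_as1d(s) for s in dataset]
    if len(series) == 0:
        raise ValueError("dataset must contain at least one series")
    length = int(np.median([s.shape[0] for s in series]))
    if init is None:
        mu0 = np.mean([_resample(s, length) for s in series], axis=0)
    else:
        mu0 = _as1d(init, "init").copy()

    def fg(mu):
        total, grad = 0.0, np.zeros_like(mu)
        for s in series:
            c, g = _softdtw_grad(np.ascontiguousarray(mu), s, gamma)
            total += c
            grad += g
        return total, grad

    res = minimize(fg, mu0, jac=True, method="L-BFGS-B", options={"maxiter": max_iter})
    return res.x
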