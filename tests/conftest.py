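import numpy as np
import pytest

from crt_cluster import CohortConfig, synth_cohort
from crt_cluster.synthetic import default_archetypes


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def noise_free_cfg():
    return CohortConfig(n_per_archetype=(1, 1), noise_sd=0.0,
                        within_participant_sd_scale=0.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """24-participant noisy cohort shared across segmentation/pipeline tests."""
    return synth_cohort(CohortConfig(n_per_archetype=(10, 14), seed=42))


def brute_force_dtw(x, y):
    """Independent oracle: recursive minimum over every admissible warp path.

    Enumerates paths explicitly (no DP/memoization), so it is only usable for
    small grids; squared pointwise cost, single final square root.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    best = [np.inf]

    def rec(i, j, cost):
        cost += (x[i] - y[j]) ** 2
        if cost >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = cost
            return
        if i + 1 < m and j + 1 < n:
            rec(i + 1, j + 1, cost)
        if i + 1 < m:
            rec(i + 1, j, cost)
        if j + 1 < n:
            rec(i, j + 1, cost)

    rec(0, 0, 0.0)
    return float(np.sqrt(best[0]))
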