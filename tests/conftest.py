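"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's step-function machinery: K
values are obtained by brute-force pair counting, and integrals by a
left-endpoint Riemann sum on a dense lattice unioned with the CDF jump
points (a step function is constant between consecutive grid points, so the
sum is exact while remaining an independent pointwise-evaluation route).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kshuff.matrix_io import DistanceMatrix, LibraryPartition

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """A valid random matrix with distances in (0, 1)."""
    d = rng.uniform(0.01, 0.99, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = tuple(f"s{i}" for i in range(n))
    return DistanceMatrix(labels, d)


def split_partition(m: DistanceMatrix, n_a: int) -> LibraryPartition:
    return LibraryPartition((("A", m.labels[:n_a]), ("B", m.labels[n_a:])))


# ---------------------------------------------------------------------------
# Brute-force K evaluation (oracle)


def brute_intra_k(m: DistanceMatrix, members, r) -> np.ndarray:
    """K(r) by exhaustive enumeration of ordered within-library pairs."""
    idx = [m.labels.index(x) for x in members]
    vals = []
    r = np.atleast_1d(r)
    for rv in r:
        count = sum(
            m.d[i, j] <= rv for i in idx for j in idx if i != j
        )
        vals.append(count / (len(idx) * (len(idx) - 1)))
    return np.array(vals)


def brute_cross_k(m: DistanceMatrix, mem_a, mem_b, r) -> np.ndarray:
    ia = [m.labels.index(x) for x in mem_a]
    ib = [m.labels.index(x) for x in mem_b]
    vals = []
    for rv in np.atleast_1d(r):
        count = sum(m.d[i, j] <= rv for i in ia for j in ib)
        vals.append(count / (len(ia) * len(ib)))
    return np.array(vals)


def dense_grid(breakpoint_sets, r_max: float = 1.0, step: float = 1e-5) -> np.ndarray:
    """1e-5 lattice on [0, r_max) unioned with all CDF jump points."""
    lattice = np.arange(0.0, r_max, step)
    pts = np.unique(np.concatenate([lattice, *map(np.asarray, breakpoint_sets)]))
    return pts[pts < r_max]


def riemann(values: np.ndarray, pts: np.ndarray, r_max: float = 1.0) -> float:
    """Left-endpoint Riemann sum of a piecewise-constant function."""
    widths = np.diff(np.append(pts, r_max))
    return float(np.sum(values * widths))


def counting_cdf(distances: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Empirical CDF at each grid point by direct counting (vectorized but
    not via the package's searchsorted/step machinery)."""
    d = np.asarray(distances, dtype=float)
    return (d[None, :] <= pts[:, None]).mean(axis=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20161202)
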