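"""Empirical K-functions and the scalar diversity indices I_kf and C_kf.

The intra K-function (IKF) of a library is the empirical CDF of the
evolutionary distances among all ordered pairs of its members; the cross
K-function (CKF) of two libraries is the empirical CDF of distances between
pairs drawn one from each.  Both are right-continuous step functions.  The
structural index I_kf is the area *above* the IKF on [0, r_max] (with the
default r_max = 1 this is exactly the mean within-library pairwise distance);
the compositional index C_kf is the summed absolute area between the CKF and
each of the two IKFs.  All integrals are computed exactly on the step
representation — K is piecewise constant, so quadrature is never needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .matrix_io import DistanceMatrix, LibraryPartition, PartitionError

__all__ = [
    "StepCDF",
    "StructuralIndex",
    "CompositionIndex",
    "UndefinedIKFError",
    "intra_k",
    "cross_k",
    "ikf_index",
    "ckf_index",
    "all_indices",
    "step_cdf_from_distances",
]

DEFAULT_R_MAX = 1.0


class UndefinedIKFError(ValueError):
    """IKF requested for a library with fewer than two members."""


@dataclass(frozen=True)
class StepCDF:
    """A right-continuous empirical CDF over distances.

    ``values[k]`` is K(r) for ``breakpoints[k] <= r < breakpoints[k+1]``;
    K(r) = 0 below the first breakpoint and 1 at and after the last.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    n_pairs: int
    domain_max: float = DEFAULT_R_MAX

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if b.ndim != 1 or v.shape != b.shape:
            raise ValueError("breakpoints and values must be 1-D and congruent")
        if b.size == 0:
            raise ValueError("empty CDF")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(np.diff(v) < 0) or v[0] < 0 or abs(v[-1] - 1.0) > 1e-9:
            raise ValueError("values must be nondecreasing in [0, 1] ending at 1")
        b.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "breakpoints", b)
        object.__setattr__(self, "values", v)

    def __call__(self, r: float | np.ndarray) -> np.ndarray:
        """Evaluate K(r) (right-continuous, '<= r' convention)."""
        idx = np.searchsorted(self.breakpoints, r, side="right")
        return np.concatenate([[0.0], self.values])[idx]

    def integral(self, r_max: float | None = None) -> float:
        """Exact integral of K over [0, r_max] from the step representation."""
        r_max = self.domain_max if r_max is None else r_max
        b, v = self.breakpoints, self.values
        inside = b < r_max
        edges = np.append(b[inside], r_max)
        return float(np.sum(v[inside] * np.diff(edges)))


def step_cdf_from_distances(
    distances: np.ndarray, n_pairs: int, domain_max: float = DEFAULT_R_MAX
) -> StepCDF:
    """Build a StepCDF from a flat array of pair distances.

    ``distances`` may carry each unordered pair once; the double-counting of
    ordered pairs cancels in the CDF.  ``n_pairs`` records the ordered-pair
    normalization for bookkeeping.
    """
    d = np.sort(np.asarray(distances, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("no pair distances")
    breaks, counts = np.unique(d, return_counts=True)
    values = np.cumsum(counts) / d.size
    return StepCDF(breaks, values, n_pairs=n_pairs, domain_max=domain_max)


@dataclass(frozen=True)
class StructuralIndex:
    """I_kf of one library: area above its IKF, i.e. structural diversity."""

    library: str
    ikf: float


@dataclass(frozen=True)
class CompositionIndex:
    """C_kf of one library pair: summed |CKF - IKF| areas (symmetric)."""

    pair: tuple[str, str]
    ckf: float


# ---------------------------------------------------------------------------


def intra_distances(m: DistanceMatrix, members: Sequence[str]) -> np.ndarray:
    """Within-library distances, each unordered pair once."""
    sub = m.submatrix(members)
    iu = np.triu_indices(len(members), k=1)
    return sub[iu]


def cross_distances(
    m: DistanceMatrix, members_a: Sequence[str], members_b: Sequence[str]
) -> np.ndarray:
    ia, ib = m.index(members_a), m.index(members_b)
    return m.d[np.ix_(ia, ib)].ravel()


def intra_k(
    m: DistanceMatrix, members: Sequence[str], r_max: float = DEFAULT_R_MAX
) -> StepCDF:
    """Intra K-function: empirical CDF of distances within one library.

    K(r) = (1 / n(n-1)) * sum over ordered pairs i != j of 1[d_ij <= r].
    """
    n = len(members)
    if n < 2:
        raise UndefinedIKFError(
            f"IKF undefined for a library of {n} sequence(s); need >= 2"
        )
    return step_cdf_from_distances(
        intra_distances(m, members), n_pairs=n * (n - 1), domain_max=r_max
    )


def cross_k(
    m: DistanceMatrix,
    members_a: Sequence[str],
    members_b: Sequence[str],
    r_max: float = DEFAULT_R_MAX,
) -> StepCDF:
    """Cross K-function: empirical CDF of between-library pair distances."""
    if not members_a or not members_b:
        raise ValueError("both libraries must be non-empty")
    if set(members_a) & set(members_b):
        raise PartitionError("libraries overlap; partition must be disjoint")
    return step_cdf_from_distances(
        cross_distances(m, members_a, members_b),
        n_pairs=len(members_a) * len(members_b),
        domain_max=r_max,
    )


def _check_domain(k: StepCDF, r_max: float) -> None:
    if k.breakpoints[-1] > r_max + 1e-12:
        raise ValueError(
            f"distance {k.breakpoints[-1]:.6g} exceeds r_max={r_max:g}; "
            "set rmax to at least the largest distance in the matrix"
        )


def ikf_index(k: StepCDF, r_max: float = DEFAULT_R_MAX) -> float:
    """I_kf = r_max - integral of K over [0, r_max] (area above the CDF).

    With r_max = 1 and distances in [0, 1] this equals the mean distance over
    all ordered within-library pairs, which is the primary correctness oracle.
    """
    _check_domain(k, r_max)
    return r_max - k.integral(r_max)


def merged_grid(cdfs: Iterable[StepCDF], r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Common evaluation grid for exact step-function integration.

    Returns (points, widths): every CDF is constant on
    [points[k], points[k] + widths[k]), and the intervals tile [0, r_max].
    """
    pts = np.unique(np.concatenate([[0.0], *[c.breakpoints for c in cdfs]]))
    pts = pts[pts < r_max]
    widths = np.diff(np.append(pts, r_max))
    return pts, widths


def ckf_index(
    k_ab: StepCDF, k_a: StepCDF, k_b: StepCDF, r_max: float = DEFAULT_R_MAX
) -> float:
    """C_kf = integral |K_ab - K_a| + integral |K_ab - K_b| over [0, r_max]."""
    for k in (k_ab, k_a, k_b):
        _check_domain(k, r_max)
    pts, widths = merged_grid((k_ab, k_a, k_b), r_max)
    vab, va, vb = k_ab(pts), k_a(pts), k_b(pts)
    return float(np.sum((np.abs(vab - va) + np.abs(vab - vb)) * widths))


def all_indices(
    m: DistanceMatrix, p: LibraryPartition, r_max: float = DEFAULT_R_MAX
) -> tuple[list[StructuralIndex], list[CompositionIndex]]:
    """Per-library I_kf and per-pair C_kf for a full partition.

    Returns L structural indices (partition order) and L(L-1)/2 composition
    indices (pairs in partition order).
    """
    if m.d.size and m.d.max() > r_max + 1e-12:
        raise ValueError(
            f"matrix contains distance {m.d.max():.6g} > r_max={r_max:g}; "
            "override rmax (note I_kf then no longer equals the mean distance)"
        )
    ikfs = {
        name: intra_k(m, mem, r_max) for name, mem in p.libraries
    }
    structural = [
        StructuralIndex(name, ikf_index(ikfs[name], r_max)) for name in p.names
    ]
    compositional = []
    for a, b in p.pairs():
        kab = cross_k(m, p.members(a), p.members(b), r_max)
        compositional.append(
            CompositionIndex((a, b), ckf_index(kab, ikfs[a], ikfs[b], r_max))
        )
    return structural, compositional
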