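"""Test statistics and Monte Carlo permutation p-values.

Two functional-ANOVA-style statistics are computed on the step CDFs:

* ``T_l`` (structural homogeneity): sum over libraries of
  ``n_l * integral (K_l - Kbar)^2``, where ``Kbar`` is the library-size
  weighted mean of the intra K-functions.  Large when library structures
  differ.  Computed globally over all L libraries and, restricted to L = 2,
  per pair.
* ``T_c`` (compositional identity, per pair): ``integral (K_ab - Kbar_ab)^2``
  where ``Kbar_ab`` is the size-weighted mean of the two intra K-functions.
  Large when the cross CDF departs from the within-library CDFs.

Null distributions are built by shuffling sequences across libraries with
library sizes preserved; because the pairwise distances are fixed, every
shuffle reuses the one distance matrix.  The p-value uses the add-the-observed
correction ``p = (1 + #{T* >= T_obs}) / (B + 1)``, which is bounded below by
``1/(B+1)`` and can never be zero.  Pairwise tests shuffle only the two
libraries' pooled members, so each pairwise p-value is self-contained; the
global structural test shuffles across all libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import false_discovery_control

from .kcore import (
    DEFAULT_R_MAX,
    StepCDF,
    StructuralIndex,
    CompositionIndex,
    all_indices,
    merged_grid,
)
from .matrix_io import DistanceMatrix, LibraryPartition, RunConfig

__all__ = [
    "TestStatistics",
    "PermutationResult",
    "KShuffResult",
    "t_structure",
    "t_composition",
    "permutation_test",
    "compare_all",
    "adjust_pairwise",
]


@dataclass(frozen=True)
class TestStatistics:
    """Observed statistics for one partition."""

    t_l: float
    pairwise_t_l: dict[tuple[str, str], float]
    pairwise_t_c: dict[tuple[str, str], float]
    kbar: StepCDF


@dataclass(frozen=True)
class PermutationResult:
    observed: TestStatistics
    b: int
    p_structure_global: float | None
    p_structure_pairwise: dict[tuple[str, str], float]
    p_composition_pairwise: dict[tuple[str, str], float]
    seed: int | None


@dataclass(frozen=True)
class KShuffResult:
    """Full report: indices, statistics and permutation p-values."""

    partition: LibraryPartition
    structural: list[StructuralIndex]
    compositional: list[CompositionIndex]
    permutation: PermutationResult
    r_max: float
    alpha: float

    def ckf(self, a: str, b: str) -> float:
        for ci in self.compositional:
            if set(ci.pair) == {a, b}:
                return ci.ckf
        raise KeyError((a, b))


# ---------------------------------------------------------------------------
# Statistics on StepCDFs (public API)


def t_structure(
    ikfs: Sequence[StepCDF],
    sizes: Sequence[int],
    r_max: float = DEFAULT_R_MAX,
) -> float:
    """Structural homogeneity statistic over L >= 2 libraries.

    T_l = sum_l n_l * integral_0^r_max [K_l(r) - Kbar(r)]^2 dr with
    Kbar = sum_l n_l K_l / N.  Exact on the merged breakpoint grid.
    """
    if len(ikfs) < 2:
        raise ValueError("need at least two libraries")
    if len(ikfs) != len(sizes):
        raise ValueError("one size per CDF required")
    n = np.asarray(sizes, dtype=float)
    pts, widths = merged_grid(ikfs, r_max)
    vals = np.stack([k(pts) for k in ikfs])  # (L, G)
    kbar = n @ vals / n.sum()
    return float(np.sum(n[:, None] * (vals - kbar) ** 2 @ widths))


def t_composition(
    k_ab: StepCDF,
    k_a: StepCDF,
    k_b: StepCDF,
    n_a: int,
    n_b: int,
    r_max: float = DEFAULT_R_MAX,
) -> float:
    """Compositional statistic: squared distance of the CKF from the
    size-weighted IKF average, integrated exactly over [0, r_max]."""
    pts, widths = merged_grid((k_ab, k_a, k_b), r_max)
    kbar = (n_a * k_a(pts) + n_b * k_b(pts)) / (n_a + n_b)
    return float(np.sum((k_ab(pts) - kbar) ** 2 * widths))


def weighted_mean_cdf(
    ikfs: Sequence[StepCDF], sizes: Sequence[int], r_max: float = DEFAULT_R_MAX
) -> StepCDF:
    """The size-weighted average of intra K-functions, as a StepCDF."""
    n = np.asarray(sizes, dtype=float)
    pts = np.unique(np.concatenate([k.breakpoints for k in ikfs]))
    vals = n @ np.stack([k(pts) for k in ikfs]) / n.sum()
    return StepCDF(pts, vals, n_pairs=int(sum(k.n_pairs for k in ikfs)), domain_max=r_max)


# ---------------------------------------------------------------------------
# Fast internals on index arrays (used by the permutation loops)


def _grid_widths(dsub: np.ndarray, r_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation grid from a pooled submatrix's off-diagonal distances.

    Every shuffle of the pooled members yields CDFs whose breakpoints are a
    subset of these values, so the grid is computed once per pool.
    """
    iu = np.triu_indices(dsub.shape[0], k=1)
    pts = np.unique(np.concatenate([[0.0], dsub[iu]]))
    pts = pts[pts < r_max]
    widths = np.diff(np.append(pts, r_max))
    return pts, widths


def _cdf_on_grid(distances: np.ndarray, pts: np.ndarray) -> np.ndarray:
    d = np.sort(distances)
    return np.searchsorted(d, pts, side="right") / d.size


def _intra_vals(dsub: np.ndarray, idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    block = dsub[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return _cdf_on_grid(block[iu], pts)


def _pair_stats(
    dsub: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    pts: np.ndarray,
    widths: np.ndarray,
) -> tuple[float, float]:
    """(pairwise T_l, T_c) for one split of a pooled submatrix."""
    na, nb = idx_a.size, idx_b.size
    ka = _intra_vals(dsub, idx_a, pts)
    kb = _intra_vals(dsub, idx_b, pts)
    kab = _cdf_on_grid(dsub[np.ix_(idx_a, idx_b)].ravel(), pts)
    kbar = (na * ka + nb * kb) / (na + nb)
    t_l = na * np.sum((ka - kbar) ** 2 * widths) + nb * np.sum((kb - kbar) ** 2 * widths)
    t_c = np.sum((kab - kbar) ** 2 * widths)
    return float(t_l), float(t_c)


def _global_t_l(
    dsub: np.ndarray,
    splits: Sequence[np.ndarray],
    pts: np.ndarray,
    widths: np.ndarray,
) -> float:
    n = np.array([s.size for s in splits], dtype=float)
    vals = np.stack([_intra_vals(dsub, s, pts) for s in splits])
    kbar = n @ vals / n.sum()
    return float(np.sum(n[:, None] * (vals - kbar) ** 2 @ widths))


def _split_sizes(perm: np.ndarray, sizes: Sequence[int]) -> list[np.ndarray]:
    out, start = [], 0
    for s in sizes:
        out.append(perm[start : start + s])
        start += s
    return out


def _mc_p(count_ge: int, b: int) -> float:
    return (1 + count_ge) / (b + 1)


def pair_permutation(
    dpool: np.ndarray,
    n_a: int,
    b: int,
    rng: np.random.Generator,
    r_max: float = DEFAULT_R_MAX,
) -> tuple[float, float, float, float]:
    """Permutation test for one pair given its pooled distance submatrix.

    The first ``n_a`` rows/columns of ``dpool`` are library A's sequences, the
    rest library B's.  Returns (t_l, t_c, p_structure, p_composition).
    """
    n = dpool.shape[0]
    pts, widths = _grid_widths(dpool, r_max)
    idx = np.arange(n)
    t_l_obs, t_c_obs = _pair_stats(dpool, idx[:n_a], idx[n_a:], pts, widths)
    ge_l = ge_c = 0
    for _ in range(b):
        perm = rng.permutation(n)
        t_l, t_c = _pair_stats(dpool, perm[:n_a], perm[n_a:], pts, widths)
        ge_l += t_l >= t_l_obs
        ge_c += t_c >= t_c_obs
    return t_l_obs, t_c_obs, _mc_p(ge_l, b), _mc_p(ge_c, b)


# ---------------------------------------------------------------------------


def permutation_test(
    m: DistanceMatrix,
    p: LibraryPartition,
    b: int = 999,
    seed: int | None = None,
    scope: str = "both",
    r_max: float = DEFAULT_R_MAX,
) -> PermutationResult:
    """Monte Carlo permutation test of structure and composition.

    Parameters
    ----------
    m, p
        Distance matrix and library partition (all n_l >= 2).
    b
        Number of shuffles (>= 1); default 999.
    seed
        Seeds a reproducible stream; identical seed gives identical p-values.
    scope
        ``"global"`` (structural test across all L libraries),
        ``"pairwise"`` (per-pair structural and compositional tests, each
        shuffling only the pair's pooled members), or ``"both"``.
    """
    if b < 1:
        raise ValueError("need at least one shuffle (b >= 1)")
    if scope not in ("global", "pairwise", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    if min(p.sizes) < 2:
        raise ValueError("every library needs >= 2 sequences for the T statistics")
    rng = np.random.default_rng(seed)
    sizes = p.sizes
    all_idx = np.concatenate([m.index(mem) for _, mem in p.libraries])
    dsub = m.d[np.ix_(all_idx, all_idx)]

    # observed statistics (always computed, on the pooled grid)
    pts, widths = _grid_widths(dsub, r_max)
    order = np.arange(dsub.shape[0])
    splits = _split_sizes(order, sizes)
    t_l_obs = _global_t_l(dsub, splits, pts, widths)

    pair_keys = p.pairs()
    offsets = np.cumsum([0, *sizes])
    pair_t_l: dict[tuple[str, str], float] = {}
    pair_t_c: dict[tuple[str, str], float] = {}
    p_struct_pair: dict[tuple[str, str], float] = {}
    p_comp_pair: dict[tuple[str, str], float] = {}

    p_global: float | None = None
    if scope in ("global", "both"):
        ge = 0
        for _ in range(b):
            perm = rng.permutation(dsub.shape[0])
            ge += _global_t_l(dsub, _split_sizes(perm, sizes), pts, widths) >= t_l_obs
        p_global = _mc_p(ge, b)

    name_pos = {name: i for i, name in enumerate(p.names)}
    for a, bname in pair_keys:
        ia, ib = name_pos[a], name_pos[bname]
        rows = np.concatenate(
            [order[offsets[ia] : offsets[ia + 1]], order[offsets[ib] : offsets[ib + 1]]]
        )
        dpool = dsub[np.ix_(rows, rows)]
        if scope in ("pairwise", "both"):
            t_l, t_c, p_l, p_c = pair_permutation(dpool, sizes[ia], b, rng, r_max)
            p_struct_pair[(a, bname)] = p_l
            p_comp_pair[(a, bname)] = p_c
        else:  # observed pairwise statistics only
            ppts, pwidths = _grid_widths(dpool, r_max)
            na = sizes[ia]
            t_l, t_c = _pair_stats(
                dpool, np.arange(na), np.arange(na, dpool.shape[0]), ppts, pwidths
            )
        pair_t_l[(a, bname)] = t_l
        pair_t_c[(a, bname)] = t_c

    ikfs = [
        StepCDF(
            *_unique_cdf(dsub, order[offsets[i] : offsets[i + 1]]),
            n_pairs=sizes[i] * (sizes[i] - 1),
            domain_max=r_max,
        )
        for i in range(len(sizes))
    ]
    observed = TestStatistics(
        t_l=t_l_obs,
        pairwise_t_l=pair_t_l,
        pairwise_t_c=pair_t_c,
        kbar=weighted_mean_cdf(ikfs, sizes, r_max),
    )
    return PermutationResult(
        observed=observed,
        b=b,
        p_structure_global=p_global,
        p_structure_pairwise=p_struct_pair,
        p_composition_pairwise=p_comp_pair,
        seed=seed,
    )


def _unique_cdf(dsub: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    block = dsub[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    breaks, counts = np.unique(block[iu], return_counts=True)
    return breaks, np.cumsum(counts) / counts.sum()


def adjust_pairwise(pvalues: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Benjamini-Hochberg adjustment over one pairwise p-value family."""
    keys = list(pvalues)
    adj = false_discovery_control([pvalues[k] for k in keys], method="bh")
    return dict(zip(keys, adj.tolist()))


def compare_all(
    m: DistanceMatrix, p: LibraryPartition, cfg: RunConfig | None = None
) -> KShuffResult:
    """Full analysis: indices plus permutation p-values, one call.

    With L libraries this yields L I_kf values, L(L-1)/2 C_kf values, one
    global structural p-value and per-pair structural/compositional p-values
    (L >= 2; with L = 1 only the single I_kf is reported and no test runs).
    """
    cfg = cfg or RunConfig()
    structural, compositional = all_indices(m, p, cfg.r_max)
    if p.n_libraries >= 2 and cfg.permutations >= 1:
        perm = permutation_test(
            m, p, b=cfg.permutations, seed=cfg.seed, scope="both", r_max=cfg.r_max
        )
    else:
        ikfs = [
            StepCDF(
                *_unique_cdf(m.d, m.index(mem)),
                n_pairs=len(mem) * (len(mem) - 1),
                domain_max=cfg.r_max,
            )
            for _, mem in p.libraries
        ]
        observed = TestStatistics(
            t_l=t_structure(ikfs, p.sizes, cfg.r_max) if p.n_libraries >= 2 else 0.0,
            pairwise_t_l={},
            pairwise_t_c={},
            kbar=weighted_mean_cdf(ikfs, p.sizes, cfg.r_max),
        )
        perm = PermutationResult(observed, 0, None, {}, {}, cfg.seed)
    return KShuffResult(
        partition=p,
        structural=structural,
        compositional=compositional,
        permutation=perm,
        r_max=cfg.r_max,
        alpha=cfg.alpha,
    )
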