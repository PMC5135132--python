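"""Synthetic communities, the mixing power-analysis design, and
conventional diversity indices.

The generator emulates the clustered distance structure of 16S rRNA gene
libraries: a community is a set of clusters (OTU-like groups of closely
related sequences), each a star phylogeny around a random ancestor.  Cluster
ancestors diverge from a shared root so that between-cluster distances are
large; offspring mutate from their ancestor at a small per-site rate so that
within-cluster distances are small.  Distances are Jukes-Cantor-corrected
p-distances capped at 1.0 (the analysis domain), so generated matrices always
satisfy the distance-matrix invariants.

The power analysis follows the mixing design: from two source pools A and B,
construct library 1 with round(omega*N) sequences from A and the rest from B,
and library 2 mirrored.  omega = 0.5 is the null (both libraries are random
blends), omega = 1.0 is maximal separation (no mixing).  Power at each
(omega, N) is the fraction of replicate pairs whose permutation test rejects
at level alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kcore import (
    DEFAULT_R_MAX,
    intra_distances,
    intra_k,
    cross_k,
    ckf_index,
)
from .inference import pair_permutation
from .matrix_io import DistanceMatrix, LibraryPartition

__all__ = [
    "ClusterSpec",
    "SyntheticCommunitySpec",
    "MixingDesign",
    "DiversityIndices",
    "generate_community",
    "mix_pair",
    "power_analysis",
    "subsample_experiment",
    "conventional_indices",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: p-distance above which the Jukes-Cantor correction is undefined
_JC_LIMIT = 0.75


@dataclass(frozen=True)
class ClusterSpec:
    """One OTU-like cluster: a star phylogeny around a single ancestor.

    ``divergence`` is the per-site substitution probability applied
    independently to each offspring; ``weight`` is the relative abundance
    used when libraries are subsampled from the community.
    """

    size: int
    divergence: float = 0.03
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not (0.0 <= self.divergence < _JC_LIMIT):
            raise ValueError(
                f"divergence rate must be in [0, {_JC_LIMIT}) for JC69; "
                f"got {self.divergence}"
            )
        if self.weight <= 0:
            raise ValueError("abundance weight must be positive")


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """A multi-cluster synthetic community.

    ``ancestor_length`` is the shared alignment length in bases (p-distances
    require equal-length sequences).  ``between_divergence`` is the target
    JC-corrected distance between cluster ancestors; 0 collapses all
    ancestors onto the root.
    """

    clusters: tuple[ClusterSpec, ...]
    ancestor_length: int = 800
    between_divergence: float = 0.8
    label_prefix: str = "seq"

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        if not self.clusters:
            raise ValueError("need at least one cluster")
        if self.ancestor_length < 1:
            raise ValueError("ancestor length must be >= 1")
        if self.between_divergence < 0:
            raise ValueError("between-cluster divergence must be >= 0")

    @property
    def n_sequences(self) -> int:
        return sum(c.size for c in self.clusters)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to one of the 3 others."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        out[hit] = (out[hit] + rng.integers(1, 4, hit.sum())) % 4
    return out


def _ancestor_rate(between_jc: float) -> float:
    """Per-site rate from root to each ancestor giving the target pairwise
    JC distance between two independently mutated ancestors.

    If each ancestor mutates from the root at per-site rate q, two ancestors
    differ at a site with probability p = 1 - (1-q)^2 - q^2/3; solving the
    quadratic gives q = (3/4) (1 - sqrt(1 - 4 p / 3)).
    """
    p_target = 0.75 * (1.0 - math.exp(-4.0 * between_jc / 3.0))
    return 0.75 * (1.0 - math.sqrt(max(0.0, 1.0 - 4.0 * p_target / 3.0)))


def _jc69(p: np.ndarray) -> np.ndarray:
    """Jukes-Cantor correction of p-distances, capped at 1.0."""
    d = np.full_like(p, 1.0)
    ok = p < _JC_LIMIT
    with np.errstate(invalid="ignore"):
        d[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return np.minimum(d, 1.0)


def generate_community(
    spec: SyntheticCommunitySpec,
    seed: int | None = None,
    correction: str = "jc69",
) -> tuple[list[tuple[str, str]], DistanceMatrix]:
    """Generate a synthetic community and its pairwise distance matrix.

    Returns ``(records, matrix)`` where records are ``(label, sequence)``
    pairs (labels ``<prefix><cluster>_<i>``) and the matrix holds
    JC69-corrected p-distances capped at 1.0 (``correction="p"`` for raw
    p-distances).  Deterministic given the seed.
    """
    if correction not in ("jc69", "p"):
        raise ValueError(f"unknown correction {correction!r}")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, spec.ancestor_length)
    q = _ancestor_rate(spec.between_divergence)
    seqs = np.empty((spec.n_sequences, spec.ancestor_length), dtype=np.int8)
    labels: list[str] = []
    row = 0
    for ci, cluster in enumerate(spec.clusters, start=1):
        ancestor = _mutate(root, q, rng) if q > 0 else root
        for i in range(1, cluster.size + 1):
            seqs[row] = _mutate(ancestor, cluster.divergence, rng)
            labels.append(f"{spec.label_prefix}{ci}_{i}")
            row += 1
    # pairwise p-distances, chunked to bound memory on large communities
    n = spec.n_sequences
    p = np.zeros((n, n))
    step = max(1, 2**24 // max(1, n * spec.ancestor_length))
    for start in range(0, n, step):
        stop = min(n, start + step)
        p[start:stop] = (seqs[start:stop, None, :] != seqs[None, :, :]).mean(axis=2)
    d = _jc69(p) if correction == "jc69" else p
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    records = [(lab, "".join("ACGT"[b] for b in seqs[i])) for i, lab in enumerate(labels)]
    return records, DistanceMatrix(tuple(labels), d)


def sample_library(
    spec: SyntheticCommunitySpec,
    labels: Sequence[str],
    size: int,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Draw a library from a community without replacement, cluster
    probabilities proportional to abundance weights."""
    weights = np.concatenate(
        [np.full(c.size, c.weight / c.size) for c in spec.clusters]
    )
    weights = weights / weights.sum()
    idx = rng.choice(len(labels), size=size, replace=False, p=weights)
    return tuple(labels[i] for i in idx)


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Mixing design


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class MixingDesign:
    """Construct two N-member libraries by mixing two source pools.

    ``omega`` in [0.5, 1.0]: library 1 takes round(omega*N) sequences from
    pool A and the rest from pool B; library 2 is the mirror image.
    """

    source_a: tuple[str, ...]
    source_b: tuple[str, ...]
    omega: float
    n: int
    replicates: int = 1
    alpha: float = 0.05
    b: int = 199
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_a", tuple(self.source_a))
        object.__setattr__(self, "source_b", tuple(self.source_b))
        if not (0.5 <= self.omega <= 1.0):
            raise ValueError("omega must be in [0.5, 1.0]")
        if self.n < 2:
            raise ValueError("library size N must be >= 2")
        if set(self.source_a) & set(self.source_b):
            raise ValueError("source pools must be disjoint")
        if min(len(self.source_a), len(self.source_b)) < self.n:
            raise ValueError(
                f"each pool must hold >= N={self.n} sequences "
                f"(got {len(self.source_a)} and {len(self.source_b)})"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def mix_pair(
    design: MixingDesign, rng: np.random.Generator | None = None
) -> LibraryPartition:
    """One mixed library pair, sampled without replacement from the pools.

    At omega = 1.0 library 1 is pure pool A and library 2 pure pool B; at
    omega = 0.5 both are half-and-half blends (the null configuration).
    """
    rng = np.random.default_rng(design.seed) if rng is None else rng
    k = _round_half_up(design.omega * design.n)
    perm_a = rng.permutation(len(design.source_a))[: design.n]
    perm_b = rng.permutation(len(design.source_b))[: design.n]
    a = [design.source_a[i] for i in perm_a]
    b = [design.source_b[i] for i in perm_b]
    lib1 = tuple(a[:k] + b[k:])
    lib2 = tuple(b[:k] + a[k:])
    return LibraryPartition((("mix_a", lib1), ("mix_b", lib2)))


def power_analysis(
    m: DistanceMatrix,
    designs: Sequence[MixingDesign],
    r_max: float = DEFAULT_R_MAX,
) -> pd.DataFrame:
    """Rejection rates of the structural and compositional tests on a grid
    of mixing designs.

    Returns one row per design with columns ``omega, n, replicates,
    power_structure, power_composition, se_structure, se_composition``;
    the standard error is sqrt(p(1-p)/replicates).
    """
    rows = []
    for design in designs:
        rng = np.random.default_rng(design.seed)
        rej_l = rej_c = 0
        for _ in range(design.replicates):
            part = mix_pair(design, rng)
            pooled = part.members("mix_a") + part.members("mix_b")
            dpool = m.submatrix(pooled)
            _, _, p_l, p_c = pair_permutation(dpool, design.n, design.b, rng, r_max)
            rej_l += p_l <= design.alpha
            rej_c += p_c <= design.alpha
        pw_l = rej_l / design.replicates
        pw_c = rej_c / design.replicates
        rows.append(
            {
                "omega": design.omega,
                "n": design.n,
                "replicates": design.replicates,
                "power_structure": pw_l,
                "power_composition": pw_c,
                "se_structure": math.sqrt(pw_l * (1 - pw_l) / design.replicates),
                "se_composition": math.sqrt(pw_c * (1 - pw_c) / design.replicates),
            }
        )
    return pd.DataFrame(rows)


def subsample_experiment(
    m: DistanceMatrix,
    libraries: Sequence[tuple[str, Sequence[str]]],
    sizes: Sequence[int],
    reps: int = 200,
    seed: int | None = None,
    r_max: float = DEFAULT_R_MAX,
) -> pd.DataFrame:
    """Sampling variation of I_kf (and C_kf for a pair) with library size.

    For each subsample size, draws ``reps`` random subsets without
    replacement from each library and reports the mean and SD of each
    library's I_kf; when two libraries are given, also of their C_kf.

    Returns a tidy frame with columns ``size, measure, mean, sd`` where
    measure is ``ikf[<name>]`` or ``ckf[<a>,<b>]``.
    """
    if not 1 <= len(libraries) <= 2:
        raise ValueError("give one library (I_kf) or two (I_kf and C_kf)")
    for name, mem in libraries:
        for size in sizes:
            if size > len(mem):
                raise ValueError(
                    f"subsample size {size} exceeds library {name!r} ({len(mem)})"
                )
            if size < 2:
                raise ValueError("subsample sizes must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        ikf_draws = {name: np.empty(reps) for name, _ in libraries}
        ckf_draws = np.empty(reps) if len(libraries) == 2 else None
        for r in range(reps):
            subs = []
            for name, mem in libraries:
                pick = rng.permutation(len(mem))[:size]
                sub = [mem[i] for i in pick]
                subs.append(sub)
                ikf_draws[name][r] = float(
                    np.mean(np.minimum(intra_distances(m, sub), r_max))
                )
            if ckf_draws is not None:
                k_ab = cross_k(m, subs[0], subs[1], r_max)
                k_a = intra_k(m, subs[0], r_max)
                k_b = intra_k(m, subs[1], r_max)
                ckf_draws[r] = ckf_index(k_ab, k_a, k_b, r_max)
        for name, _ in libraries:
            rows.append(
                {
                    "size": size,
                    "measure": f"ikf[{name}]",
                    "mean": float(ikf_draws[name].mean()),
                    "sd": float(ikf_draws[name].std(ddof=1)),
                }
            )
        if ckf_draws is not None:
            a, b = libraries[0][0], libraries[1][0]
            rows.append(
                {
                    "size": size,
                    "measure": f"ckf[{a},{b}]",
                    "mean": float(ckf_draws.mean()),
                    "sd": float(ckf_draws.std(ddof=1)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conventional diversity indices (Shannon, Simpson, Chao1)


@dataclass(frozen=True)
class DiversityIndices:
    """OTU-abundance-based indices for comparison with I_kf.

    ``inverse_simpson`` is ``inf`` when no OTU has two or more members
    (D = 0).  The Chao1 interval is the log-normal interval of Chao (1987).
    """

    richness: int
    shannon: float
    simpson: float
    inverse_simpson: float
    chao1: float
    chao1_lci: float
    chao1_hci: float


def conventional_indices(abundances: Sequence[int]) -> DiversityIndices:
    """Shannon H, Simpson D (with reciprocal), and Chao1 with a 95% CI.

    H = -sum (n_i/N) ln(n_i/N); D = sum n_i (n_i - 1) / (N (N - 1));
    Chao1 = S + n1^2 / (2 n2) with n1 singletons and n2 doubletons
    (S + n1 (n1 - 1) / 2 when n2 = 0; S when n1 = 0).
    """
    counts = np.asarray(abundances)
    if counts.size == 0 or np.any(counts < 0) or not np.all(counts == counts.astype(int)):
        raise ValueError("abundances must be nonnegative integers")
    counts = counts[counts > 0].astype(float)
    if counts.size == 0:
        raise ValueError("at least one OTU must have a positive count")
    total = counts.sum()
    s = int(counts.size)
    frac = counts / total
    shannon = float(-np.sum(frac * np.log(frac)))
    simpson = float(np.sum(counts * (counts - 1)) / (total * (total - 1))) if total > 1 else 0.0
    inv_simpson = 1.0 / simpson if simpson > 0 else math.inf

    n1 = int(np.sum(counts == 1))
    n2 = int(np.sum(counts == 2))
    if n1 == 0:
        chao, var = float(s), 0.0
    elif n2 == 0:
        chao = s + n1 * (n1 - 1) / 2.0
        var = n1 * (n1 - 1) / 2.0 + n1 * (2 * n1 - 1) ** 2 / 4.0 - n1**4 / (4.0 * chao)
    else:
        ratio = n1 / n2
        chao = s + n1**2 / (2.0 * n2)
        var = n2 * (0.5 * ratio**2 + ratio**3 + 0.25 * ratio**4)
    extra = chao - s
    if extra > 0 and var > 0:
        k = math.exp(1.96 * math.sqrt(math.log(1.0 + var / extra**2)))
        lci, hci = s + extra / k, s + extra * k
    else:
        lci = hci = chao
    return DiversityIndices(
        richness=s,
        shannon=shannon,
        simpson=simpson,
        inverse_simpson=inv_simpson,
        chao1=chao,
        chao1_lci=lci,
        chao1_hci=hci,
    )
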