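"""Synthetic community generator, mixing design, subsampling and the
conventional diversity indices."""

import math

import numpy as np
import pytest

from kshuff.simulate import (
    ClusterSpec,
    MixingDesign,
    SyntheticCommunitySpec,
    conventional_indices,
    generate_community,
    mix_pair,
    power_analysis,
    subsample_experiment,
    write_fasta,
)
from conftest import random_distance_matrix


def two_cluster_spec(size=20, divergence=0.02, between=0.8, length=400):
    return SyntheticCommunitySpec(
        (ClusterSpec(size, divergence), ClusterSpec(size, divergence)),
        ancestor_length=length,
        between_divergence=between,
    )


# ---------------------------------------------------------------------------
# generate_community


def test_zero_divergence_zero_distances():
    spec = SyntheticCommunitySpec(
        (ClusterSpec(5, 0.0),), ancestor_length=200, between_divergence=0.0
    )
    _, m = generate_community(spec, seed=0)
    assert np.all(m.d == 0.0)


def test_within_less_than_between():
    _, m = generate_community(two_cluster_spec(), seed=4)
    n = 20
    iu = np.triu_indices(n, k=1)
    within_a = m.d[:n, :n][iu]
    within_b = m.d[n:, n:][iu]
    between = m.d[:n, n:]
    assert within_a.mean() < between.mean()
    assert within_b.mean() < between.mean()
    # between-cluster JC distance lands near the requested target
    assert between.mean() == pytest.approx(0.8, rel=0.15)


def test_determinism_and_seed_sensitivity():
    spec = two_cluster_spec(size=8, length=200)
    _, m1 = generate_community(spec, seed=11)
    _, m2 = generate_community(spec, seed=11)
    _, m3 = generate_community(spec, seed=12)
    np.testing.assert_array_equal(m1.d, m2.d)
    assert not np.array_equal(m1.d, m3.d)


def test_generated_matrix_satisfies_invariants():
    _, m = generate_community(two_cluster_spec(size=10, length=300), seed=2)
    assert np.all(np.diag(m.d) == 0)
    assert np.all(m.d >= 0) and np.all(m.d <= 1.0)
    np.testing.assert_array_equal(m.d, m.d.T)
    assert len(set(m.labels)) == m.n


def test_p_distance_mode_uncorrected():
    spec = two_cluster_spec(size=5, length=300)
    _, mp = generate_community(spec, seed=3, correction="p")
    _, mjc = generate_community(spec, seed=3, correction="jc69")
    off = ~np.eye(mp.n, dtype=bool)
    assert np.all(mjc.d[off] >= mp.d[off] - 1e-12)  # JC inflates p-distances


def test_divergence_rate_limit():
    with pytest.raises(ValueError, match="0.75"):
        ClusterSpec(5, 0.8)


def test_fasta_roundtrips_sequences(tmp_path):
    records, _ = generate_community(two_cluster_spec(size=3, length=150), seed=1)
    path = tmp_path / "seqs.fasta"
    write_fasta(records, path)
    text = path.read_text()
    assert text.count(">") == 6
    assert records[0][1].replace("\n", "") in text.replace("\n", "")


# ---------------------------------------------------------------------------
# mix_pair


@pytest.fixture()
def pools():
    a = tuple(f"a{i}" for i in range(120))
    b = tuple(f"b{i}" for i in range(120))
    return a, b


def count_sources(members, prefix):
    return sum(1 for x in members if x.startswith(prefix))


def test_no_mixing_at_omega_one(pools):
    a, b = pools
    part = mix_pair(MixingDesign(a, b, omega=1.0, n=100, seed=0))
    assert count_sources(part.members("mix_a"), "a") == 100
    assert count_sources(part.members("mix_b"), "b") == 100


def test_seventy_thirty_at_omega_07(pools):
    a, b = pools
    part = mix_pair(MixingDesign(a, b, omega=0.70, n=100, seed=1))
    lib1, lib2 = part.members("mix_a"), part.members("mix_b")
    assert count_sources(lib1, "a") == 70 and count_sources(lib1, "b") == 30
    assert count_sources(lib2, "b") == 70 and count_sources(lib2, "a") == 30


def test_symmetric_split_at_omega_half(pools):
    a, b = pools
    part = mix_pair(MixingDesign(a, b, omega=0.5, n=50, seed=2))
    for lib in ("mix_a", "mix_b"):
        assert count_sources(part.members(lib), "a") == 25
        assert count_sources(part.members(lib), "b") == 25


def test_mix_is_sampling_without_replacement(pools):
    a, b = pools
    part = mix_pair(MixingDesign(a, b, omega=0.75, n=80, seed=3))
    pooled = part.members("mix_a") + part.members("mix_b")
    assert len(set(pooled)) == 160  # libraries disjoint, no duplicates


def test_rounding_is_half_up(pools):
    a, b = pools
    # omega*N = 55.5 -> 56 with half-up rounding
    part = mix_pair(MixingDesign(a, b, omega=0.555, n=100, seed=4))
    assert count_sources(part.members("mix_a"), "a") == 56


def test_insufficient_pool_rejected(pools):
    a, b = pools
    with pytest.raises(ValueError, match="N=200"):
        MixingDesign(a, b, omega=0.6, n=200)


def test_omega_outside_range_rejected(pools):
    a, b = pools
    with pytest.raises(ValueError):
        MixingDesign(a, b, omega=0.4, n=10)


# ---------------------------------------------------------------------------
# power_analysis (cheap smoke checks; calibration lives in the acceptance suite)


def test_power_one_at_maximal_separation():
    _, m = generate_community(two_cluster_spec(size=60, divergence=0.024), seed=5)
    a, b = m.labels[:60], m.labels[60:]
    curve = power_analysis(
        m, [MixingDesign(a, b, omega=1.0, n=50, replicates=20, b=99, seed=9)]
    )
    assert curve.loc[0, "power_composition"] == 1.0
    assert curve.loc[0, "se_composition"] == 0.0


def test_power_table_layout():
    _, m = generate_community(two_cluster_spec(size=30, length=200), seed=6)
    a, b = m.labels[:30], m.labels[30:]
    designs = [
        MixingDesign(a, b, omega=w, n=20, replicates=3, b=19, seed=i)
        for i, w in enumerate((0.5, 0.75, 1.0))
    ]
    curve = power_analysis(m, designs)
    assert list(curve["omega"]) == [0.5, 0.75, 1.0]
    assert set(curve.columns) >= {
        "omega", "n", "replicates", "power_structure", "power_composition",
        "se_structure", "se_composition",
    }
    for _, row in curve.iterrows():
        p = row["power_composition"]
        assert row["se_composition"] == pytest.approx(math.sqrt(p * (1 - p) / 3))


# ---------------------------------------------------------------------------
# subsample_experiment


def test_full_library_subsample_has_zero_sd(rng):
    m = random_distance_matrix(rng, 12)
    lib = ("L", m.labels)
    table = subsample_experiment(m, [lib], sizes=[12], reps=10, seed=0)
    row = table.iloc[0]
    assert row["sd"] == 0.0
    from kshuff.kcore import intra_k, ikf_index
    assert row["mean"] == pytest.approx(ikf_index(intra_k(m, m.labels)))


def test_subsample_reports_ckf_for_pairs(rng):
    m = random_distance_matrix(rng, 20)
    table = subsample_experiment(
        m, [("A", m.labels[:10]), ("B", m.labels[10:])], sizes=[4, 8], reps=25, seed=1
    )
    measures = set(table["measure"])
    assert {"ikf[A]", "ikf[B]", "ckf[A,B]"} <= measures
    assert len(table) == 6  # 3 measures x 2 sizes


def test_subsample_size_exceeding_library(rng):
    m = random_distance_matrix(rng, 6)
    with pytest.raises(ValueError, match="exceeds"):
        subsample_experiment(m, [("L", m.labels)], sizes=[7], reps=2, seed=0)


def test_different_seeds_agree_within_error(rng):
    m = random_distance_matrix(rng, 30)
    lib = [("L", m.labels)]
    t1 = subsample_experiment(m, lib, sizes=[10], reps=150, seed=1)
    t2 = subsample_experiment(m, lib, sizes=[10], reps=150, seed=2)
    se = t1.iloc[0]["sd"] / math.sqrt(150)
    assert abs(t1.iloc[0]["mean"] - t2.iloc[0]["mean"]) < 4 * se


# ---------------------------------------------------------------------------
# conventional diversity indices


def test_equal_singletons():
    idx = conventional_indices([1, 1, 1, 1])
    assert idx.richness == 4
    assert idx.shannon == pytest.approx(math.log(4))
    assert idx.simpson == 0.0
    assert math.isinf(idx.inverse_simpson)


def test_no_singletons_chao_equals_richness():
    idx = conventional_indices([2, 2])
    assert idx.chao1 == 2.0
    assert idx.chao1_lci == idx.chao1_hci == 2.0


def test_formulas_match_direct_evaluation():
    counts = [5, 3, 1, 1, 2]
    n = sum(counts)
    idx = conventional_indices(counts)
    assert idx.richness == 5
    assert idx.shannon == pytest.approx(-sum(c / n * math.log(c / n) for c in counts))
    assert idx.simpson == pytest.approx(
        sum(c * (c - 1) for c in counts) / (n * (n - 1))
    )
    # n1 = 2 singletons, n2 = 1 doubleton
    assert idx.chao1 == pytest.approx(5 + 2**2 / (2 * 1))
    assert idx.chao1_lci <= idx.chao1 <= idx.chao1_hci


def test_zero_counts_dropped_and_all_zero_rejected():
    assert conventional_indices([3, 0, 2]).richness == 2
    with pytest.raises(ValueError):
        conventional_indices([0, 0])
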