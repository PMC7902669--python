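import itertools

import numpy as np
import pytest

from popsweep.io import GenotypeMatrix, PopulationSpec
from popsweep.stats import (
    SiteCounts,
    filter_variants,
    fst_weir_cockerham,
    ld_r2,
    nucleotide_diversity,
    site_counts,
    tajimas_d,
    tile_windows,
    wattersons_theta,
    windowed_stat,
)

from conftest import random_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def pi_bruteforce(calls, span):
    """Mean over all pairs of per-pair Hamming distance / span (complete data)."""
    n = len(calls)
    total = sum(
        np.sum(calls[i] != calls[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / span


def tajima_d_direct(calls):
    """Direct-formula Tajima's D for a complete 0/1 matrix."""
    n, m = calls.shape
    freqs = calls.sum(axis=0)
    seg = (freqs > 0) & (freqs < n)
    s = seg.sum()
    if s == 0:
        return float("nan")
    pi = pi_bruteforce(calls, 1.0)  # total pairwise differences per pair
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def fst_wc_direct(k1, n1, k2, n2):
    """Independently coded haploid Weir-Cockerham components for one site."""
    p1, p2 = k1 / n1, k2 / n2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / 1.0
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - s2 / 2)
    a = nbar / nc * (s2 - b / nbar)
    return a, b


def r2_from_hap_freqs(x, y):
    """D^2 / (p (1-p) q (1-q)) from haplotype frequencies."""
    p = x.mean()
    q = y.mean()
    pxy = np.mean(x * y)
    d = pxy - p * q
    denom = p * (1 - p) * q * (1 - q)
    return float("nan") if denom == 0 else d * d / denom


def matrix_from_calls(calls):
    n, m = calls.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        chrom=np.array(["c"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["T"] * m, dtype=object),
        calls=calls.astype(np.int8),
    )


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

class TestPi:
    def test_identical_haplotypes_zero(self):
        m = matrix_from_calls(np.ones((4, 10), dtype=int))
        assert nucleotide_diversity(m, span_bp=100) == 0.0

    def test_two_haplotypes_three_of_hundred(self):
        calls = np.zeros((2, 3), dtype=int)
        calls[1] = 1
        m = matrix_from_calls(calls)
        assert nucleotide_diversity(m, span_bp=100) == pytest.approx(0.03)

    def test_matches_bruteforce(self, rng):
        m = random_matrix(rng, n_hap=8, n_sites=40)
        got = nucleotide_diversity(m, span_bp=40)
        assert got == pytest.approx(pi_bruteforce(m.calls, 40), rel=1e-12)

    def test_invalid_span(self, rng):
        m = random_matrix(rng)
        with pytest.raises(ValueError):
            nucleotide_diversity(m, span_bp=0)

    def test_all_missing_undefined(self):
        calls = np.full((3, 2), -1, dtype=int)
        m = matrix_from_calls(calls)
        assert np.isnan(nucleotide_diversity(m, span_bp=10))

    def test_sample_reorder_invariant(self, rng):
        m = random_matrix(rng, n_hap=7, n_sites=30)
        perm = rng.permutation(7)
        assert nucleotide_diversity(m, span_bp=30) == pytest.approx(
            nucleotide_diversity(m.subset_samples(perm), span_bp=30))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimasD:
    def test_monomorphic_undefined(self):
        m = matrix_from_calls(np.zeros((6, 5), dtype=int))
        assert np.isnan(tajimas_d(m))

    def test_singletons_negative(self):
        calls = np.zeros((10, 5), dtype=int)
        for j in range(5):
            calls[j, j] = 1  # five singleton sites
        assert tajimas_d(matrix_from_calls(calls)) < 0

    def test_matches_direct_formula(self, rng):
        for _ in range(5):
            m = random_matrix(rng, n_hap=10, n_sites=60)
            expected = tajima_d_direct(m.calls)
            assert tajimas_d(m) == pytest.approx(expected, rel=1e-10)

    def test_watterson_theta(self, rng):
        m = random_matrix(rng, n_hap=6, n_sites=25)
        freqs = m.calls.sum(axis=0)
        s = int(((freqs > 0) & (freqs < 6)).sum())
        a1 = sum(1 / i for i in range(1, 6))
        assert wattersons_theta(m) == pytest.approx(s / a1, rel=1e-12)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def counts_single(k1, n1, k2, n2):
    return SiteCounts(
        chrom=np.array(["c"], dtype=object), pos=np.array([1]),
        k1=np.array([k1]), n1=np.array([n1]),
        k2=np.array([k2]), n2=np.array([n2]),
    )


class TestFst:
    def test_complete_fixation_is_one(self):
        res = fst_weir_cockerham(counts_single(10, 10, 0, 10))
        assert res.per_site[0] == pytest.approx(1.0)
        assert res.overall == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        c = SiteCounts(
            chrom=np.array(["c"] * 4, dtype=object), pos=np.arange(1, 5),
            k1=np.array([3, 5, 2, 8]), n1=np.full(4, 10),
            k2=np.array([3, 5, 2, 8]), n2=np.full(4, 10),
        )
        assert fst_weir_cockerham(c).overall <= 0

    def test_matches_direct_oracle(self):
        res = fst_weir_cockerham(counts_single(8, 10, 2, 10))
        a, b = fst_wc_direct(8, 10, 2, 10)
        assert res.a[0] == pytest.approx(a, rel=1e-12)
        assert res.b[0] == pytest.approx(b, rel=1e-12)
        assert res.per_site[0] == pytest.approx(a / (a + b), rel=1e-12)

    def test_single_site_overall_equals_per_site(self):
        res = fst_weir_cockerham(counts_single(7, 12, 1, 9))
        assert res.overall == pytest.approx(res.per_site[0], rel=1e-12)

    def test_monomorphic_sites_excluded(self):
        c = SiteCounts(
            chrom=np.array(["c"] * 2, dtype=object), pos=np.arange(1, 3),
            k1=np.array([0, 8]), n1=np.full(2, 10),
            k2=np.array([0, 2]), n2=np.full(2, 10),
        )
        res = fst_weir_cockerham(c)
        assert np.isnan(res.per_site[0])
        a, b = fst_wc_direct(8, 10, 2, 10)
        assert res.overall == pytest.approx(a / (a + b), rel=1e-12)

    def test_never_exceeds_one(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 20, size=2)
            k1 = rng.integers(0, n1 + 1)
            k2 = rng.integers(0, n2 + 1)
            res = fst_weir_cockerham(counts_single(k1, n1, k2, n2))
            if not np.isnan(res.per_site[0]):
                assert res.per_site[0] <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# r^2
# ---------------------------------------------------------------------------

class TestLdR2:
    def test_identical_columns(self):
        calls = np.array([[0, 0], [1, 1], [0, 0], [1, 1]])
        assert ld_r2(matrix_from_calls(calls), 0, 1) == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        calls = np.array([[0, 1], [1, 0], [0, 1], [1, 0]])
        assert ld_r2(matrix_from_calls(calls), 0, 1) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        calls = np.array([[0, 1], [0, 0], [0, 1]])
        assert np.isnan(ld_r2(matrix_from_calls(calls), 0, 1))

    def test_matches_haplotype_frequency_oracle(self, rng):
        for _ in range(20):
            calls = rng.integers(0, 2, size=(12, 2))
            m = matrix_from_calls(calls)
            got = ld_r2(m, 0, 1)
            want = r2_from_hap_freqs(calls[:, 0].astype(float), calls[:, 1].astype(float))
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)


# ---------------------------------------------------------------------------
# variant filter cascade
# ---------------------------------------------------------------------------

def filter_oracle(matrix, maf_min, r2_max, missing_max, ld_window=50):
    """Naive re-implementation of the documented cascade."""
    keep = []
    n_hap = matrix.n_haplotypes
    for j in range(matrix.n_sites):
        col = matrix.calls[:, j]
        called = col != -1
        if (1 - called.sum() / n_hap) >= missing_max:
            continue
        p = (col[called] == 1).mean() if called.any() else 0.0
        if min(p, 1 - p) <= maf_min:
            continue
        keep.append(j)
    kept = []
    for j in keep:
        ok = True
        for i in kept:
            if j - i >= ld_window:
                continue
            r2 = ld_r2(matrix, i, j)
            if not np.isnan(r2) and r2 >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


class TestFilterVariants:
    def test_monomorphic_all_dropped(self):
        m = matrix_from_calls(np.zeros((6, 8), dtype=int))
        assert filter_variants(m).n_sites == 0

    def test_duplicated_column_pruned(self):
        col = np.array([0, 1, 0, 1, 1, 0])
        calls = np.stack([col, col], axis=1)
        m = matrix_from_calls(calls)
        assert filter_variants(m, maf_min=0.1, r2_max=0.2).n_sites == 1

    def test_matches_oracle(self, rng):
        m = random_matrix(rng, n_hap=20, n_sites=200, missing_frac=0.15)
        got = filter_variants(m, maf_min=0.1, r2_max=0.2, missing_max=0.3)
        want = filter_oracle(m, 0.1, 0.2, 0.3)
        np.testing.assert_array_equal(got.pos, m.pos[want])


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

class TestWindows:
    def test_tiling_example(self):
        assert tile_windows(2000, 1000, 500) == [(0, 1000), (500, 1500), (1000, 2000)]

    def test_terminal_window_clipped(self):
        ws = tile_windows(2100, 1000, 500)
        assert ws[-1] == (1500, 2100)

    def test_empty_window_undefined(self, rng):
        m = random_matrix(rng, n_hap=6, n_sites=10)
        m.pos = np.arange(1, 11)  # all SNPs in [0, 10)
        track = windowed_stat(m, None, "pi", window_size=5, step=5,
                              chrom_lengths={"chr1": 20})
        assert track.n_snps[-1] == 0 and np.isnan(track.value[-1])

    def test_partition_conserves_snps(self, rng):
        m = random_matrix(rng, n_hap=6, n_sites=50)
        track = windowed_stat(m, None, "tajimas_d", window_size=100, step=100)
        assert track.n_snps.sum() == m.n_sites

    def test_windowed_fst(self, rng):
        m = random_matrix(rng, n_hap=8, n_sites=30)
        spec = PopulationSpec({f"s{i}": ("a" if i < 4 else "b") for i in range(8)})
        track = windowed_stat(m, spec, "fst", window_size=10_000, step=10_000,
                              pop_pair=("a", "b"))
        counts = site_counts(m, spec, "a", "b")
        assert track.value[0] == pytest.approx(fst_weir_cockerham(counts).overall)
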