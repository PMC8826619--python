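"""Unit and oracle tests for the diversity / Tajima's D / LD primitives.

Oracles are independent of the implementation: site pi is checked against
exhaustive pairwise mismatch enumeration over chromosomes, Tajima's D against
a from-scratch recomputation of the canonical 1989 constants, r^2 against a
hand-computed Pearson correlation.
"""

import itertools
import math

import numpy as np
import pytest

from retropop.popgen import (
    genotype_r2,
    ld_prune,
    mean_ld,
    site_pi,
    sites_pi,
    tajima_constants,
    tajimas_d,
    windowed_pi,
)
from retropop.types import SNPMatrix


def _snps(positions, dosages, samples=None, chrom="chr1"):
    dosages = np.asarray(dosages)
    samples = samples or [f"s{i}" for i in range(dosages.shape[1])]
    return SNPMatrix(chrom, np.asarray(positions), samples, dosages)


def pi_by_pair_enumeration(dosages):
    """Oracle: fraction of mismatching chromosome pairs at one site."""
    chroms = []
    for d in dosages:
        if d == -1:
            continue
        chroms += [1] * d + [0] * (2 - d)
    if len(chroms) < 2:
        return math.nan
    pairs = list(itertools.combinations(chroms, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


class TestSitePi:
    def test_monomorphic(self):
        assert site_pi([0, 0, 0]) == 0.0
        assert site_pi([2, 2]) == 0.0

    def test_single_het_two_chromosomes(self):
        assert site_pi([1]) == 1.0

    def test_printed_value(self):
        # j=3 alt among k=10 chromosomes -> 2*3*7/90
        assert site_pi([1, 1, 1, 0, 0]) == pytest.approx(2 * 3 * 7 / 90)
        assert site_pi([1, 1, 1, 0, 0]) == pytest.approx(0.4667, abs=5e-5)

    def test_undefined_below_two_chromosomes(self):
        assert math.isnan(site_pi([-1, -1]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_enumeration_k_le_12(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))  # up to 12 chromosomes, with missing
        d = rng.integers(-1, 3, size=n)
        expected = pi_by_pair_enumeration(d)
        got = site_pi(d)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        d = rng.integers(-1, 3, size=(40, 8))
        vec = sites_pi(d)
        for i in range(40):
            s = site_pi(d[i])
            assert (math.isnan(s) and math.isnan(vec[i])) or vec[i] == pytest.approx(s)


class TestWindowedPi:
    def test_identical_haplotypes_zero(self):
        snps = _snps([10, 20, 30], np.full((3, 4), 2, dtype=int))
        stats = windowed_pi(snps, region=(1, 100), window=50, step=25)
        assert all(w.value == 0 for w in stats)

    def test_single_site_per_bp(self):
        snps = _snps([5000], [[1]])  # site_pi = 1.0
        stats = windowed_pi(snps, region=(1, 10_000), window=10_000)
        assert len(stats) == 1
        assert stats[0].value == pytest.approx(1e-4)
        assert stats[0].n_sites == 1

    def test_sum_oracle_30_sites(self):
        rng = np.random.default_rng(5)
        positions = np.sort(rng.choice(np.arange(1, 20_001), 30, replace=False))
        dosages = rng.integers(0, 3, size=(30, 6))
        snps = _snps(positions, dosages)
        stats = windowed_pi(snps, region=(1, 20_000), window=5_000, step=5_000)
        total = sum(w.value * (w.window_end - w.window_start) for w in stats)
        expected = sum(site_pi(dosages[i]) for i in range(30))
        assert total == pytest.approx(expected, rel=1e-10)

    def test_nonoverlapping_total_equals_region_mean(self):
        rng = np.random.default_rng(7)
        dosages = rng.integers(0, 3, size=(50, 5))
        positions = np.sort(rng.choice(np.arange(1, 40_001), 50, replace=False))
        snps = _snps(positions, dosages)
        stats = windowed_pi(snps, region=(1, 40_000), window=8_000, step=8_000)
        total = sum(w.value * (w.window_end - w.window_start) for w in stats)
        region_pi = float(np.nansum(sites_pi(dosages)))
        assert total == pytest.approx(region_pi)

    def test_empty_window(self):
        snps = _snps([100], [[1]])
        stats = windowed_pi(snps, region=(1, 30_000), window=10_000, step=10_000)
        assert stats[1].value == 0 and stats[1].n_sites == 0


def tajimas_d_oracle(haplotypes):
    """From-scratch D on a (n_haplotypes, n_sites) 0/1 matrix."""
    h = np.asarray(haplotypes)
    n, n_sites = h.shape
    counts = h.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    pi = 0.0
    for i, j in itertools.combinations(range(n), 2):
        pi += (h[i] != h[j]).sum()
    pi /= n * (n - 1) / 2
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def _haplotypes_to_snps(haps, positions=None):
    """Pair consecutive haplotypes into diploid dosages."""
    h = np.asarray(haps)
    dosages = h[0::2] + h[1::2]
    positions = positions or list(range(1, h.shape[1] + 1))
    return _snps(positions, dosages.T)


class TestTajimasD:
    def test_all_singletons_negative(self):
        # n=10 haplotypes (5 diploids), 5 singleton sites
        h = np.zeros((10, 5), dtype=int)
        for s in range(5):
            h[s, s] = 1
        assert tajimas_d(_haplotypes_to_snps(h)) < 0

    def test_balanced_frequencies_positive(self):
        h = np.zeros((10, 4), dtype=int)
        h[:5, :] = 1
        assert tajimas_d(_haplotypes_to_snps(h)) > 0

    def test_matches_from_scratch_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            h = rng.integers(0, 2, size=(6, 8))
            counts = h.sum(axis=0)
            if not (((counts > 0) & (counts < 6)).any()):
                continue
            expected = tajimas_d_oracle(h)
            got = tajimas_d(_haplotypes_to_snps(h))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_no_segregating_sites_undefined(self):
        snps = _snps([10, 20], np.zeros((2, 5), dtype=int))
        assert math.isnan(tajimas_d(snps))

    def test_constants_identity(self):
        c = tajima_constants(10)
        assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))

    def test_neutral_simulation_mean_near_zero(self):
        """Neutral synthetic flanks give mean D in (-0.5, 0.5) over 200 replicates."""
        from retropop.synthetic import SimConfig, simulate_flank_haplotypes

        cfg = SimConfig(seed=0, flank_length=5_000, sweep_core_bp=2_000)
        ds = []
        for s in range(200):
            snps, _ = simulate_flank_haplotypes(5, 5, cfg, sweep=False, seed=s)
            d = tajimas_d(snps)
            if not math.isnan(d):
                ds.append(d)
        assert -0.5 < np.mean(ds) < 0.5


class TestGenotypeR2:
    def test_identical_vectors(self):
        assert genotype_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert genotype_r2([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_hand_computed_pearson_squared(self):
        a = np.array([0, 1, 2, 1, 0], dtype=float)
        b = np.array([0, 1, 0, 1, 2], dtype=float)
        r = np.corrcoef(a, b)[0, 1]  # independent route to Pearson
        assert genotype_r2(a, b) == pytest.approx(r**2, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert math.isnan(genotype_r2([1, 1, 1], [0, 1, 2]))

    def test_missing_pairwise_deleted(self):
        # deleting the missing pair leaves identical vectors
        assert genotype_r2([0, 1, -1, 2], [0, 1, 2, 2]) == pytest.approx(1.0)


class TestMeanLD:
    def test_single_snp_undefined(self):
        snps = _snps([100], [[0, 1, 2]])
        assert math.isnan(mean_ld(snps))

    def test_perfect_ld_block(self):
        row = [0, 1, 2, 1]
        snps = _snps([100, 200, 300], [row, row, row])
        assert mean_ld(snps) == pytest.approx(1.0)

    def test_four_snp_pair_mean_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(4, 8))
        snps = _snps([10, 20, 30, 40], d)
        pairs = [
            genotype_r2(d[i], d[j]) for i, j in itertools.combinations(range(4), 2)
        ]
        pairs = [p for p in pairs if not math.isnan(p)]
        assert mean_ld(snps) == pytest.approx(np.mean(pairs))


class TestLDPrune:
    def test_independent_sites_all_retained(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(10, 200))
        snps = _snps(list(range(10, 110, 10)), d)
        kept = ld_prune(snps, r2_threshold=0.2)
        # sanity: with 200 individuals random sites rarely exceed 0.2
        assert len(kept) >= 9

    def test_duplicate_keeps_earlier(self):
        row = [0, 1, 2, 1, 0, 2]
        other = [0, 2, 0, 1, 2, 0]
        snps = _snps([10, 20, 30], [row, other, row])
        kept = ld_prune(snps)
        assert 0 in kept and 2 not in kept

    def test_perfect_block_keeps_one(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=30)
        rows = [rng.integers(0, 3, size=30) for _ in range(7)]
        d = np.vstack([rows[0], base, base, rows[1], base] + rows[2:])
        snps = _snps(list(range(10, 10 + 10 * d.shape[0], 10)), d)
        kept = ld_prune(snps)
        block = {1, 2, 4}
        assert len(block & set(kept)) == 1
        assert min(block & set(kept)) == 1  # earliest of the block

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(30, 12))
        snps = _snps(list(range(5, 5 + 150, 5)), d)
        kept = ld_prune(snps, window=30, step=10, r2_threshold=0.3)
        for i, j in itertools.combinations(kept, 2):
            r2 = genotype_r2(snps.dosages[i], snps.dosages[j])
            assert math.isnan(r2) or r2 < 0.3


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=-1, max_value=2), min_size=1, max_size=6))
def test_site_pi_is_pairwise_mismatch_fraction(dosages):
    """Property: site pi always equals the exhaustive pair-mismatch fraction."""
    expected = pi_by_pair_enumeration(dosages)
    got = site_pi(dosages)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert abs(got - expected) < 1e-12
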