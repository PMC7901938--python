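"""nSL statistic: identity lengths, raw score vs brute-force oracle,
orientation, bin standardization, candidate regions, imputation audit."""

import numpy as np
import pytest

from driftscan import syndata
from driftscan.nsl import (
    HaplotypeTable,
    call_candidates,
    compute_nsl,
    imputation_bias_check,
    orient_positive,
    pair_identity_length,
    standardize_bins,
)


def brute_force_nsl(haps, s):
    """Independent O(n^2 m) oracle: mean pairwise identity length per class."""
    n = haps.shape[0]
    alt = [i for i in range(n) if haps[i, s] == 1]
    ref = [i for i in range(n) if haps[i, s] == 0]
    if len(alt) < 2 or len(ref) < 2:
        return None

    def scan(i, j):
        m = haps.shape[1]
        lo = s
        while lo > 0 and haps[i, lo - 1] == haps[j, lo - 1]:
            lo -= 1
        hi = s
        while hi < m - 1 and haps[i, hi + 1] == haps[j, hi + 1]:
            hi += 1
        return hi - lo + 1

    sl_alt = np.mean([scan(i, j) for a, i in enumerate(alt) for j in alt[a + 1:]])
    sl_ref = np.mean([scan(i, j) for a, i in enumerate(ref) for j in ref[a + 1:]])
    return np.log(sl_ref / sl_alt)


class TestPairIdentityLength:
    def test_identical_haplotypes_full_length(self):
        haps = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (2, 1))
        for s in range(5):
            assert pair_identity_length(haps, 0, 1, s) == 5

    def test_everywhere_different_gives_zero(self):
        haps = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        for s in range(3):
            assert pair_identity_length(haps, 0, 1, s) == 0

    def test_interior_mismatches_bound_interval(self):
        # differ at SNPs 0 and 6 (0-based); focal 3 -> shared run of 5
        a = np.array([0, 1, 0, 1, 1, 0, 0], dtype=np.int8)
        b = a.copy()
        b[0] ^= 1
        b[6] ^= 1
        haps = np.vstack([a, b])
        assert pair_identity_length(haps, 0, 1, 3) == 5

    def test_extension_monotone_in_added_flanks(self):
        # appending identical flanking SNPs never shortens interior intervals
        rng = np.random.default_rng(0)
        core = rng.integers(0, 2, size=(2, 9)).astype(np.int8)
        grown = np.hstack([core, np.ones((2, 3), dtype=np.int8)])
        for s in range(9):
            assert pair_identity_length(grown, 0, 1, s) >= pair_identity_length(core, 0, 1, s)


class TestRawNsl:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        haps = (rng.random((20, 200)) < rng.uniform(0.2, 0.8, 200)).astype(np.int8)
        table = HaplotypeTable(haplotypes=haps, positions=np.arange(1, 201) * 500)
        records = compute_nsl(table)
        checked = 0
        for s in range(0, 200, 7):
            want = brute_force_nsl(haps, s)
            rec = records[s]
            if want is None:
                assert not rec.defined
            else:
                assert rec.raw_nsl == pytest.approx(want, abs=1e-12)
                checked += 1
        assert checked > 10

    def test_symmetric_classes_give_zero(self):
        # ref and alt classes mirror images -> identical length distributions
        block = np.array(
            [[1, 1, 0, 1], [1, 0, 0, 1]], dtype=np.int8
        )
        haps = np.vstack([
            np.hstack([block, np.zeros((2, 1), np.int8), block]),
            np.hstack([1 - block, np.ones((2, 1), np.int8), 1 - block]),
        ])
        table = HaplotypeTable(haplotypes=haps, positions=np.arange(1, 10) * 10)
        rec = compute_nsl(table)[4]
        assert rec.defined
        assert rec.raw_nsl == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_alt_class_negative_score(self):
        rng = np.random.default_rng(2)
        m = 50
        alt_hap = rng.integers(0, 2, size=m).astype(np.int8)
        alt_hap[25] = 1
        haps = np.vstack(
            [np.tile(alt_hap, (4, 1))]
            + [rng.integers(0, 2, size=m).astype(np.int8) for _ in range(4)]
        )
        haps[4:, 25] = 0
        table = HaplotypeTable(haplotypes=haps, positions=np.arange(1, m + 1) * 100)
        rec = compute_nsl(table)[25]
        assert rec.defined
        assert rec.raw_nsl < 0  # alt haplotypes longer -> ln(ref/alt) < 0
        assert rec.raw_nsl == pytest.approx(brute_force_nsl(haps, 25), abs=1e-12)

    def test_singleton_undefined(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        haps[:, 10] = 0
        haps[0, 10] = 1  # singleton alt
        table = HaplotypeTable(haplotypes=haps, positions=np.arange(1, 31) * 100)
        assert not compute_nsl(table)[10].defined

    def test_allele_label_swap_flips_sign(self):
        rng = np.random.default_rng(4)
        haps = (rng.random((12, 60)) < rng.uniform(0.3, 0.7, 60)).astype(np.int8)
        table = HaplotypeTable(haplotypes=haps, positions=np.arange(1, 61) * 100)
        swapped = haps.copy()
        swapped[:, 30] ^= 1
        table2 = HaplotypeTable(haplotypes=swapped, positions=np.arange(1, 61) * 100)
        r1 = compute_nsl(table)[30]
        r2 = compute_nsl(table2)[30]
        if r1.defined:
            assert r2.raw_nsl == pytest.approx(-r1.raw_nsl, abs=1e-12)


class TestOrientation:
    def _rec(self, raw, freq):
        from driftscan.nsl import NslRecord

        return NslRecord(0, 2.0, 2.0, raw, raw, freq, defined=True)

    def test_negative_flipped(self):
        out = orient_positive(self._rec(-2.3, 0.8))
        assert out.oriented_score == pytest.approx(2.3)
        assert out.oriented_freq == pytest.approx(0.2)

    def test_positive_unchanged(self):
        out = orient_positive(self._rec(1.1, 0.4))
        assert out.oriented_score == 1.1 and out.oriented_freq == 0.4

    def test_idempotent(self):
        once = orient_positive(self._rec(-0.7, 0.6))
        twice = orient_positive(once)
        assert once == twice


class TestStandardizeBins:
    def _records(self, scores, freqs):
        from driftscan.nsl import NslRecord

        return [
            NslRecord(i, 2.0, 2.0, s, abs(s), f, defined=True)
            for i, (s, f) in enumerate(zip(scores, freqs))
        ]

    def test_zscore_moments_per_bin(self):
        rng = np.random.default_rng(5)
        recs = self._records(rng.normal(1, 0.5, 500), rng.uniform(0.01, 0.99, 500))
        out = standardize_bins(recs, n_bins=20)
        import collections

        by_bin = collections.defaultdict(list)
        for r in out:
            by_bin[r.bin_index].append(r.std_score)
        for b, zs in by_bin.items():
            assert abs(np.mean(zs)) < 1e-10
            assert abs(np.std(zs) - 1.0) < 1e-10

    def test_degenerate_bin_scores_zeroed(self):
        recs = self._records([1.0, 1.0, 1.0], [0.11, 0.12, 0.13])
        with pytest.warns(UserWarning):
            out = standardize_bins(recs, n_bins=20)
        assert all(r.std_score == 0.0 for r in out)

    def test_sparse_bins_merged(self):
        # one record at extreme frequency merges into nearest occupied bin
        recs = self._records([1.0, 1.2, 0.9, 2.0], [0.50, 0.52, 0.51, 0.99])
        out = standardize_bins(recs, n_bins=20)
        assert out[3].bin_index == out[0].bin_index

    def test_undefined_passthrough(self):
        from driftscan.nsl import NslRecord

        recs = self._records([1.0, 2.0, 1.5], [0.4, 0.45, 0.42])
        recs.append(NslRecord(9, float("nan"), float("nan"), float("nan"),
                              float("nan"), 0.5, defined=False))
        out = standardize_bins(recs)
        assert not out[-1].defined and np.isnan(out[-1].std_score)

    def test_neutral_upper_tail_small(self):
        cfg = syndata.HaploSimConfig(n_haplotypes=40, n_snps=800, ne=100,
                                     n_generations=15, recomb_prob=0.05, seed=6)
        table = syndata.simulate_haplotypes(cfg)
        records = [orient_positive(r) for r in compute_nsl(table)]
        out = standardize_bins(records)
        z = np.array([r.std_score for r in out if r.defined])
        assert (z > 2).mean() < 0.05


class TestCallCandidates:
    def _records(self, z_by_index):
        from driftscan.nsl import NslRecord

        return [
            NslRecord(i, 2.0, 2.0, 1.0, 1.0, 0.5, defined=True, bin_index=0, std_score=z)
            for i, z in z_by_index.items()
        ]

    def test_no_outliers_empty(self):
        recs = self._records({0: 1.0, 1: 2.0})
        assert call_candidates(recs, np.array([100, 200])) == []

    def test_strong_tier(self):
        positions = np.arange(1, 13) * 4000  # 12 SNPs in 48 kb
        zs = {i: 6.5 for i in range(11)}
        zs[11] = 5.5  # 12 candidates, 11 above 6
        regions = call_candidates(self._records(zs), positions)
        assert len(regions) == 1
        assert regions[0].tier == "strong"
        assert regions[0].n_candidate_snps == 12

    def test_gap_splits_regions(self):
        positions = np.array([1_000_000, 3_500_000])
        recs = self._records({0: 5.5, 1: 5.5})
        regions = call_candidates(recs, positions, gap_bp=1_000_000)
        assert len(regions) == 2
        assert all(r.n_candidate_snps == 1 for r in regions)


class TestImputationBias:
    def _region(self, start, end):
        from driftscan.nsl import CandidateRegion

        return CandidateRegion("1", start, end, 5, 0, 6.0, "candidate")

    def test_uniform_counts_pvalue_one(self):
        positions = np.arange(1, 101) * 1000
        counts = np.full(100, 3.0)
        rep = imputation_bias_check([self._region(10_000, 20_000)], positions, counts,
                                    n_permutations=500, seed=0)
        assert rep["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_extreme_region_flagged(self):
        rng = np.random.default_rng(7)
        positions = np.arange(1, 1001) * 1000
        counts = rng.poisson(2.6, 1000).astype(float)
        top = np.argsort(counts)[-40:]
        # move the 40 most-imputed SNPs into one region
        counts[:40], counts[top[:40]] = counts[top[:40]].copy(), counts[:40].copy()
        rep = imputation_bias_check([self._region(1000, 40_000)], positions, counts,
                                    n_permutations=2000, seed=1)
        assert rep["pvalue"].iloc[0] < 0.01

    def test_random_region_null_pvalues_spread(self):
        rng = np.random.default_rng(8)
        positions = np.arange(1, 501) * 1000
        counts = rng.poisson(2.6, 500).astype(float)
        pvals = []
        for rep_i in range(20):
            start = rng.integers(1, 450) * 1000
            rep = imputation_bias_check(
                [self._region(start, start + 20_000)], positions, counts,
                n_permutations=400, seed=rep_i,
            )
            pvals.append(rep["pvalue"].iloc[0])
        pvals = np.array(pvals)
        assert pvals.min() < 0.5 < pvals.max()
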