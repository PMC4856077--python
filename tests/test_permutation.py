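"""Permutation null machinery: marginals, determinism, calibration, gene blocks."""

import numpy as np
import pytest
from scipy import stats

from allelenet.ccc import compute_ccc_all, pairwise_ccc_arrays
from allelenet.genotype_io import MISSING, GenotypeMatrix, SnpRecord
from allelenet.permutation import (
    NoAdmissibleThresholdError,
    PermutationCalibration,
    calibrate,
    permute_columns,
    permute_gene_blocks,
    select_threshold,
)

from conftest import random_matrix


class TestPermuteColumns:
    def test_per_snp_genotype_counts_preserved(self, rng):
        m = random_matrix(rng, n_ind=25, n_snp=6, missing_rate=0.2)
        p = permute_columns(m, seed=5)
        for j in range(6):
            before = np.bincount(m.dosage[:, j] + 1, minlength=4)
            after = np.bincount(p.dosage[:, j] + 1, minlength=4)
            np.testing.assert_array_equal(before, after)

    def test_single_individual_is_identity(self, rng):
        m = random_matrix(rng, n_ind=1, n_snp=4, missing_rate=0.0)
        p = permute_columns(m, seed=3)
        np.testing.assert_array_equal(p.dosage, m.dosage)

    def test_fixed_seed_reproducible(self, rng):
        m = random_matrix(rng, n_ind=20, n_snp=5, missing_rate=0.1)
        a = permute_columns(m, seed=11)
        b = permute_columns(m, seed=11)
        np.testing.assert_array_equal(a.dosage, b.dosage)


class TestCalibrate:
    def test_matches_naive_recomputation(self, rng):
        """Trial counts agree with an explicit permute-then-recompute loop
        driven by the same seed substreams."""
        m = random_matrix(rng, n_ind=12, n_snp=6, missing_rate=0.1)
        thresholds = [0.5, 0.6, 0.7, 0.8]
        cal = calibrate(m, 50, thresholds, seed=7)
        streams = np.random.SeedSequence(7).spawn(50)
        for t in (0, 13, 49):
            trial_rng = np.random.default_rng(streams[t])
            perm = np.empty_like(m.dosage)
            for j in range(m.n_snps):
                perm[:, j] = m.dosage[trial_rng.permutation(m.n_individuals), j]
            elems = []
            pm = GenotypeMatrix(list(m.snps), list(m.individuals), perm)
            for vec in compute_ccc_all(pm):
                if vec.calculable:
                    elems.extend(vec.ccc)
            elems = np.array(elems)
            assert cal.max_ccc[t] == pytest.approx(elems.max())
            for k, thr in enumerate(thresholds):
                assert cal.counts[t, k] == (elems >= thr).sum()

    def test_unattainable_threshold_has_empty_tail(self, rng):
        m = random_matrix(rng, n_ind=15, n_snp=5, missing_rate=0.0)
        cal = calibrate(m, 30, [0.5, 1.01], seed=1)
        assert (cal.counts[:, 1] == 0).all()

    def test_counts_non_increasing_in_threshold(self, rng):
        m = random_matrix(rng, n_ind=15, n_snp=5, missing_rate=0.1)
        cal = calibrate(m, 40, np.arange(0.3, 1.0, 0.05), seed=2)
        assert (np.diff(cal.counts, axis=1) <= 0).all()

    def test_count_distribution_sums_to_one(self, rng):
        m = random_matrix(rng, n_ind=15, n_snp=5, missing_rate=0.1)
        cal = calibrate(m, 40, [0.5, 0.7], seed=2)
        for k in range(2):
            assert sum(cal.count_distribution(k).values()) == pytest.approx(1.0)


class TestSelectThreshold:
    def _cal(self, counts, thresholds):
        counts = np.asarray(counts)
        return PermutationCalibration(
            counts.shape[0], np.asarray(thresholds, float),
            np.zeros(counts.shape[0]), counts, seed=0,
        )

    def test_first_all_zero_candidate_selected(self):
        counts = np.array([[2, 1, 0, 0], [1, 0, 0, 0], [3, 1, 0, 0]])
        cal = self._cal(counts, [0.70, 0.80, 0.84, 0.90])
        assert select_threshold(cal, "zero-false-positives") == 0.84

    def test_all_zero_everywhere_gives_smallest(self):
        cal = self._cal(np.zeros((5, 3), dtype=int), [0.6, 0.7, 0.8])
        assert select_threshold(cal) == 0.6

    def test_mean_rate_rule(self):
        counts = np.array([[4, 1, 0], [2, 0, 0], [3, 2, 0], [3, 1, 0]])
        cal = self._cal(counts, [0.6, 0.7, 0.8])
        assert select_threshold(cal, "max-mean-rate", max_mean_rate=1.0) == 0.7
        assert select_threshold(cal, "max-mean-rate", max_mean_rate=0.0) == 0.8

    def test_no_admissible_threshold_signalled(self):
        cal = self._cal(np.ones((4, 2), dtype=int), [0.6, 0.7])
        with pytest.raises(NoAdmissibleThresholdError):
            select_threshold(cal, "zero-false-positives")


class TestGeneBlocks:
    def test_within_gene_ccc_preserved(self, rng):
        m = random_matrix(rng, n_ind=30, n_snp=8, missing_rate=0.1, n_genes=2)
        p = permute_gene_blocks(m, seed=9)
        ccc_before = pairwise_ccc_arrays(m.dosage)[0]
        ccc_after = pairwise_ccc_arrays(p.dosage)[0]
        gene_of = [s.gene for s in m.snps]
        for i in range(8):
            for j in range(i + 1, 8):
                if gene_of[i] == gene_of[j]:
                    np.testing.assert_allclose(
                        ccc_after[:, i, j], ccc_before[:, i, j], atol=1e-12
                    )

    def test_single_gene_is_row_permutation(self, rng):
        m = random_matrix(rng, n_ind=12, n_snp=4, missing_rate=0.1, n_genes=1)
        p = permute_gene_blocks(m, seed=4)
        before = {tuple(row) for row in m.dosage}
        after = {tuple(row) for row in p.dosage}
        assert before == after

    def test_unlabeled_snp_rejected(self, rng):
        m = random_matrix(rng, n_ind=10, n_snp=3, missing_rate=0.0)
        m.snps[1] = SnpRecord("rs2", gene="", allele_a="G", allele_b="T")
        with pytest.raises(ValueError, match="gene"):
            permute_gene_blocks(m, seed=0)

    def test_block_null_matches_full_independence_for_inter_gene_pairs(self, rng):
        """Mean inter-gene CCC under gene-block permutation equals the mean
        under SNP-column permutation (both destroy between-gene structure)."""
        m = random_matrix(rng, n_ind=40, n_snp=6, missing_rate=0.0, n_genes=2)
        # plant an inter-gene association
        m.dosage[:, 3] = m.dosage[:, 0]
        gene_of = [s.gene for s in m.snps]
        inter = [
            (i, j)
            for i in range(6)
            for j in range(i + 1, 6)
            if gene_of[i] != gene_of[j]
        ]

        def mean_inter(permuter, n_trials):
            vals = []
            for t in range(n_trials):
                p = permuter(m, seed=t)
                ccc = pairwise_ccc_arrays(p.dosage)[0]
                vals.append(np.mean([ccc[:, i, j].max() for i, j in inter]))
            return np.array(vals)

        block = mean_inter(permute_gene_blocks, 200)
        full = mean_inter(permute_columns, 200)
        assert stats.ttest_ind(block, full).pvalue > 0.01


class TestNullCongruence:
    def test_independent_snps_match_their_own_permutation_null(self, rng):
        """Supra-threshold rates on an independent-SNP matrix and on its
        column-permuted self are statistically indistinguishable."""
        m = random_matrix(rng, n_ind=60, n_snp=8, missing_rate=0.0)
        thr = [0.55]
        a = calibrate(m, 150, thr, seed=21)
        b = calibrate(permute_columns(m, seed=99), 150, thr, seed=22)
        x, nx = int(a.counts.sum()), a.counts.size
        y, ny = int(b.counts.sum()), b.counts.size
        res = stats.poisson_means_test(x, nx, y, ny)
        assert res.pvalue > 0.01
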