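"""Scalar LD: EM haplotype frequencies, r²/D′, step-down resampling."""

import itertools

import numpy as np
import pytest

from allelenet.genotype_io import MISSING
from allelenet.scalar_ld import (
    em_haplotype_freqs,
    ld_all,
    ld_pair,
    pairwise_ld_arrays,
    stepdown_adjust,
)

from conftest import random_matrix


def _genotypes_from_haplotypes(rng, hap_freqs, n):
    """Draw n individuals as two gametes from (AB, Ab, aB, ab) frequencies.

    Returns dosage columns (counting the lowercase alleles) and the raw
    gamete draws.
    """
    gametes = rng.choice(4, size=(n, 2), p=hap_freqs)
    # gamete index: bit 0 (value & 2) -> a at SNP1? encode: 0=AB,1=Ab,2=aB,3=ab
    a1 = (gametes >= 2).sum(axis=1)       # copies of a
    a2 = (gametes % 2).sum(axis=1)        # copies of b
    return a1, a2, gametes


class TestEMHaplotypes:
    def test_unambiguous_data_equals_direct_gamete_counts(self):
        # no double heterozygotes: genotypes (0,0), (0,2), (2,2), (1,0)
        g1 = np.array([0, 0, 2, 1, 1])
        g2 = np.array([0, 2, 2, 0, 2])
        freqs, n = em_haplotype_freqs(g1, g2)
        assert n == 5
        # gametes: AB,AB | Ab,Ab | ab,ab | AB,aB | Ab,ab
        np.testing.assert_allclose(freqs, [3 / 10, 3 / 10, 1 / 10, 3 / 10], atol=1e-9)

    def test_perfect_coupling(self):
        g = np.array([0, 0, 2, 2, 0, 2])
        pair = ld_pair(g, g)
        assert pair.r_squared == pytest.approx(1.0, abs=1e-9)
        assert pair.d_prime == pytest.approx(1.0, abs=1e-9)
        assert pair.hap_freqs[0] == pytest.approx(0.5, abs=1e-9)  # p(AB) = p(A)

    @pytest.mark.parametrize("seed", range(5))
    def test_em_matches_profile_likelihood_grid(self, seed):
        """EM optimum agrees to 1e-4 with a dense 1-D likelihood grid over
        p(AB) at the observed allele frequencies (the ML margins)."""
        rng = np.random.default_rng(seed)
        g1 = rng.integers(0, 3, 8)
        g2 = rng.integers(0, 3, 8)
        g1[0] = g2[0] = 1  # force a double heterozygote
        if len(set(g1)) == 1 or len(set(g2)) == 1:
            g1[1], g2[1] = 2, 0
        freqs, n = em_haplotype_freqs(g1, g2, tol=1e-12)
        pA = 1 - g1.mean() / 2
        pB = 1 - g2.mean() / 2

        def loglik(pab_):
            p = np.array(
                [pab_, pA - pab_, pB - pab_, 1 - pA - pB + pab_]
            )
            if (p < -1e-12).any():
                return -np.inf
            p = np.clip(p, 1e-12, 1)
            cell = {
                (0, 0): p[0] ** 2, (0, 1): 2 * p[0] * p[1], (0, 2): p[1] ** 2,
                (1, 0): 2 * p[0] * p[2], (1, 2): 2 * p[1] * p[3],
                (2, 0): p[2] ** 2, (2, 1): 2 * p[2] * p[3], (2, 2): p[3] ** 2,
                (1, 1): 2 * (p[0] * p[3] + p[1] * p[2]),
            }
            return sum(np.log(cell[(a, b)]) for a, b in zip(g1, g2))

        lo = max(0.0, pA + pB - 1)
        hi = min(pA, pB)
        grid = np.linspace(lo, hi, 20001)
        best = grid[int(np.argmax([loglik(x) for x in grid]))]
        assert freqs[0] == pytest.approx(best, abs=1e-4)

    def test_monomorphic_pair_not_calculable(self):
        g1 = np.zeros(10, dtype=int)
        g2 = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        pair = ld_pair(g1, g2)
        assert not pair.calculable and np.isnan(pair.r_squared)


class TestLDStatistics:
    def test_r2_matches_phased_gamete_correlation(self, rng):
        hap = np.array([0.4, 0.1, 0.2, 0.3])  # D = 0.4 - 0.5*0.6 = 0.1
        g1, g2, gametes = _genotypes_from_haplotypes(rng, hap, 6000)
        pair = ld_pair(g1, g2)
        ind_a = (gametes >= 2).ravel().astype(float)
        ind_b = (gametes % 2).ravel().astype(float)
        gamete_r2 = np.corrcoef(ind_a, ind_b)[0, 1] ** 2
        # EM sees genotypes only; both are estimates of the same gametic r²
        assert pair.r_squared == pytest.approx(gamete_r2, abs=0.03)
        true_r2 = 0.1**2 / (0.5 * 0.5 * 0.6 * 0.4)
        assert pair.r_squared == pytest.approx(true_r2, abs=0.03)

    def test_equilibrium_pair_has_near_zero_r2(self, rng):
        g1 = rng.binomial(2, 0.4, 5000)
        g2 = rng.binomial(2, 0.6, 5000)
        assert ld_pair(g1, g2).r_squared < 0.01

    def test_dprime_bounds_and_dominates_r(self, rng):
        for _ in range(15):
            m = random_matrix(rng, n_ind=40, n_snp=2, missing_rate=0.1)
            pair = ld_pair(m.dosage[:, 0], m.dosage[:, 1])
            if not pair.calculable:
                continue
            assert 0 <= pair.r_squared <= 1 + 1e-9
            assert 0 <= pair.d_prime <= 1 + 1e-9
            assert pair.d_prime >= np.sqrt(pair.r_squared) - 1e-9

    def test_all_pairs_table_is_complete(self, rng):
        m = random_matrix(rng, n_ind=12, n_snp=64, missing_rate=0.02)
        tab = ld_all(m)
        assert len(tab) == 2016

    def test_vectorised_matches_pair_path(self, rng):
        m = random_matrix(rng, n_ind=30, n_snp=6, missing_rate=0.15)
        r2, dp, poly = pairwise_ld_arrays(m.dosage)
        for i in range(6):
            for j in range(i + 1, 6):
                pair = ld_pair(m.dosage[:, i], m.dosage[:, j])
                if pair.calculable:
                    assert r2[i, j] == pytest.approx(pair.r_squared, abs=1e-8)
                    assert dp[i, j] == pytest.approx(pair.d_prime, abs=1e-8)
                else:
                    assert not poly[i, j]


class TestStepdown:
    def test_single_hypothesis_equals_raw_permutation_p(self, rng):
        obs = np.array([0.7])
        null = rng.random((200, 1))
        adj = stepdown_adjust(obs, null)
        assert adj[0] == pytest.approx((null[:, 0] >= 0.7).mean())

    def test_adjusted_p_non_decreasing_along_ordering(self, rng):
        for _ in range(10):
            obs = rng.random(8)
            null = rng.random((100, 8))
            adj = stepdown_adjust(obs, null)
            order = np.argsort(-obs)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_naive_enumeration_at_four_individuals(self):
        """Three pairwise statistics under the fully enumerated permutation
        null of a 4-individual matrix: the step-down adjustment agrees with
        an explicit loop implementation."""
        g0 = np.array([0, 1, 2, 2])
        g1 = np.array([0, 2, 1, 2])
        g2 = np.array([2, 0, 1, 0])

        def stat(a, b):
            pair = ld_pair(a, b)
            return pair.r_squared if pair.calculable else np.nan

        observed = np.array([stat(g0, g1), stat(g0, g2), stat(g1, g2)])
        perms = list(itertools.permutations(range(4)))
        null = np.empty((len(perms) ** 2, 3))
        k = 0
        for p1 in perms:
            for p2 in perms:
                h1, h2 = g1[list(p1)], g2[list(p2)]
                null[k] = [stat(g0, h1), stat(g0, h2), stat(h1, h2)]
                k += 1
        adj = stepdown_adjust(observed, null)

        # independent naive step-down: sort, tail maxima by loops
        order = sorted(range(3), key=lambda i: -observed[i])
        naive = np.empty(3)
        prev = 0.0
        for rank, idx in enumerate(order):
            tail = [order[r] for r in range(rank, 3)]
            count = 0
            for row in np.nan_to_num(null, nan=-np.inf):
                if max(row[t] for t in tail) >= observed[idx]:
                    count += 1
            p = max(prev, count / len(null))
            naive[idx] = p
            prev = p
        np.testing.assert_allclose(adj, naive, atol=1e-12)

    def test_minp_variant_monotone_and_bounded(self, rng):
        obs = rng.random(6)
        null = rng.random((300, 6))
        adj = stepdown_adjust(obs, null, method="minP")
        assert ((0 <= adj) & (adj <= 1)).all()
        order = np.argsort((null >= obs[None, :]).mean(axis=0))
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            stepdown_adjust(np.array([0.5]), np.empty((0, 1)))
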