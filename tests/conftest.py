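"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from allelenet.genotype_io import MISSING, GenotypeMatrix, PopulationPanel, SnpRecord


@pytest.fixture
def worked_example() -> tuple[np.ndarray, np.ndarray]:
    """The published 10-individual two-SNP example: one Aa/bb, one AA/Bb,
    eight AA/bb.  Dosage counts the lowercase allele (a, b)."""
    g1 = np.array([1] + [0] * 9)          # SNP 1: one Aa, nine AA
    g2 = np.array([2, 1] + [2] * 8)       # SNP 2: bb, Bb, eight bb
    return g1, g2


def random_matrix(
    rng: np.random.Generator,
    n_ind: int = 20,
    n_snp: int = 10,
    missing_rate: float = 0.1,
    n_genes: int = 2,
) -> GenotypeMatrix:
    """A random genotype matrix with missingness, for round-trip/property tests."""
    dosage = rng.integers(0, 3, size=(n_ind, n_snp)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        # keep at least one scored call per SNP
        for j in range(n_snp):
            if mask[:, j].all():
                mask[rng.integers(n_ind), j] = False
        dosage = np.where(mask, MISSING, dosage).astype(np.int8)
    alleles = [("A", "C"), ("G", "T"), ("A", "G"), ("C", "T")]
    snps = [
        SnpRecord(
            snp_id=f"rs{j + 1}",
            chromosome=str(j % n_genes + 1),
            position=100 * (j + 1),
            gene=f"gene{j % n_genes + 1}",
            allele_a=alleles[j % 4][0],
            allele_b=alleles[j % 4][1],
        )
        for j in range(n_snp)
    ]
    individuals = [f"ind{i + 1}" for i in range(n_ind)]
    return GenotypeMatrix(snps, individuals, dosage)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def brute_force_ccc(
    g_i: np.ndarray, g_j: np.ndarray, q: float = 1.5
) -> tuple[np.ndarray, np.ndarray, int]:
    """Independent CCC oracle: explicit per-individual loops, frequencies
    recomputed from raw allele counts among pairwise-complete individuals.

    Returns (r, ccc, n_complete) in combination order (AB, Ab, aB, ab) with
    uppercase = the allele whose dosage is ``2 - d``.
    """
    contrib = np.zeros(4)
    copies_a_i = copies_a_j = 0  # copies of the uppercase allele
    n = 0
    for di, dj in zip(g_i, g_j):
        if di == MISSING or dj == MISSING:
            continue
        n += 1
        copies_a_i += 2 - di
        copies_a_j += 2 - dj
        ui, vi = (2 - di) / 2.0, di / 2.0
        uj, vj = (2 - dj) / 2.0, dj / 2.0
        contrib += [ui * uj, ui * vj, vi * uj, vi * vj]
    if n == 0:
        raise ValueError("incalculable")
    r = contrib / n
    fA_i = copies_a_i / (2.0 * n)
    fA_j = copies_a_j / (2.0 * n)
    freqs_i = [fA_i, fA_i, 1 - fA_i, 1 - fA_i]
    freqs_j = [fA_j, 1 - fA_j, fA_j, 1 - fA_j]
    ccc = np.array(
        [
            4.5 * r[t] * (1 - freqs_i[t] / q) * (1 - freqs_j[t] / q)
            for t in range(4)
        ]
    )
    return r, ccc, n
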