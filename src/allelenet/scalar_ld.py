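"""Scalar linkage disequilibrium (r², D′) on unphased genotypes.

Haplotype frequencies for a SNP pair are estimated by expectation-
maximisation: every genotype pair except the double heterozygote resolves
its two gametes unambiguously; the double heterozygote is a phase mixture
of (AB, ab) and (Ab, aB), apportioned each E-step by the current haplotype
frequencies.  From the EM frequencies,

    D  = p(AB) - p(A) p(B)
    r² = D² / (p(A) p(a) p(B) p(b))
    D′ = |D| / D_max,   D_max the admissible bound given allele frequencies.

Pairs where either SNP is monomorphic among the pairwise-complete
individuals are flagged incalculable and excluded before any multiplicity
adjustment.

Family-wise significance over all pairs is assessed by permutation
(per-SNP columns, or intact per-gene blocks to focus power on unlinked
pairs) with the Westfall–Young step-down resampling correction: hypotheses
are ordered by decreasing observed statistic and each adjusted p is the
proportion of null trials whose maximum over the remaining hypotheses
reaches the observed value, with monotonicity enforced down the ordering.
A minP variant (step-down on per-pair permutation p-values) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from .permutation import _permute_columns_array, _permute_gene_blocks_array

__all__ = [
    "LDPair",
    "em_haplotype_freqs",
    "ld_pair",
    "ld_all",
    "pairwise_ld_arrays",
    "ld_permutation_null",
    "stepdown_adjust",
    "ld_significance",
]


@dataclass
class LDPair:
    """Scalar LD summary for one SNP pair.

    ``hap_freqs`` is (p_AB, p_Ab, p_aB, p_ab) with uppercase = allele_a of
    each SNP; NaN statistics where ``calculable`` is False.
    """

    snp_i: str
    snp_j: str
    hap_freqs: np.ndarray
    r_squared: float
    d_prime: float
    n_complete: int
    calculable: bool


def _pair_genotype_counts(g_i: np.ndarray, g_j: np.ndarray) -> np.ndarray:
    """3x3 table of genotype-pair counts over pairwise-complete individuals."""
    ok = (g_i != MISSING) & (g_j != MISSING)
    counts = np.zeros((3, 3))
    for a, b in zip(g_i[ok], g_j[ok]):
        counts[int(a), int(b)] += 1
    return counts


def _em_on_counts(
    counts: np.ndarray, tol: float, max_iter: int
) -> np.ndarray:
    """Vectorised EM; ``counts`` has shape (3, 3, ...) and broadcasts.

    Returns haplotype frequencies with shape (4, ...), order
    (AB, Ab, aB, ab).
    """
    n = counts
    c_ab_known = np.stack(
        [
            2 * n[0, 0] + n[0, 1] + n[1, 0],
            2 * n[0, 2] + n[0, 1] + n[1, 2],
            2 * n[2, 0] + n[1, 0] + n[2, 1],
            2 * n[2, 2] + n[2, 1] + n[1, 2],
        ]
    ).astype(float)
    n_dh = n[1, 1].astype(float)  # double heterozygotes: ambiguous phase
    total = c_ab_known.sum(axis=0) + 2 * n_dh
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.full(np.shape(n_dh), 0.5)
        p = (c_ab_known + np.stack([n_dh * x, n_dh * (1 - x), n_dh * (1 - x), n_dh * x])) / total
        for _ in range(max_iter):
            denom = p[0] * p[3] + p[1] * p[2]
            x = np.where(denom > 0, p[0] * p[3] / np.where(denom > 0, denom, 1.0), 0.5)
            new_p = (c_ab_known + np.stack([n_dh * x, n_dh * (1 - x), n_dh * (1 - x), n_dh * x])) / total
            done = np.all(np.nan_to_num(np.abs(new_p - p), nan=0.0) < tol)
            p = new_p
            if done:
                break
    return p


def em_haplotype_freqs(
    g_i: np.ndarray,
    g_j: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> tuple[np.ndarray, int]:
    """Maximum-likelihood haplotype frequencies for one unphased SNP pair.

    Returns (freqs (4,), n_complete).  Raises ValueError when no individual
    is complete at both SNPs.
    """
    counts = _pair_genotype_counts(np.asarray(g_i), np.asarray(g_j))
    n_complete = int(counts.sum())
    if n_complete == 0:
        raise ValueError("no pairwise-complete individuals")
    return _em_on_counts(counts, tol, max_iter), n_complete


def _stats_from_hap(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(r², D′, calculable) from haplotype frequencies of shape (4, ...)."""
    pA = p[0] + p[1]
    pB = p[0] + p[2]
    pa, pb = 1 - pA, 1 - pB
    with np.errstate(invalid="ignore", divide="ignore"):
        D = p[0] - pA * pB
        denom = pA * pa * pB * pb
        poly = denom > 0
        r2 = np.where(poly, D**2 / np.where(poly, denom, 1.0), np.nan)
        dmax = np.where(D >= 0, np.minimum(pA * pb, pa * pB), np.minimum(pA * pB, pa * pb))
        dprime = np.where(
            poly, np.abs(D) / np.where(dmax > 0, dmax, 1.0), np.nan
        )
        dprime = np.where(poly & (dmax == 0), 0.0, dprime)
    return r2, dprime, poly


def ld_pair(
    g_i: np.ndarray,
    g_j: np.ndarray,
    snp_i: str = "snp_i",
    snp_j: str = "snp_j",
    method: str = "em",
) -> LDPair:
    """r² and D′ for one pair of dosage columns.

    ``method="em"`` (default) computes both from EM haplotype frequencies;
    ``method="composite"`` replaces r² with the squared Pearson correlation
    of the dosage vectors (the genotypic composite measure), D′ stays
    EM-based.
    """
    freqs, n = em_haplotype_freqs(g_i, g_j)
    r2, dprime, poly = _stats_from_hap(freqs)
    r2, dprime, calculable = float(r2), float(dprime), bool(poly)
    if method == "composite" and calculable:
        ok = (np.asarray(g_i) != MISSING) & (np.asarray(g_j) != MISSING)
        r2 = float(np.corrcoef(g_i[ok], g_j[ok])[0, 1] ** 2)
    elif method not in ("em", "composite"):
        raise ValueError(f"unknown method {method!r}")
    if not calculable:
        r2 = dprime = float("nan")
    return LDPair(snp_i, snp_j, freqs, r2, dprime, n, calculable)


def _all_pair_counts(X: np.ndarray) -> np.ndarray:
    """Genotype-pair count tables for all SNP pairs: shape (3, 3, p, p)."""
    G = [(X == k).astype(float) for k in (0, 1, 2)]
    p = X.shape[1]
    out = np.empty((3, 3, p, p))
    for a in range(3):
        for b in range(3):
            out[a, b] = G[a].T @ G[b]
    return out


def pairwise_ld_arrays(
    dosage: np.ndarray, tol: float = 1e-10, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs (r², D′, calculable) matrices of shape (p, p)."""
    counts = _all_pair_counts(np.asarray(dosage))
    p = _em_on_counts(counts, tol, max_iter)
    return _stats_from_hap(p)


def ld_all(matrix: GenotypeMatrix, method: str = "em") -> pd.DataFrame:
    """Scalar LD for every unordered SNP pair of a matrix.

    Returns a DataFrame with columns snp_i, snp_j, r2, dprime, n_complete,
    calculable; all C(p, 2) pairs are present.
    """
    X = matrix.dosage
    r2, dprime, poly = pairwise_ld_arrays(X)
    if method == "composite":
        # composite r²: squared dosage correlation on pairwise-complete sets
        scored = (X != MISSING)
        M = scored.astype(float)
        Xz = np.where(scored, X, 0).astype(float)
        N = M.T @ M
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = Xz.T @ M
            sxx = (Xz**2).T @ M
            sxy = Xz.T @ Xz
            cov = sxy / N - (sx / N) * (sx / N).T
            var_i = sxx / N - (sx / N) ** 2
            r2 = cov**2 / (var_i * var_i.T)
    elif method != "em":
        raise ValueError(f"unknown method {method!r}")
    scored = (X != MISSING).astype(int)
    N = scored.T @ scored
    iu, ju = np.triu_indices(matrix.n_snps, k=1)
    ids = matrix.snp_ids
    return pd.DataFrame(
        {
            "snp_i": [ids[i] for i in iu],
            "snp_j": [ids[j] for j in ju],
            "r2": np.where(poly[iu, ju], r2[iu, ju], np.nan),
            "dprime": np.where(poly[iu, ju], dprime[iu, ju], np.nan),
            "n_complete": N[iu, ju],
            "calculable": poly[iu, ju],
        }
    )


def ld_permutation_null(
    matrix: GenotypeMatrix,
    n_trials: int,
    seed: int,
    unit: str = "snp",
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Null distributions of r² and D′ over all pairs by permutation.

    Returns (null_r2, null_dprime, (iu, ju)) with null arrays of shape
    (n_trials, n_pairs) in upper-triangle pair order.  ``unit`` selects
    per-SNP column permutation or intact per-gene block permutation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    X = matrix.dosage
    p = matrix.n_snps
    iu, ju = np.triu_indices(p, k=1)
    gene_of = [s.gene for s in matrix.snps]
    if unit == "gene" and any(not g for g in gene_of):
        raise ValueError("gene-unit permutation requires gene labels on every SNP")
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    null_r2 = np.empty((n_trials, len(iu)))
    null_dp = np.empty((n_trials, len(iu)))
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if unit == "gene":
            perm = _permute_gene_blocks_array(X, gene_of, rng)
        else:
            perm = _permute_columns_array(X, rng)
        r2, dprime, poly = pairwise_ld_arrays(perm)
        null_r2[t] = np.where(poly[iu, ju], r2[iu, ju], np.nan)
        null_dp[t] = np.where(poly[iu, ju], dprime[iu, ju], np.nan)
    return null_r2, null_dp, (iu, ju)


def stepdown_adjust(
    observed: np.ndarray, null_trials: np.ndarray, method: str = "maxT"
) -> np.ndarray:
    """Westfall–Young step-down adjusted p-values.

    Parameters
    ----------
    observed
        Observed statistics, shape (m,).  Larger = more extreme.
    null_trials
        Null statistics, shape (n_trials, m), hypothesis-aligned with
        ``observed``.  NaNs (incalculable under a permutation) are treated
        as non-extreme.
    method
        ``"maxT"`` steps down on the statistics themselves; ``"minP"``
        first converts to per-hypothesis permutation p-values and steps
        down on their minima.

    Adjusted p-values are returned in the input hypothesis order, with
    monotonicity enforced along the step-down ordering.
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null_trials, dtype=float)
    if null.ndim != 2 or null.shape[1] != observed.size:
        raise ValueError("null_trials must have shape (n_trials, len(observed))")
    if null.shape[0] == 0:
        raise ValueError("at least one null trial is required")
    n_trials, m = null.shape

    if method == "maxT":
        order = np.argsort(-observed, kind="stable")
        null_ord = np.nan_to_num(null[:, order], nan=-np.inf)
        obs_ord = observed[order]
        # successive maxima over hypotheses k..m-1, built from the tail
        tail_max = np.maximum.accumulate(null_ord[:, ::-1], axis=1)[:, ::-1]
        p_ord = (tail_max >= obs_ord[None, :]).mean(axis=0)
        p_ord = np.maximum.accumulate(p_ord)  # enforce monotone non-decreasing
        out = np.empty(m)
        out[order] = p_ord
        return out
    if method == "minP":
        nan_null = np.nan_to_num(null, nan=-np.inf)
        # per-hypothesis raw p of observed and of every null draw (rank based)
        raw = (nan_null >= observed[None, :]).mean(axis=0)
        null_p = np.empty_like(nan_null)
        for j in range(m):
            col = nan_null[:, j]
            ranks = np.searchsorted(np.sort(col), col, side="left")
            null_p[:, j] = (n_trials - ranks) / n_trials
        order = np.argsort(raw, kind="stable")
        tail_min = np.minimum.accumulate(null_p[:, order][:, ::-1], axis=1)[:, ::-1]
        p_ord = (tail_min <= raw[order][None, :]).mean(axis=0)
        p_ord = np.maximum.accumulate(p_ord)
        out = np.empty(m)
        out[order] = p_ord
        return out
    raise ValueError(f"unknown method {method!r}")


def ld_significance(
    matrix: GenotypeMatrix,
    n_trials: int = 1000,
    seed: int = 0,
    unit: str = "snp",
    method: str = "maxT",
    alpha: float = 0.05,
    inter_gene_only: bool = False,
) -> pd.DataFrame:
    """Full scalar-LD scan with permutation step-down multiplicity control.

    Incalculable pairs are excluded before adjustment.  With
    ``inter_gene_only`` (natural with ``unit="gene"``), only pairs whose
    SNPs sit in different genes enter the family being tested.  Returns the
    pair table with raw and adjusted p-values and significance flags for
    both r² and D′, separately adjusted.
    """
    obs = ld_all(matrix)
    null_r2, null_dp, (iu, ju) = ld_permutation_null(matrix, n_trials, seed, unit=unit)
    gene_of = [s.gene for s in matrix.snps]
    same_gene = np.array([gene_of[i] == gene_of[j] for i, j in zip(iu, ju)])
    in_family = obs["calculable"].to_numpy()
    if inter_gene_only:
        in_family = in_family & ~same_gene

    for stat, null in (("r2", null_r2), ("dprime", null_dp)):
        values = obs[stat].to_numpy()
        raw = np.full(len(obs), np.nan)
        adj = np.full(len(obs), np.nan)
        if in_family.any():
            fam_null = np.nan_to_num(null[:, in_family], nan=-np.inf)
            fam_obs = values[in_family]
            raw[in_family] = (fam_null >= fam_obs[None, :]).mean(axis=0)
            adj[in_family] = stepdown_adjust(fam_obs, fam_null, method=method)
        obs[f"p_raw_{stat}"] = raw
        obs[f"p_adj_{stat}"] = adj
        obs[f"significant_{stat}"] = adj <= alpha
    obs["in_family"] = in_family
    return obs
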