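"""The Custom Correlation Coefficient (CCC): a vector measure of allele-specific LD.

For a pair of biallelic SNPs *i* and *j* with alleles (A, a) and (B, b), the
CCC is a four-element vector indexed by the allelic combinations
(AB, Ab, aB, ab):

    CCC_ij[t] = (9/2) * R_ij[t] * ff_it * ff_jt

where R_ij[t] is the average, over individuals scored at both SNPs, of the
per-individual contribution to combination *t* — the product of the
individual's within-genotype allele frequencies (dosage/2 for the B-type
allele, 1 - dosage/2 for the A-type allele) — and ff_kt = 1 - f_kt / q is a
frequency damping factor built from the frequency f_kt of the combination's
allele at SNP *k*, with weighting factor q (default 1.5).  The 9/2 scale is a
fixed constant chosen so that values fall in [0, 1] in practice.

Because each element isolates one allelic combination, the CCC retains phase
information that scalar LD measures (r², D′) collapse: two complementary
haplotypes at the same SNP pair surface as two different large elements.

Missing data are handled pairwise-complete: an individual missing at either
SNP contributes to neither R nor the allele frequencies of that pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SCALE",
    "DEFAULT_Q",
    "COMBO_ORDER",
    "CCCVector",
    "IncalculablePairError",
    "pair_r_vector",
    "compute_ccc_pair",
    "compute_ccc_all",
    "pairwise_ccc_arrays",
    "iter_supra_threshold_edges",
]

#: Empirical scaling constant of the CCC formula.
SCALE: float = 9.0 / 2.0
#: Default frequency-factor weighting.
DEFAULT_Q: float = 1.5
#: Combination order: first symbol from SNP i, second from SNP j;
#: uppercase slot = allele_a, lowercase slot = allele_b.
COMBO_ORDER: tuple[str, str, str, str] = ("AB", "Ab", "aB", "ab")

FreqMode = Literal["pairwise", "per-snp"]


class IncalculablePairError(ValueError):
    """No individual is scored at both SNPs of a pair."""


@dataclass
class CCCVector:
    """CCC result for one unordered SNP pair.

    ``combos`` spells each combination in the SNPs' own allele symbols, in
    :data:`COMBO_ORDER`.  ``f_i``/``f_j`` are the (allele_a, allele_b)
    frequencies at each SNP among the pairwise-complete individuals.
    An incalculable pair (``n_complete == 0``) is kept with
    ``calculable=False`` and NaN statistics rather than dropped.
    """

    snp_i: str
    snp_j: str
    combos: tuple[tuple[str, str], ...]
    r: np.ndarray
    ccc: np.ndarray
    n_complete: int
    f_i: np.ndarray
    f_j: np.ndarray
    q: float = DEFAULT_Q
    scale: float = SCALE

    @property
    def calculable(self) -> bool:
        return self.n_complete > 0

    @property
    def monomorphic(self) -> bool:
        """True if either SNP shows only one allele among complete individuals."""
        return bool(
            self.n_complete > 0
            and (np.isclose(self.f_i, 0).any() or np.isclose(self.f_j, 0).any())
        )

    def max_element(self) -> float:
        return float(np.max(self.ccc)) if self.calculable else float("nan")


def _within_individual_freqs(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual frequencies of allele_a (u) and allele_b (v), plus scored mask."""
    g = np.asarray(g)
    scored = g != MISSING
    d = np.where(scored, g, 0).astype(float)
    v = d / 2.0
    u = 1.0 - v
    return np.where(scored, u, 0.0), np.where(scored, v, 0.0), scored


def pair_r_vector(g_i: np.ndarray, g_j: np.ndarray) -> tuple[np.ndarray, int]:
    """Average per-individual combination contributions R for one SNP pair.

    Returns the four-element r vector in :data:`COMBO_ORDER` and the number
    of pairwise-complete individuals.  Raises
    :class:`IncalculablePairError` when no individual is complete.
    """
    u_i, v_i, m_i = _within_individual_freqs(g_i)
    u_j, v_j, m_j = _within_individual_freqs(g_j)
    both = m_i & m_j
    n = int(both.sum())
    if n == 0:
        raise IncalculablePairError("no individual scored at both SNPs")
    r = np.array(
        [
            (u_i * u_j)[both].sum(),
            (u_i * v_j)[both].sum(),
            (v_i * u_j)[both].sum(),
            (v_i * v_j)[both].sum(),
        ]
    ) / n
    return r, n


def compute_ccc_pair(
    g_i: np.ndarray,
    g_j: np.ndarray,
    q: float = DEFAULT_Q,
    snp_i: str = "snp_i",
    snp_j: str = "snp_j",
    alleles_i: tuple[str, str] = ("A", "a"),
    alleles_j: tuple[str, str] = ("B", "b"),
    freq_mode: FreqMode = "pairwise",
) -> CCCVector:
    """Compute the CCC vector for a single pair of dosage columns.

    ``freq_mode`` selects the individual set over which the frequency
    factors' allele frequencies are taken: ``"pairwise"`` (default) uses the
    pairwise-complete set — the same individuals that define R — while
    ``"per-snp"`` uses each SNP's own non-missing individuals.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    combos = tuple(
        (alleles_i[t // 2], alleles_j[t % 2]) for t in range(4)
    )
    try:
        r, n = pair_r_vector(g_i, g_j)
    except IncalculablePairError:
        nan4 = np.full(4, np.nan)
        return CCCVector(snp_i, snp_j, combos, nan4, nan4.copy(), 0,
                         np.full(2, np.nan), np.full(2, np.nan), q)

    u_i, v_i, m_i = _within_individual_freqs(g_i)
    u_j, v_j, m_j = _within_individual_freqs(g_j)
    if freq_mode == "pairwise":
        both = m_i & m_j
        fa_i = u_i[both].mean()
        fa_j = u_j[both].mean()
    elif freq_mode == "per-snp":
        fa_i = u_i[m_i].mean()
        fa_j = u_j[m_j].mean()
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    f_i = np.array([fa_i, 1.0 - fa_i])
    f_j = np.array([fa_j, 1.0 - fa_j])

    ff_i = 1.0 - f_i / q
    ff_j = 1.0 - f_j / q
    ccc = np.array([SCALE * r[t] * ff_i[t // 2] * ff_j[t % 2] for t in range(4)])
    return CCCVector(snp_i, snp_j, combos, r, ccc, n, f_i, f_j, q)


def pairwise_ccc_arrays(
    dosage: np.ndarray, q: float = DEFAULT_Q, freq_mode: FreqMode = "pairwise"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs CCC on a raw dosage array.

    Parameters
    ----------
    dosage
        ``(n_individuals, n_snps)`` array with entries 0/1/2 or MISSING.

    Returns
    -------
    ccc : ``(4, p, p)`` array; ``ccc[t, i, j]`` is element *t* (COMBO_ORDER)
        for the ordered pair (i, j); NaN where no complete individual.
    r : ``(4, p, p)`` array of R values.
    n_complete : ``(p, p)`` integer array of pairwise-complete counts.

    The implementation reduces the whole computation to a handful of
    ``(p, n) x (n, p)`` matrix products, which is what makes million-trial
    permutation calibration tractable.
    """
    X = np.asarray(dosage)
    scored = (X != MISSING)
    M = scored.astype(float)
    V = np.where(scored, X, 0).astype(float) / 2.0  # allele_b within-ind freq
    U = M - V                                        # allele_a within-ind freq

    N = M.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.stack([U.T @ U, U.T @ V, V.T @ U, V.T @ V]) / N
        if freq_mode == "pairwise":
            FA = (U.T @ M) / N           # FA[i, j]: freq of allele_a at i on complete(i,j)
            FA_j = FA.T                  # freq of allele_a at j on the same set
        elif freq_mode == "per-snp":
            fa = U.sum(axis=0) / M.sum(axis=0)
            p = X.shape[1]
            FA = np.broadcast_to(fa[:, None], (p, p))
            FA_j = np.broadcast_to(fa[None, :], (p, p))
        else:
            raise ValueError(f"unknown freq_mode {freq_mode!r}")
        ffA_i, ffa_i = 1.0 - FA / q, 1.0 - (1.0 - FA) / q
        ffA_j, ffa_j = 1.0 - FA_j / q, 1.0 - (1.0 - FA_j) / q
        ccc = SCALE * r * np.stack(
            [ffA_i * ffA_j, ffA_i * ffa_j, ffa_i * ffA_j, ffa_i * ffa_j]
        )
    return ccc, r, N.astype(int)


def compute_ccc_all(
    matrix: GenotypeMatrix, q: float = DEFAULT_Q, freq_mode: FreqMode = "pairwise"
) -> list[CCCVector]:
    """CCC vectors for every unordered SNP pair of a matrix.

    Exactly ``C(n_snps, 2)`` records are returned; incalculable pairs are
    flagged, never silently dropped, so the element universe downstream
    stays auditable (64 SNPs -> 2016 pairs -> 8064 elements when all pairs
    are calculable).
    """
    if matrix.n_snps < 2:
        raise ValueError("need at least two SNPs")
    ccc, r, n = pairwise_ccc_arrays(matrix.dosage, q=q, freq_mode=freq_mode)
    U_scored = (matrix.dosage != MISSING)
    V = np.where(U_scored, matrix.dosage, 0) / 2.0
    out: list[CCCVector] = []
    p = matrix.n_snps
    for i in range(p):
        si = matrix.snps[i]
        for j in range(i + 1, p):
            sj = matrix.snps[j]
            combos = tuple(
                ((si.allele_a, si.allele_b)[t // 2], (sj.allele_a, sj.allele_b)[t % 2])
                for t in range(4)
            )
            nij = int(n[i, j])
            if nij == 0:
                nan4 = np.full(4, np.nan)
                out.append(
                    CCCVector(si.snp_id, sj.snp_id, combos, nan4, nan4.copy(), 0,
                              np.full(2, np.nan), np.full(2, np.nan), q)
                )
                continue
            # recover pair frequencies from the r identities: f(allele_a at i) = r[AB]+r[Ab]
            rij = r[:, i, j]
            fa_i = rij[0] + rij[1]
            fa_j = rij[0] + rij[2]
            out.append(
                CCCVector(
                    si.snp_id,
                    sj.snp_id,
                    combos,
                    rij,
                    ccc[:, i, j],
                    nij,
                    np.array([fa_i, 1 - fa_i]),
                    np.array([fa_j, 1 - fa_j]),
                    q,
                )
            )
    return out


def vectors_from_table(table) -> list[CCCVector]:
    """Rebuild :class:`CCCVector` records from a serialized long-format table.

    The table (e.g. the pipeline's ``ccc.tsv`` read with pandas) has one row
    per pair and combination, with columns snp_i, snp_j, combo ("A/G"), r,
    ccc, n_complete, calculable — the inverse of the pipeline's writer, so a
    run can be restarted from the serialized CCC stage.
    """
    out: list[CCCVector] = []
    for (si, sj), grp in table.groupby(["snp_i", "snp_j"], sort=False):
        grp = grp.reset_index(drop=True)
        if len(grp) != 4:
            raise ValueError(f"pair ({si}, {sj}): expected 4 combination rows")
        combos = tuple(tuple(c.split("/")) for c in grp["combo"])
        r = grp["r"].to_numpy(dtype=float)
        n = int(grp["n_complete"].iloc[0])
        fa_i = r[0] + r[1] if n else float("nan")
        fa_j = r[0] + r[2] if n else float("nan")
        out.append(
            CCCVector(
                si, sj, combos, r, grp["ccc"].to_numpy(dtype=float), n,
                np.array([fa_i, 1 - fa_i]), np.array([fa_j, 1 - fa_j]),
            )
        )
    return out


def iter_supra_threshold_edges(
    dosage: np.ndarray,
    threshold: float,
    q: float = DEFAULT_Q,
    block: int = 512,
    freq_mode: FreqMode = "pairwise",
) -> Iterator[tuple[int, int, int, float]]:
    """Stream (i, j, combo_index, ccc) for elements ``>= threshold``.

    Block-wise evaluation over SNP-index tiles keeps memory bounded for
    large panels (tens of thousands of SNPs), running the same arithmetic
    as :func:`pairwise_ccc_arrays` per tile.  Only the upper triangle
    ``i < j`` is emitted.
    """
    X = np.asarray(dosage)
    scored = (X != MISSING)
    M = scored.astype(float)
    V = np.where(scored, X, 0).astype(float) / 2.0
    U = M - V
    p = X.shape[1]
    if freq_mode == "per-snp":
        fa_all = U.sum(axis=0) / M.sum(axis=0)
    for bi in range(0, p, block):
        iu = slice(bi, min(bi + block, p))
        for bj in range(bi, p, block):
            ju = slice(bj, min(bj + block, p))
            N = M[:, iu].T @ M[:, ju]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.stack(
                    [
                        U[:, iu].T @ U[:, ju],
                        U[:, iu].T @ V[:, ju],
                        V[:, iu].T @ U[:, ju],
                        V[:, iu].T @ V[:, ju],
                    ]
                ) / N
                if freq_mode == "pairwise":
                    FA = (U[:, iu].T @ M[:, ju]) / N
                    FAj = (M[:, iu].T @ U[:, ju]) / N
                else:
                    FA = np.broadcast_to(fa_all[iu][:, None], N.shape)
                    FAj = np.broadcast_to(fa_all[ju][None, :], N.shape)
                ffA_i, ffa_i = 1.0 - FA / q, 1.0 - (1.0 - FA) / q
                ffA_j, ffa_j = 1.0 - FAj / q, 1.0 - (1.0 - FAj) / q
                ccc = SCALE * r * np.stack(
                    [ffA_i * ffA_j, ffA_i * ffa_j, ffa_i * ffA_j, ffa_i * ffa_j]
                )
            hits = np.argwhere(np.nan_to_num(ccc, nan=-1.0) >= threshold)
            for t, ii, jj in hits:
                gi, gj = bi + ii, bj + jj
                if gi < gj:
                    yield int(gi), int(gj), int(t), float(ccc[t, ii, jj])
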