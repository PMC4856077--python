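"""Permutation calibration of CCC significance thresholds.

The null hypothesis of no inter-SNP association is simulated by permuting
each SNP's genotype column independently across individuals: per-SNP
genotype counts (and therefore Hardy–Weinberg departures) are preserved
while all between-SNP structure is destroyed.  The permutation unit is the
diploid genotype state, and a missing call travels with its genotype.

Per trial all pairwise CCC elements are recomputed and, for each candidate
threshold, the number of supra-threshold elements ("false positives") is
counted.  The per-trial maximum statistic supports family-wise threshold
selection: the smallest threshold at which no trial yields any
supra-threshold element controls the family-wise error across every pair
and combination simultaneously.

A second permutation unit — intact per-gene multi-SNP genotype blocks —
preserves within-gene LD while destroying between-gene association; it is
the null for tests that focus power on unlinked (inter-chromosomal) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ccc import DEFAULT_Q, FreqMode, pairwise_ccc_arrays
from .genotype_io import GenotypeMatrix

__all__ = [
    "PermutationCalibration",
    "NoAdmissibleThresholdError",
    "permute_columns",
    "permute_gene_blocks",
    "calibrate",
    "select_threshold",
]


class NoAdmissibleThresholdError(ValueError):
    """No candidate threshold satisfies the selection rule."""


@dataclass
class PermutationCalibration:
    """Summary of a CCC permutation-null calibration run.

    ``counts[trial, k]`` is the number of CCC elements ``>=`` the k-th
    candidate threshold in that trial; ``max_ccc[trial]`` the trial's
    maximum element over all pairs and combinations.
    """

    n_trials: int
    thresholds: np.ndarray
    max_ccc: np.ndarray
    counts: np.ndarray
    seed: int
    q: float = DEFAULT_Q

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("candidate thresholds must be strictly increasing")
        if self.counts.shape != (self.n_trials, len(self.thresholds)):
            raise ValueError("counts shape inconsistent with trials x thresholds")

    def mean_false_positives(self) -> np.ndarray:
        """Mean supra-threshold elements per trial, per candidate threshold."""
        return self.counts.mean(axis=0)

    def count_distribution(self, threshold_index: int) -> dict[int, float]:
        """Fraction of trials with exactly 0, 1, 2, ... supra-threshold elements."""
        vals, freq = np.unique(self.counts[:, threshold_index], return_counts=True)
        return {int(v): float(c) / self.n_trials for v, c in zip(vals, freq)}

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "seed": self.seed,
            "q": self.q,
            "thresholds": self.thresholds.tolist(),
            "mean_false_positives": self.mean_false_positives().tolist(),
            "zero_fp_fraction": (self.counts == 0).mean(axis=0).tolist(),
            "count_distributions": [
                self.count_distribution(k) for k in range(len(self.thresholds))
            ],
            "max_ccc_quantiles": {
                "q50": float(np.quantile(self.max_ccc, 0.5)),
                "q95": float(np.quantile(self.max_ccc, 0.95)),
                "q99": float(np.quantile(self.max_ccc, 0.99)),
                "max": float(self.max_ccc.max()),
            },
        }


def _permute_columns_array(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(dosage)
    n = dosage.shape[0]
    for j in range(dosage.shape[1]):
        out[:, j] = dosage[rng.permutation(n), j]
    return out


def permute_columns(matrix: GenotypeMatrix, seed: int | np.random.Generator) -> GenotypeMatrix:
    """Independently permute each SNP's genotype column across individuals."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GenotypeMatrix(
        list(matrix.snps),
        list(matrix.individuals),
        _permute_columns_array(matrix.dosage, rng),
    )


def _permute_gene_blocks_array(
    dosage: np.ndarray, gene_of: list[str], rng: np.random.Generator
) -> np.ndarray:
    out = np.empty_like(dosage)
    n = dosage.shape[0]
    genes: dict[str, list[int]] = {}
    for j, g in enumerate(gene_of):
        genes.setdefault(g, []).append(j)
    for cols in genes.values():
        perm = rng.permutation(n)
        out[:, cols] = dosage[np.ix_(perm, cols)]
    return out


def permute_gene_blocks(
    matrix: GenotypeMatrix,
    gene_map: dict[str, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Permute intact multi-SNP genotype blocks, one permutation per gene.

    Within-gene associations are preserved exactly (rows move as units);
    between-gene associations are destroyed.  Every SNP must carry a gene
    label, either in its record or via ``gene_map``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_of = [
        (gene_map or {}).get(s.snp_id) or s.gene for s in matrix.snps
    ]
    unlabeled = [s.snp_id for s, g in zip(matrix.snps, gene_of) if not g]
    if unlabeled:
        raise ValueError(f"SNPs without a gene assignment: {unlabeled}")
    return GenotypeMatrix(
        list(matrix.snps),
        list(matrix.individuals),
        _permute_gene_blocks_array(matrix.dosage, gene_of, rng),
    )


def calibrate(
    matrix: GenotypeMatrix,
    n_trials: int,
    thresholds: np.ndarray | list[float],
    seed: int,
    q: float = DEFAULT_Q,
    freq_mode: FreqMode = "pairwise",
    unit: str = "snp",
    exclude_monomorphic: bool = False,
) -> PermutationCalibration:
    """Estimate null supra-threshold counts by column (or gene-block) permutation.

    One master seed spawns independent per-trial substreams so that trials
    are reproducible regardless of execution order.  ``unit`` is ``"snp"``
    (independent columns) or ``"gene"`` (intact gene blocks).
    ``exclude_monomorphic`` drops elements of pairs where either SNP is
    monomorphic among the pairwise-complete individuals, for use when the
    observed scan applies the same exclusion.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    gene_of = [s.gene for s in matrix.snps] if unit == "gene" else None
    if unit == "gene" and any(not g for g in gene_of):
        raise ValueError("gene-unit calibration requires gene labels on every SNP")

    streams = np.random.SeedSequence(seed).spawn(n_trials)
    p = matrix.n_snps
    triu = np.triu_indices(p, k=1)
    max_ccc = np.empty(n_trials)
    counts = np.empty((n_trials, len(thresholds)), dtype=np.int64)
    for t, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if unit == "gene":
            perm = _permute_gene_blocks_array(matrix.dosage, gene_of, rng)
        else:
            perm = _permute_columns_array(matrix.dosage, rng)
        ccc, r, n = pairwise_ccc_arrays(perm, q=q, freq_mode=freq_mode)
        elems = ccc[:, triu[0], triu[1]]
        if exclude_monomorphic:
            fa_i = r[0] + r[1]
            fa_j = r[0] + r[2]
            mono = (
                np.isclose(fa_i, 0) | np.isclose(fa_i, 1)
                | np.isclose(fa_j, 0) | np.isclose(fa_j, 1)
            )[triu[0], triu[1]]
            elems = elems[:, ~mono]
        finite = elems[np.isfinite(elems)]
        max_ccc[t] = finite.max() if finite.size else 0.0
        counts[t] = (finite[None, :] >= thresholds[:, None]).sum(axis=1)
    return PermutationCalibration(n_trials, thresholds, max_ccc, counts, seed, q)


def select_threshold(
    calibration: PermutationCalibration,
    rule: str = "zero-false-positives",
    max_mean_rate: float | None = None,
) -> float:
    """Choose a CCC threshold from a calibration.

    ``"zero-false-positives"``: the smallest candidate at which no trial
    produced any supra-threshold element (family-wise control over the
    whole scan).  ``"max-mean-rate"``: the smallest candidate whose mean
    supra-threshold count per trial is ``<= max_mean_rate``.
    """
    zero_frac = (calibration.counts == 0).mean(axis=0)
    if rule == "zero-false-positives":
        ok = np.flatnonzero(zero_frac == 1.0)
    elif rule == "max-mean-rate":
        if max_mean_rate is None:
            raise ValueError("max-mean-rate rule requires max_mean_rate")
        ok = np.flatnonzero(calibration.mean_false_positives() <= max_mean_rate)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if ok.size == 0:
        raise NoAdmissibleThresholdError(
            f"no candidate threshold satisfies rule {rule!r}"
        )
    return float(calibration.thresholds[ok[0]])
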