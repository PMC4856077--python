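"""Weighted latitudinal-cline regressions and the inter/intrachromosomal test.

Network carrier frequencies are regressed on population latitude by
weighted least squares, with the per-network carrier denominators as
weights (sample sizes differ across networks because of missing data).  A
quadratic model is fitted first; if its quadratic term is not significant
at ``alpha`` the linear model is refitted and reported instead.  R² is
1 - weighted residual SS / weighted total SS about the weighted mean, the
quantity that is invariant to any affine re-parameterisation of the
predictors and therefore comparable across software.

Named population-exclusion variants (e.g. dropping sub-Saharan African
populations, "-Af", or East Asian populations, "-As") rerun the same fit
on a subset, the standard probe for whether a cline is driven by an
in-/out-of-Africa frequency split rather than latitude per se.

``fisher_exact_2x2`` is the two-tailed Fisher exact test used to ask
whether candidate genes are enriched for interchromosomal associations
relative to the genomic background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import PopulationPanel
from .networks import NetworkFrequencyTable

__all__ = [
    "ClineFit",
    "NonIdentifiableError",
    "fit_cline",
    "exclusion_variants",
    "fisher_exact_2x2",
    "interchromosomal_counts",
]


class NonIdentifiableError(ValueError):
    """The regression design is degenerate (too few or coincident latitudes)."""


@dataclass
class ClineFit:
    """A fitted frequency-on-latitude regression for one network.

    ``quadratic`` is None for the linear model.  Coefficient units:
    intercept in frequency, slope in frequency per degree latitude,
    quadratic term in frequency per degree².
    """

    model: str  # "linear" | "quadratic"
    intercept: float
    slope: float
    quadratic: float | None
    p_intercept: float
    p_slope: float
    p_quadratic: float | None
    r_squared: float
    n_populations: int
    weights: dict[str, float]
    excluded: frozenset[str] = frozenset()

    def significant_slope(self, alpha: float = 0.05) -> bool:
        return self.p_slope <= alpha

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "intercept": self.intercept,
            "slope": self.slope,
            "quadratic": self.quadratic,
            "p_intercept": self.p_intercept,
            "p_slope": self.p_slope,
            "p_quadratic": self.p_quadratic,
            "r_squared": self.r_squared,
            "n_populations": self.n_populations,
            "excluded": sorted(self.excluded),
        }


def _r_squared(result) -> float:
    """Weighted R²; defined as 0 when the response carries no variance."""
    r2 = float(result.rsquared)
    return r2 if np.isfinite(r2) else 0.0


def _design(latitudes: np.ndarray, quadratic: bool) -> np.ndarray:
    cols = [np.ones_like(latitudes), latitudes]
    if quadratic:
        cols.append(latitudes**2)
    return np.column_stack(cols)


def fit_cline(
    freqs: NetworkFrequencyTable,
    panel: PopulationPanel,
    exclude: Iterable[str] = (),
    alpha: float = 0.05,
) -> ClineFit:
    """Weighted linear/quadratic regression of carrier frequency on latitude.

    Populations with a zero denominator or NaN frequency are dropped.  At
    least 3 populations are needed for the linear model and 4 for the
    quadratic to be attempted; the quadratic term is kept only when its
    p-value is ``<= alpha``.
    """
    excluded = frozenset(exclude)
    tab = freqs.table
    tab = tab[~tab["population"].isin(excluded)]
    tab = tab[(tab["denominator"] > 0) & np.isfinite(tab["frequency"])]
    pops = list(tab["population"])
    if len(pops) < 3:
        raise NonIdentifiableError(
            f"network {freqs.network_id}: only {len(pops)} populations after exclusion"
        )
    lat = np.array([panel.latitude[p] for p in pops], dtype=float)
    if np.unique(lat).size < 2:
        raise NonIdentifiableError(
            f"network {freqs.network_id}: all populations at one latitude"
        )
    y = tab["frequency"].to_numpy(dtype=float)
    w = tab["denominator"].to_numpy(dtype=float)
    weights = dict(zip(pops, w))

    if len(pops) >= 4 and np.unique(lat).size >= 3:
        quad = sm.WLS(y, _design(lat, True), weights=w).fit()
        if quad.pvalues[2] <= alpha:
            return ClineFit(
                "quadratic",
                float(quad.params[0]),
                float(quad.params[1]),
                float(quad.params[2]),
                float(quad.pvalues[0]),
                float(quad.pvalues[1]),
                float(quad.pvalues[2]),
                _r_squared(quad),
                len(pops),
                weights,
                excluded,
            )
    lin = sm.WLS(y, _design(lat, False), weights=w).fit()
    return ClineFit(
        "linear",
        float(lin.params[0]),
        float(lin.params[1]),
        None,
        float(lin.pvalues[0]),
        float(lin.pvalues[1]),
        None,
        _r_squared(lin),
        len(pops),
        weights,
        excluded,
    )


def exclusion_variants(
    freqs: NetworkFrequencyTable,
    panel: PopulationPanel,
    groups: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> dict[str, ClineFit | NonIdentifiableError]:
    """One fit per named exclusion set (e.g. {"full": [], "-Af": [...]}).

    A variant whose exclusion leaves a degenerate design maps to the
    :class:`NonIdentifiableError` instance instead of a fit.
    """
    known = set(panel.latitude)
    out: dict[str, ClineFit | NonIdentifiableError] = {}
    for name, excl in groups.items():
        excl = list(excl)
        unknown = set(excl) - known
        if unknown:
            raise KeyError(f"exclusion group {name!r} names unknown populations {sorted(unknown)}")
        try:
            out[name] = fit_cline(freqs, panel, exclude=excl, alpha=alpha)
        except NonIdentifiableError as err:
            out[name] = err
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the table [[a, b], [c, d]].

    All tables with the observed margins whose hypergeometric probability
    does not exceed the observed table's are summed.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("at least one margin must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def interchromosomal_counts(
    edge_table: pd.DataFrame, chromosome_of: Mapping[str, str]
) -> tuple[int, int]:
    """(inter, intra) chromosomal edge counts from a network edge table."""
    inter = intra = 0
    for _, row in edge_table.iterrows():
        if chromosome_of[row["snp_i"]] != chromosome_of[row["snp_j"]]:
            inter += 1
        else:
            intra += 1
    return inter, intra
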