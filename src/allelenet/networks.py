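"""Allele networks: connected components of supra-threshold CCC elements.

A panel of n biallelic SNPs defines 2n allele nodes, two per SNP.  Every
CCC element at or above a permutation-calibrated threshold contributes an
edge between the two participating allele nodes; the connected components
with at least two nodes are the allele networks.  Because nodes are
allele-specific, the two alleles of one SNP can end up in different
networks — two complementary haplotypes over the same SNPs surface as two
disjoint components, phase information that scalar LD cannot express.

A network's *carriers* in a cohort are the individuals who possess, at
every SNP in the network's node set, at least one copy of the network's
allele at that SNP (strategy switch: a homozygous-required and a
dosage-weighted variant are also provided).  Individuals missing a call at
any network SNP are excluded from numerator and denominator, so carrier
denominators vary across networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .ccc import CCCVector
from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel

__all__ = [
    "AlleleNode",
    "AlleleNetwork",
    "NetworkFrequencyTable",
    "EmptyNetworkError",
    "build_networks",
    "reduce_network",
    "carrier_frequencies",
    "carrier_mask",
    "networks_to_edge_table",
]

CarrierRule = Literal["any-copy", "homozygous", "dosage"]


class EmptyNetworkError(ValueError):
    """A network reduction removed every node."""


class AlleleNode(NamedTuple):
    """One allele of one SNP."""

    snp_id: str
    allele: str


@dataclass
class AlleleNetwork:
    """A connected component of allele nodes joined by supra-threshold CCC edges.

    ``edges`` may be empty after a reduction: membership semantics are
    carried by the node set, not by connectivity.
    """

    network_id: str
    nodes: frozenset[AlleleNode]
    edges: tuple[tuple[AlleleNode, AlleleNode, float], ...]
    genes: frozenset[str] = frozenset()
    chromosomes: frozenset[str] = frozenset()

    @property
    def snp_ids(self) -> frozenset[str]:
        return frozenset(n.snp_id for n in self.nodes)

    @property
    def interchromosomal(self) -> bool:
        return len(self.chromosomes - {""}) >= 2

    def allele_at(self, snp_id: str) -> str:
        alleles = {n.allele for n in self.nodes if n.snp_id == snp_id}
        if len(alleles) != 1:
            raise ValueError(
                f"network {self.network_id}: SNP {snp_id} has {len(alleles)} "
                "member alleles; carrier semantics need exactly one"
            )
        return next(iter(alleles))


@dataclass
class NetworkFrequencyTable:
    """Per-population carrier counts for one network.

    ``table`` columns: population, carriers, denominator, frequency.
    Frequency is NaN where the denominator is zero (every individual of the
    population missing at some network SNP).
    """

    network_id: str
    table: pd.DataFrame

    def frequency(self, population: str) -> float:
        row = self.table.loc[self.table["population"] == population]
        if row.empty:
            raise KeyError(population)
        return float(row["frequency"].iloc[0])

    def denominator(self, population: str) -> int:
        row = self.table.loc[self.table["population"] == population]
        if row.empty:
            raise KeyError(population)
        return int(row["denominator"].iloc[0])


def build_networks(
    ccc_results: Iterable[CCCVector],
    threshold: float,
    snp_annotations: dict[str, tuple[str, str]] | None = None,
) -> list[AlleleNetwork]:
    """Connected components over allele nodes with CCC ``>=`` threshold.

    ``snp_annotations`` maps snp_id -> (gene, chromosome) for labelling;
    when absent, gene/chromosome sets are empty.  Networks are ordered by
    descending node count, ties broken by smallest member snp_id, and named
    ``<threshold percent>_<rank>`` (threshold 0.65 -> ``65_1``, ``65_2``...).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    graph = nx.Graph()
    for vec in ccc_results:
        if not vec.calculable:
            continue
        for (ai, aj), value in zip(vec.combos, vec.ccc):
            if value >= threshold:
                u = AlleleNode(vec.snp_i, ai)
                v = AlleleNode(vec.snp_j, aj)
                # keep the strongest element if duplicated input lists a pair twice
                if not graph.has_edge(u, v) or graph[u][v]["ccc"] < value:
                    graph.add_edge(u, v, ccc=float(value))

    components = [c for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), min(n.snp_id for n in c)))
    prefix = f"{threshold * 100:g}".replace(".", "p")
    out: list[AlleleNetwork] = []
    for k, comp in enumerate(components, start=1):
        edges = tuple(
            sorted(
                (min(u, v), max(u, v), graph[u][v]["ccc"])
                for u, v in graph.subgraph(comp).edges
            )
        )
        genes, chroms = frozenset(), frozenset()
        if snp_annotations:
            genes = frozenset(
                snp_annotations[n.snp_id][0] for n in comp if n.snp_id in snp_annotations
            )
            chroms = frozenset(
                snp_annotations[n.snp_id][1] for n in comp if n.snp_id in snp_annotations
            )
        out.append(
            AlleleNetwork(f"{prefix}_{k}", frozenset(comp), edges, genes, chroms)
        )
    return out


def reduce_network(network: AlleleNetwork, available_snps: Iterable[str]) -> AlleleNetwork:
    """Restrict a network to the SNPs scored in another panel.

    The reduced network keeps carrier semantics by node set even if it is
    edge-disconnected.  Its id gains an ``R<k>`` suffix recording how many
    SNPs were dropped.
    """
    avail = set(available_snps)
    nodes = frozenset(n for n in network.nodes if n.snp_id in avail)
    if not nodes:
        raise EmptyNetworkError(
            f"network {network.network_id}: no member SNP available after reduction"
        )
    edges = tuple(
        (u, v, c) for u, v, c in network.edges if u in nodes and v in nodes
    )
    dropped = len(network.snp_ids) - len({n.snp_id for n in nodes})
    suffix = f"R{dropped}" if dropped else ""
    return AlleleNetwork(
        network.network_id + suffix, nodes, edges, network.genes, network.chromosomes
    )


def carrier_mask(
    network: AlleleNetwork, matrix: GenotypeMatrix, rule: CarrierRule = "any-copy"
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean carrier and complete-data masks over a matrix's individuals.

    ``complete[i]`` is True when individual i is scored at every network
    SNP; ``carrier[i]`` is only meaningful where ``complete`` holds.
    Under ``"dosage"`` the returned carrier array is a float in [0, 1]
    (product over SNPs of the within-individual network-allele frequency).
    """
    snp_ids = sorted(network.snp_ids)
    cols = []
    for sid in snp_ids:
        allele = network.allele_at(sid)
        rec = matrix.snp(sid)
        d = matrix.column(sid).astype(float)
        if allele == rec.allele_b:
            copies = d
        elif allele == rec.allele_a:
            copies = np.where(d == MISSING, MISSING, 2 - d)
        else:
            raise ValueError(
                f"network allele {allele!r} is not an allele of SNP {sid!r}"
            )
        cols.append(copies)
    copies = np.column_stack(cols)  # copies of the network allele, MISSING<0
    complete = (copies >= 0).all(axis=1)
    if rule == "any-copy":
        carrier = (copies >= 1).all(axis=1)
    elif rule == "homozygous":
        carrier = (copies == 2).all(axis=1)
    elif rule == "dosage":
        carrier = np.prod(np.clip(copies, 0, 2) / 2.0, axis=1)
    else:
        raise ValueError(f"unknown carrier rule {rule!r}")
    return carrier, complete


def carrier_frequencies(
    network: AlleleNetwork,
    matrix: GenotypeMatrix,
    panel: PopulationPanel,
    rule: CarrierRule = "any-copy",
) -> NetworkFrequencyTable:
    """Per-population frequency of individuals carrying a network's allele set."""
    missing_snps = network.snp_ids - set(matrix.snp_ids)
    if missing_snps:
        raise KeyError(
            f"network {network.network_id}: SNPs absent from matrix: {sorted(missing_snps)}"
        )
    carrier, complete = carrier_mask(network, matrix, rule=rule)
    idx = {ind: i for i, ind in enumerate(matrix.individuals)}
    rows = []
    for pop in panel.populations:
        members = [idx[i] for i in panel.individuals_of(pop) if i in idx]
        comp = [i for i in members if complete[i]]
        denom = len(comp)
        carriers = float(np.sum(carrier[comp])) if denom else 0.0
        rows.append(
            {
                "population": pop,
                "carriers": carriers if rule == "dosage" else int(carriers),
                "denominator": denom,
                "frequency": carriers / denom if denom else np.nan,
            }
        )
    return NetworkFrequencyTable(network.network_id, pd.DataFrame(rows))


def networks_to_edge_table(networks: Sequence[AlleleNetwork]) -> pd.DataFrame:
    """Flatten networks to a TSV-ready edge list."""
    rows = []
    for net in networks:
        for u, v, c in net.edges:
            rows.append(
                {
                    "network_id": net.network_id,
                    "snp_i": u.snp_id,
                    "allele_i": u.allele,
                    "snp_j": v.snp_id,
                    "allele_j": v.allele,
                    "ccc": c,
                }
            )
    return pd.DataFrame(
        rows, columns=["network_id", "snp_i", "allele_i", "snp_j", "allele_j", "ccc"]
    )
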