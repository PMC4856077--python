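"""Allele-network construction, reduction, and carrier frequencies."""

import numpy as np
import pytest

from allelenet.ccc import CCCVector, compute_ccc_all
from allelenet.genotype_io import MISSING, GenotypeMatrix, PopulationPanel, SnpRecord
from allelenet.networks import (
    AlleleNetwork,
    AlleleNode,
    EmptyNetworkError,
    build_networks,
    carrier_frequencies,
    carrier_mask,
    reduce_network,
)

from conftest import random_matrix


def _vec(snp_i, snp_j, values, alleles=("A", "G")):
    """A CCCVector stub with given element values."""
    combos = tuple((alleles[t // 2], alleles[t % 2]) for t in range(4))
    v = np.asarray(values, dtype=float)
    return CCCVector(
        snp_i, snp_j, combos, v / max(v.sum(), 1e-9), v, 10,
        np.array([0.5, 0.5]), np.array([0.5, 0.5]),
    )


class TestBuildNetworks:
    def test_empty_when_nothing_supra_threshold(self):
        vecs = [_vec("s1", "s2", [0.1, 0.2, 0.1, 0.3])]
        assert build_networks(vecs, 0.65) == []

    def test_shared_allele_chains_components(self):
        vecs = [
            _vec("s1", "s2", [0.0, 0.9, 0.0, 0.0]),  # s1.A -- s2.G
            _vec("s2", "s3", [0.0, 0.0, 0.8, 0.0]),  # s2.G -- s3.A
        ]
        nets = build_networks(vecs, 0.65)
        assert len(nets) == 1
        assert nets[0].nodes == frozenset(
            [AlleleNode("s1", "A"), AlleleNode("s2", "G"), AlleleNode("s3", "A")]
        )

    def test_threshold_comparison_is_inclusive(self):
        vecs = [_vec("s1", "s2", [0.65, 0, 0, 0])]
        assert len(build_networks(vecs, 0.65)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_components_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_snp = 12
        vecs = []
        for i in range(n_snp):
            for j in range(i + 1, n_snp):
                vals = rng.random(4) * 0.9
                vecs.append(_vec(f"s{i:02d}", f"s{j:02d}", vals))
        thr = 0.75
        nets = build_networks(vecs, thr)

        # independent union-find over the same edge set
        parent: dict = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            parent[find(a)] = find(b)

        for v in vecs:
            for (ai, aj), val in zip(v.combos, v.ccc):
                if val >= thr:
                    union((v.snp_i, ai), (v.snp_j, aj))
        groups: dict = {}
        for node in list(parent):
            groups.setdefault(find(node), set()).add(node)
        oracle = {frozenset(g) for g in groups.values() if len(g) >= 2}
        built = {frozenset((n.snp_id, n.allele) for n in net.nodes) for net in nets}
        assert built == oracle

    def test_partition_independent_of_edge_ordering(self, rng):
        vecs = []
        for i in range(8):
            for j in range(i + 1, 8):
                vecs.append(_vec(f"s{i}", f"s{j}", rng.random(4)))
        a = build_networks(vecs, 0.7)
        b = build_networks(list(reversed(vecs)), 0.7)
        assert [n.nodes for n in a] == [n.nodes for n in b]

    def test_higher_threshold_refines_networks(self, rng):
        m = random_matrix(rng, n_ind=40, n_snp=10, missing_rate=0.05)
        # plant a block so components exist
        m.dosage[:, 1] = m.dosage[:, 0]
        m.dosage[:, 2] = m.dosage[:, 0]
        vecs = compute_ccc_all(m)
        low = build_networks(vecs, 0.60)
        high = build_networks(vecs, 0.75)
        for net in high:
            parents = [p for p in low if net.nodes <= p.nodes]
            assert len(parents) == 1


class TestReduce:
    def _network(self):
        nodes = frozenset(AlleleNode(f"s{k}", "A") for k in range(4))
        edges = tuple(
            (AlleleNode(f"s{k}", "A"), AlleleNode(f"s{k+1}", "A"), 0.8)
            for k in range(3)
        )
        return AlleleNetwork("65_1", nodes, edges)

    def test_identity_when_all_snps_available(self):
        net = self._network()
        red = reduce_network(net, {"s0", "s1", "s2", "s3"})
        assert red.nodes == net.nodes and red.network_id == "65_1"

    def test_reduction_drops_nodes_and_edges(self):
        net = self._network()
        red = reduce_network(net, {"s0", "s1"})
        assert {n.snp_id for n in red.nodes} == {"s0", "s1"}
        assert len(red.edges) == 1
        assert red.network_id == "65_1R2"

    def test_empty_reduction_signalled(self):
        with pytest.raises(EmptyNetworkError):
            reduce_network(self._network(), {"sX"})


def _matrix_and_panel():
    """5 individuals, 2 populations, 2 SNPs; one missing genotype."""
    snps = [
        SnpRecord("s1", gene="g1", allele_a="A", allele_b="G"),
        SnpRecord("s2", gene="g2", allele_a="C", allele_b="T"),
    ]
    dosage = np.array(
        [[1, 2], [0, 1], [2, MISSING], [1, 0], [2, 2]], dtype=np.int8
    )
    m = GenotypeMatrix(snps, [f"i{k}" for k in range(1, 6)], dosage)
    panel = PopulationPanel(
        {"i1": "P1", "i2": "P1", "i3": "P1", "i4": "P2", "i5": "P2"},
        {"P1": 10.0, "P2": 40.0},
    )
    return m, panel


class TestCarrierFrequencies:
    def test_hand_enumeration_with_missing_data(self):
        m, panel = _matrix_and_panel()
        net = AlleleNetwork(
            "n1",
            frozenset([AlleleNode("s1", "G"), AlleleNode("s2", "T")]),
            (),
        )
        tab = carrier_frequencies(net, m, panel)
        # P1: i3 missing at s2 -> denominator 2; carriers: i1 (G>=1, T>=1) yes,
        # i2 (0 G) no -> 1/2.  P2: i4 no (0 T), i5 yes -> 1/2.
        assert tab.denominator("P1") == 2 and tab.frequency("P1") == 0.5
        assert tab.denominator("P2") == 2 and tab.frequency("P2") == 0.5

    def test_single_allele_network_equals_allele_carrier_frequency(self):
        m, panel = _matrix_and_panel()
        net = AlleleNetwork("n1", frozenset([AlleleNode("s1", "G")]), ())
        tab = carrier_frequencies(net, m, panel)
        # P1: dosages 1,0,2 -> carriers 2/3
        assert tab.frequency("P1") == pytest.approx(2 / 3)

    def test_everyone_homozygous_gives_frequency_one(self):
        snps = [SnpRecord("s1", allele_a="A", allele_b="G")]
        m = GenotypeMatrix(snps, ["i1", "i2"], np.array([[2], [2]], dtype=np.int8))
        panel = PopulationPanel({"i1": "P", "i2": "P"}, {"P": 0.0})
        net = AlleleNetwork("n", frozenset([AlleleNode("s1", "G")]), ())
        assert carrier_frequencies(net, m, panel).frequency("P") == 1.0

    def test_homozygous_rule_is_stricter(self):
        m, panel = _matrix_and_panel()
        net = AlleleNetwork("n1", frozenset([AlleleNode("s1", "G")]), ())
        any_copy = carrier_frequencies(net, m, panel, rule="any-copy")
        homo = carrier_frequencies(net, m, panel, rule="homozygous")
        for pop in ("P1", "P2"):
            assert homo.frequency(pop) <= any_copy.frequency(pop)

    def test_zero_denominator_population_flagged(self):
        snps = [SnpRecord("s1", allele_a="A", allele_b="G")]
        m = GenotypeMatrix(
            snps, ["i1", "i2"], np.array([[1], [MISSING]], dtype=np.int8)
        )
        panel = PopulationPanel({"i1": "P1", "i2": "P2"}, {"P1": 0.0, "P2": 1.0})
        net = AlleleNetwork("n", frozenset([AlleleNode("s1", "G")]), ())
        tab = carrier_frequencies(net, m, panel)
        assert tab.denominator("P2") == 0 and np.isnan(tab.frequency("P2"))

    def test_reduced_network_never_loses_carriers(self, rng):
        m = random_matrix(rng, n_ind=50, n_snp=4, missing_rate=0.0)
        nodes = frozenset(AlleleNode(s.snp_id, s.allele_b) for s in m.snps)
        parent = AlleleNetwork("p", nodes, ())
        reduced = reduce_network(parent, {"rs1", "rs2"})
        c_parent, comp = carrier_mask(parent, m)
        c_red, _ = carrier_mask(reduced, m)
        assert (c_red[comp] >= c_parent[comp]).all()
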