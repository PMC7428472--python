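import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crosskingdom.networks import (
    AssociationNetwork,
    Edge,
    compare_networks,
    dcor_edges,
    dcor_permutation_p,
    distance_correlation,
    network_stats,
    spearman_edges,
    spearman_pair,
)
from crosskingdom.simulate import network_scenario, simulate_tables
from crosskingdom.table_io import AbundanceTable, SampleMetadata, relative_abundance


def brute_force_dcor(x, y):
    """Independent O(n^2) oracle with explicit double loops."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        row = [sum(r) / n for r in m]
        col = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(row) / n
        return [[m[i][j] - row[i] - col[j] + grand for j in range(n)]
                for i in range(n)]

    ca, cb = center(a), center(b)
    dcov2 = sum(ca[i][j] * cb[i][j] for i in range(n) for j in range(n)) / n ** 2
    dvx = sum(ca[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    dvy = sum(cb[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvx * dvy) ** 0.5) ** 0.5


def make_table(data, kingdom="bacteria", prefix="t"):
    data = np.asarray(data, dtype=float)
    return AbundanceTable(
        pd.DataFrame(data, index=[f"s{i}" for i in range(data.shape[0])],
                     columns=[f"{prefix}{j}" for j in range(data.shape[1])]),
        kingdom,
    )


class TestDistanceCorrelation:
    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert distance_correlation(x, y) == pytest.approx(
                brute_force_dcor(x, y), abs=1e-10)

    def test_affine_relation_is_one(self):
        x = np.arange(10.0)
        assert distance_correlation(x, 3.0 + 2.0 * x) == pytest.approx(1.0)
        assert distance_correlation(x, 1.0 - 0.5 * x) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        x = np.arange(8.0)
        assert distance_correlation(x, np.full(8, 3.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distance_correlation(np.arange(5.0), np.arange(6.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            distance_correlation(np.arange(3.0), np.arange(3.0))

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        d = distance_correlation(x, y)
        assert d == pytest.approx(distance_correlation(y, x), abs=1e-12)
        assert d == pytest.approx(distance_correlation(2.5 * x - 1.0, y), abs=1e-9)
        assert 0.0 <= d <= 1.0


class TestDcorPermutation:
    def test_planted_correlation_recovered(self):
        hits = 0
        seeds = range(20)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            z = rng.normal(size=40)
            x = z + 0.72 * rng.normal(size=40)  # corr ~ 0.81
            y = z + 0.72 * rng.normal(size=40)
            _, p = dcor_permutation_p(x, y, n_perm=199, seed=seed)
            hits += p < 0.05
        assert hits >= 0.9 * len(seeds)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(200):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = dcor_permutation_p(x, y, n_perm=99, seed=i)
            ps.append(p)
        rate = np.mean(np.array(ps) < 0.05)
        assert abs(rate - 0.05) <= 0.04

    def test_constant_input(self):
        d, p = dcor_permutation_p(np.arange(10.0), np.zeros(10), n_perm=99)
        assert d == 0.0 and p == 1.0


class TestSpearman:
    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            rho, _ = spearman_pair(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_perfect_monotone_edge(self):
        x = np.linspace(0, 1, 20)
        table = make_table(np.column_stack([x, np.exp(x)]))
        net = spearman_edges(relative_abundance(table) if False else table,
                             alpha=0.05)
        assert len(net.edges) == 1
        assert net.edges[0].value == pytest.approx(1.0)
        assert net.edges[0].sign == 1

    def test_exact_small_sample_p(self):
        # n=6, perfect monotone: exact permutation p = 2/6!
        x = np.arange(6.0)
        rho, p = spearman_pair(x, x * 2 + 1)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 720, rel=1e-9)

    def test_null_edge_rate(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.uniform(size=(30, 46)))  # C(46,2) = 1035 pairs
        net = spearman_edges(table, alpha=0.05)
        n_pairs = 46 * 45 // 2
        assert abs(len(net.edges) / n_pairs - 0.05) <= 0.02

    def test_constant_taxon_skipped(self):
        data = np.column_stack([np.ones(12), np.arange(12.0), np.arange(12.0) ** 2])
        net = spearman_edges(make_table(data))
        involved = {t for e in net.edges for t in (e.taxon_a, e.taxon_b)}
        assert "t0" not in involved

    def test_needs_five_samples(self):
        with pytest.raises(ValueError):
            spearman_edges(make_table(np.ones((4, 3))))


class TestDcorEdges:
    def make_pair(self, rng, n=30, nb=6, nf=5, link=None):
        b = rng.uniform(1, 10, size=(n, nb))
        f = rng.uniform(1, 10, size=(n, nf))
        if link:
            i, j, strength = link
            shared = rng.normal(size=n)
            b[:, i] = 10 + shared + strength * rng.normal(size=n)
            f[:, j] = 10 + shared + strength * rng.normal(size=n)
        return make_table(b, "bacteria", "b"), make_table(f, "fungi", "f")

    def test_planted_cross_edge_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bact, fungi = self.make_pair(rng, link=(0, 0, 0.6))
            net = dcor_edges(bact, fungi, n_perm=199, seed=seed)
            hits += any({e.taxon_a, e.taxon_b} == {"b0", "f0"} for e in net.edges)
        assert hits >= 9

    def test_only_cross_kingdom_pairs(self):
        rng = np.random.default_rng(4)
        bact, fungi = self.make_pair(rng)
        net = dcor_edges(bact, fungi, n_perm=99, seed=1)
        for e in net.edges:
            assert e.kingdom_a != e.kingdom_b

    def test_determinism(self):
        rng = np.random.default_rng(6)
        bact, fungi = self.make_pair(rng, link=(1, 2, 0.8))
        n1 = dcor_edges(bact, fungi, n_perm=99, seed=7)
        n2 = dcor_edges(bact, fungi, n_perm=99, seed=7)
        assert n1.edges == n2.edges

    def test_alignment_required(self):
        rng = np.random.default_rng(8)
        bact, fungi = self.make_pair(rng)
        shuffled = fungi.select_samples(list(reversed(fungi.sample_ids)))
        with pytest.raises(ValueError, match="aligned"):
            dcor_edges(bact, shuffled)

    def test_null_edge_rate(self):
        rng = np.random.default_rng(12)
        bact = make_table(rng.uniform(size=(40, 40)), "bacteria", "b")
        fungi = make_table(rng.uniform(size=(40, 26)), "fungi", "f")
        net = dcor_edges(bact, fungi, n_perm=199, seed=3)  # 1040 pairs
        assert abs(len(net.edges) / (40 * 26) - 0.05) <= 0.02


class TestNetworkStats:
    def star(self, k):
        edges = tuple(Edge("hub", f"leaf{i}", "bacteria", "bacteria",
                           "spearman", 0.9, 1, 0.001) for i in range(k))
        taxa = ("hub",) + tuple(f"leaf{i}" for i in range(k))
        return AssociationNetwork(edges, taxa,
                                  {t: "bacteria" for t in taxa}, alpha=0.05)

    def test_arithmetic(self):
        # 20 nodes / 30 edges -> connectedness 1.5 (ring plus chords)
        taxa = tuple(f"n{i}" for i in range(20))
        edges = []
        for i in range(20):
            edges.append(Edge(f"n{i}", f"n{(i + 1) % 20}", "bacteria", "bacteria",
                              "spearman", 0.5, 1, 0.01))
        for i in range(10):
            edges.append(Edge(f"n{i}", f"n{i + 5}", "bacteria", "bacteria",
                              "spearman", 0.5, 1, 0.01))
        net = AssociationNetwork(tuple(edges), taxa,
                                 {t: "bacteria" for t in taxa}, alpha=0.05)
        s = network_stats(net)
        assert s["nodes"] == 20 and s["edges"] == 30
        assert s["connectedness"] == pytest.approx(1.5)

    def test_triangle(self):
        taxa = ("a", "b", "c")
        edges = tuple(Edge(x, y, "bacteria", "bacteria", "spearman", 0.5, 1, 0.01)
                      for x, y in (("a", "b"), ("b", "c"), ("a", "c")))
        net = AssociationNetwork(edges, taxa, {t: "bacteria" for t in taxa},
                                 alpha=0.05)
        s = network_stats(net)
        assert (net.degrees() == 2).all()
        assert s["connectedness"] == pytest.approx(1.0)

    def test_star_closed_form(self):
        s = network_stats(self.star(7))
        assert s["edges"] == 7 and s["nodes"] == 8
        assert s["connectedness"] == pytest.approx(7 / 8)
        assert network_stats(self.star(7))["mean_degree"] == pytest.approx(14 / 8)

    def test_degree_sum_twice_edges(self):
        net = self.star(5)
        assert net.degrees().sum() == 2 * len(net.edges)

    def test_empty_network(self):
        net = AssociationNetwork((), ("a", "b"), {"a": "bacteria", "b": "bacteria"})
        s = network_stats(net)
        assert s["nodes"] == 0 and s["connectedness"] == 0.0

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            AssociationNetwork(
                (Edge("a", "a", "bacteria", "bacteria", "spearman", 1.0, 1, 0.01),),
                ("a",), {"a": "bacteria"})

    def test_insignificant_edge_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            AssociationNetwork(
                (Edge("a", "b", "bacteria", "bacteria", "spearman", 1.0, 1, 0.2),),
                ("a", "b"), {"a": "bacteria", "b": "bacteria"}, alpha=0.05)


class TestCompareNetworks:
    def test_identical_networks_p_one(self):
        taxa = ("a", "b", "c")
        edges = tuple(Edge(x, y, "bacteria", "bacteria", "spearman", 0.5, 1, 0.01)
                      for x, y in (("a", "b"), ("b", "c"), ("a", "c")))
        net = AssociationNetwork(edges, taxa, {t: "bacteria" for t in taxa})
        comp = compare_networks(net, net)
        assert comp.degree_p_value == 1.0

    def test_parameter_mismatch_rejected(self):
        taxa = ("a", "b", "c")
        edges = tuple(Edge(x, y, "bacteria", "bacteria", "spearman", 0.5, 1, 0.001)
                      for x, y in (("a", "b"), ("b", "c")))
        kings = {t: "bacteria" for t in taxa}
        n1 = AssociationNetwork(edges, taxa, kings, alpha=0.05)
        n2 = AssociationNetwork(edges, taxa, kings, alpha=0.01)
        with pytest.raises(ValueError, match="parameters"):
            compare_networks(n1, n2)

    def test_dense_vs_sparse_direction_and_significance(self):
        bact, fungi, meta, truth = simulate_tables(network_scenario(seed=0))
        nets = {}
        for group in ("dense", "sparse"):
            keep = meta.groups[meta.groups == group].index
            nets[group] = dcor_edges(
                relative_abundance(bact.select_samples(keep)),
                relative_abundance(fungi.select_samples(keep)),
                n_perm=199, seed=0, group_label=group)
        comp = compare_networks(nets["dense"], nets["sparse"])
        frame = comp.stats_per_group
        assert (frame.loc["dense", "connectedness"]
                > frame.loc["sparse", "connectedness"])
        assert comp.degree_p_value < 1e-4

    def test_edge_count_monotone_in_alpha(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.uniform(size=(25, 15)))
        strict = spearman_edges(table, alpha=0.01)
        loose = spearman_edges(table, alpha=0.10)
        assert len(strict.edges) <= len(loose.edges)


class TestExport:
    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        from crosskingdom.networks import edges_frame, write_edges, write_graphml

        taxa = ("a", "b", "c")
        edges = (
            Edge("a", "b", "bacteria", "fungi", "dcor", 0.8, 1, 0.01),
            Edge("b", "c", "fungi", "fungi", "dcor", 0.6, -1, 0.02),
        )
        net = AssociationNetwork(edges, taxa, {"a": "bacteria", "b": "fungi",
                                               "c": "fungi"})
        gml = tmp_path / "net.graphml"
        write_graphml(net, gml)
        g = nx.read_graphml(gml)
        assert set(g.nodes) == {"a", "b", "c"}
        assert g.edges[("a", "b")]["sign"] == 1

        tsv = tmp_path / "edges.tsv"
        write_edges(net, tsv)
        frame = edges_frame(net)
        back = pd.read_csv(tsv, sep="\t")
        assert list(back.columns) == list(frame.columns)
        assert len(back) == 2
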